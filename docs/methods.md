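# Methods

## Biological setting

HER2-positive breast cancer cells signal through the MAP kinases ERK, JNK
and p38 downstream of the HER2 receptor. Dual-specificity phosphatases
(DUSPs) close negative-feedback loops on this axis: a DUSP is
transcriptionally induced by one or more MAP kinases and dephosphorylates
(inactivates) its substrate kinases. Herceptin (trastuzumab) blocks HER2
dimerization and so cuts the upstream drive. This package models the first
24 h of that perturbation with Boolean logic, processes qPCR time courses of
DUSP expression, clusters them by shape, and uses the models to infer which
kinase induces the DUSPs whose regulation is only partially known.

## Boolean model semantics

Nodes are binary (ON/OFF). Update rules are Boolean expressions over node
names with `and`, `or`, `not` (precedence NOT > AND > OR). Synchronous
updating rewrites every node from the previous state at once; it is
deterministic, so every trajectory enters a limit cycle (a fixed point is a
cycle of length 1) within at most 2^k steps for k free nodes.
`find_attractor` iterates until a state repeats and returns the transient
and the cycle; it is cross-checked in the test suite against exhaustive
state-transition-graph construction over all 2^k states. Asynchronous
updating (one uniformly chosen non-input node per step, mandatory RNG seed)
is provided as a confirmation mode; synchronous results are canonical.

Clamped input nodes (Herceptin, Basal) hold their externally supplied value
for the whole run.

### Scaffold construction

Each modelled DUSP gets a seven-node scaffold:

    HER2*     = not Herceptin
    kinase K* = (HER2 or Basal) and not DUSP   if K is a substrate of the DUSP
    kinase K* = HER2                           otherwise
    DUSP*     = OR of its inducer kinases
    Survival* = not (JNK and p38)

Choices that were genuinely open, and how they were made:

* **Basal drive.** With Herceptin ON, HER2 shuts down and every loop would
  trivially collapse to all-OFF. A Herceptin-insensitive basal drive
  (ligand-independent HER2 homodimer signalling, basal kinase activity) is
  the minimal addition that keeps the DUSP–kinase negative feedback engaged.
  It is applied uniformly to every substrate kinase, which preserves the
  JNK↔p38 symmetry of the scaffold exactly; the qualitative-outcome suite
  validates the choice for every shipped model.
* **Survival as a pure apoptosis gate.** Sustained co-activity of the two
  stress kinases JNK and p38 drives apoptosis; ERK is not required for
  survival in the scaffold. This reproduces survival staying ON in models
  where ERK oscillates or decays, and switching OFF only in the DUSP16
  model, where the DUSP restrains both stress kinases and its loss of
  induction releases them together.
* **OR for induction.** Induction edges combine by OR; AND is reserved for
  explicitly cooperative regulation, which none of the modelled induction
  statements assert.
* **One node per DUSP.** Transcript and active protein are collapsed,
  because the measured mRNA time courses are compared directly to the
  Boolean node.
* **Initial condition.** All nodes start ON: the cells carry active HER2
  signalling before treatment, and at t = 0 every measured DUSP sits at its
  control expression level (fold change 1). Herceptin is clamped ON from
  t = 0. Both are exposed in configuration.

### Pattern classification

A node's long-run behaviour is labelled from its attractor: OSCILLATING if
it varies within the cycle; otherwise the initial value is compared with the
settled cycle value — unchanged → CONSTANT_ON/OFF, 1→0 → ON_THEN_OFF, 0→1 →
OFF_THEN_ON. Classification by endpoints is deliberate: synchronous updating
produces one-step synchronization artifacts during the transient (e.g. JNK
and p38 simultaneously ON for a single step immediately after the clamp
switches), and a single-step excursion that returns to the starting level is
not a qualitative state change. The labels are total over all trajectories
and invariant to extending the simulation beyond one full cycle.

## ΔΔCT processing

Per replicate (2 biological × 3 technical): ΔCT = CT_target − mean of the
two reference CTs (arithmetic mean on the CT scale, equivalent to
geometric-mean normalization on the expression scale); ΔΔCT = ΔCT(t) − mean
control ΔCT; fold = 2^(−ΔΔCT), i.e. assumed primer efficiency 2. ΔΔCT is
propagated per replicate rather than computed on averaged CTs so that
replicate spread reaches the reported standard errors. The per-time point
estimate is the geometric mean of replicate folds, which makes fold(t=0)
exactly 1 by construction; the SE is the standard error of the replicate
folds. Significance per time point is a two-sided Welch t-test of the
replicate log2 folds against the control replicates at α = 0.05, with no
multiple-testing correction (per-gene, per-time flags mirror common qPCR
reporting practice; a known limitation).

## Correlation clustering

Fold-change series are log10-transformed; pairwise Pearson correlations are
computed and negatives clipped to zero, so clusters contain only positively
co-varying genes. Each gene's feature vector is its row of the clipped
matrix; rows are agglomerated by average linkage on euclidean distances
(the defaults of a standard clustermap; the metric is a documented choice,
not a measured fact). Cutting at `cut_height` yields flat clusters;
singletons are reported UNCLUSTERED. The default cut of 0.4 was calibrated
once on the noise-free synthetic fixture to recover the planted cluster
count. Zero-variance series get correlation 0 with a warning.

Cluster (and per-gene) shape descriptors are direction-symbol strings over
{+, −, 0}: the sign of each consecutive difference of mean log10 fold
change, with a dead-band ε = 0.05 log10 units (configurable) flattening
replicate noise to "0".

## Regulator inference

For a DUSP with unknown inducers, all 7 non-empty OR-combined subsets of
{ERK, JNK, p38} are enumerated (ordered by size, then ERK < JNK < p38). Each
candidate model is simulated to its attractor under Herceptin; the DUSP
node's values over transient + one cycle become a symbol string. Agreement
with the experimental descriptor is

    score = 1 − levenshtein(sim, exp) / max(|sim|, |exp|)

computed on **run-length-compressed** strings (consecutive repeats
collapsed) — Boolean time is only ordinally aligned to experimental time, so
dwell time in a monotone segment carries no information; without compression
the metric would systematically reward long oscillating strings through free
deletions. A +0.1 bonus (capped at 1) is added when the simulated pattern
class matches the class implied by the experimental string. Hypotheses
related by swapping JNK and p38 are merged into one symmetry class (the
scaffold treats the two stress kinases identically whenever the substrate
set does); class members provably share a score, and the ranking never
breaks ties arbitrarily — hypotheses that are dynamically indistinguishable
(e.g. {JNK} vs {JNK, p38} when neither stress kinase is a substrate) are
reported jointly at the same rank.

Self-consistency holds by construction and is asserted exhaustively: for
each of the four inference targets and each of the 7 planted inducer
subsets, generating the experimental string from the planted model and
re-running inference puts the planted hypothesis's class at the top score
(28/28, joint rank 1 where indistinguishable).

**Identifiability limits.** In the minimal scaffold, a DUSP whose substrates
include all three kinases (DUSP3, DUSP23) makes every kinase follow the same
rule, so all 7 hypotheses produce identical dynamics — the inducer is not
identifiable from this scaffold and the ranking reports a complete tie. A
monotone-decreasing DUSP16 course singles out ERK induction (the only
hypothesis without a feedback loop through the DUSP, hence the only
non-oscillating model). Experimental patterns containing a late rise (the
cluster-2 shape) are matched best by oscillating-feedback hypotheses;
richer network topologies could separate these further but are outside the
scaffold.

## Synthetic data generator

The generator emulates the study design: 21 genes, times 0/2/4/12/24 h,
2 biological × 3 technical replicates, references Actinb and GAPDH. Seven
log2 fold-change templates transcribe the verbal cluster shapes (amplitudes
are free parameters chosen once at plausible qPCR effect sizes of 0.3–2
log2 units); cluster membership mirrors the reported composition (3 + 2×6
genes); six genes carry individual templates and are planted unclustered.
Cluster 5 is described only as a small-range oscillation with no stated
phase; its template is phase-shifted from cluster 4's alternating shape
because two same-phase alternating templates are Pearson-indistinguishable
on five time points.

CT values: `ref_ct + baseline_offset + jitter_gene − template_log2fc(t) + ε`
with ε ~ N(0, sd) per well on the CT scale (default sd 0.15 cycles — typical
technical cycle noise; lognormal multiplicative noise on the expression
scale) and a fixed per-gene baseline jitter (sd 1.5 cycles). The planted
truth is a separate artifact; the pipeline can recover it only through the
data.

What the generator does **not** emulate: primer-efficiency differences,
amplification-curve artifacts, plate/batch effects, biological-repeat random
effects beyond well noise, and between-gene correlation of noise. Passing
recovery tests therefore demonstrates correctness of the computational
pipeline under the assumed noise model, not robustness to every failure
mode of real qPCR data.

## Problem sizes and numerics

Boolean models here have ≤ 6 free nodes, so attractors close within ~65
steps; the engine caps nothing and detects repeats exactly. The
engine-vs-oracle suite uses 100 random networks of ≤ 8 nodes (2^8-state
exhaustive graphs). Clustering recovery uses 20 generator seeds. All
randomness flows through explicit `numpy.random.default_rng` seeds; reports
carry no timestamps, so identical configuration and seed give byte-identical
outputs.

## Known limitations

* The scaffolds are minimal reconstructions from textual regulation
  statements, not transcriptions of full published pathway maps; only the
  stated qualitative behaviours are binding, and intermediate kinases
  (RAS/RAF/MEK, MKKs) are collapsed.
* No statistical confidence accompanies inference rankings; the score is a
  qualitative agreement measure.
* No multiple-testing correction in the per-time significance flags.
* Boolean time is ordinal; durations (e.g. "decrease until 12 h") inform
  template shapes but are never compared quantitatively to simulation steps.
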