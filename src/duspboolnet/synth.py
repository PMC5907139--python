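"""Synthetic qPCR data with planted cluster structure.

The generator emulates the study design: 21 DUSP genes measured at 0, 2, 4,
12 and 24 h after Herceptin exposure, two biological repeats each in
triplicate, normalized against the stable reference genes Actinb and GAPDH.
Seven cluster templates transcribe the verbally described cluster shapes
(e.g. cluster 1: immediate decrease, rise to 12 h, drop after 12 h) into
log2 fold-change anchors; template amplitudes are free parameters of the
generator, not measured values.  Six further genes carry individual
templates and are planted as unclustered.

CT values are built as ``ref_ct + offset_gene − template_log2fc(t) + ε``
with Gaussian noise ε on the CT (cycle) scale — the standard model for qPCR
threshold-cycle noise, equivalent to lognormal multiplicative noise on the
expression scale.  The planted truth (cluster labels, true fold changes) is
returned as a separate artifact; nothing downstream can read it except
through the data itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .clustering import UNCLUSTERED
from .qpcr import REFERENCE_GENES, TIME_POINTS_H, ExpressionSeries

__all__ = [
    "SynthConfig",
    "PlantedTruth",
    "default_config",
    "generate_ct_table",
    "generate_pattern_series",
    "CLUSTER_TEMPLATES",
    "CLUSTER_MEMBERS",
    "UNCLUSTERED_TEMPLATES",
]

# log2 fold-change anchors at 0, 2, 4, 12, 24 h transcribing the described
# cluster shapes; interval sign patterns in comments.
CLUSTER_TEMPLATES = {
    1: [0.0, -1.0, 0.5, 2.0, 0.2],     # - + + -  dip, rise to 12 h, drop
    2: [0.0, 0.1, 0.15, 1.8, 1.2],     # 0 0 + -  flat to 4 h, late rise
    3: [0.0, -0.8, -1.6, -0.3, -0.35], # - - + 0  fall to 4 h, recover
    4: [0.0, -1.2, 0.6, -1.2, 0.3],    # - + - +  alternating, large swing
    5: [0.0, 0.35, -0.3, 0.35, -0.3],  # + - + -  small-range oscillation
    6: [0.0, -0.7, -1.3, -2.0, -0.8],  # - - - +  fall to 12 h, recover
    7: [0.0, 0.6, -0.4, -1.4, -2.0],   # + - - -  brief rise, steady fall
}

# Planted membership mirrors the reported cluster composition.
CLUSTER_MEMBERS = {
    1: ["DUSP2", "DUSP6", "DUSP8"],
    2: ["DUSP9", "DUSP11"],
    3: ["DUSP4", "DUSP7"],
    4: ["DUSP23", "DUSP28"],
    5: ["DUSP5", "DUSP22"],
    6: ["DUSP3", "DUSP21"],
    7: ["DUSP1", "DUSP12"],
}

# Individual shapes for the six genes that did not fit any cluster.
UNCLUSTERED_TEMPLATES = {
    "DUSP10": [0.0, -0.5, -0.9, -1.2, -1.5],
    "DUSP14": [0.0, -0.3, -1.8, -1.9, -2.0],
    "DUSP15": [0.0, 0.8, 1.6, -0.5, -1.0],
    "DUSP16": [0.0, -0.4, -0.8, -1.3, -1.8],
    "DUSP18": [0.0, 0.4, 0.8, 1.3, 1.8],
    "DUSP19": [0.0, 1.5, 0.2, -0.2, -0.3],
}


@dataclass
class SynthConfig:
    templates: dict = field(default_factory=lambda: dict(CLUSTER_TEMPLATES))
    members: dict = field(default_factory=lambda: {
        k: list(v) for k, v in CLUSTER_MEMBERS.items()
    })
    unclustered: dict = field(default_factory=lambda: dict(UNCLUSTERED_TEMPLATES))
    times_h: tuple = TIME_POINTS_H
    ct_noise_sd: float = 0.15   # cycles
    ref_ct: float = 15.0        # baseline reference-gene CT
    baseline_offset: float = 5.0  # target genes sit this many cycles above refs
    gene_jitter_sd: float = 1.5   # fixed per-gene baseline spread, cycles
    bio_reps: int = 2
    tech_reps: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if self.bio_reps < 1 or self.tech_reps < 1:
            raise ValueError("replicate counts must be >= 1")
        n_times = len(self.times_h)
        for cid, tmpl in self.templates.items():
            if len(tmpl) != n_times:
                raise ValueError(f"template for cluster {cid} has wrong length")
            if tmpl[0] != 0:
                raise ValueError(
                    f"template for cluster {cid} must be 0 at t = 0 "
                    "(control-relative)"
                )
            if cid not in self.members:
                raise ValueError(f"cluster {cid} has a template but no members")
        for cid in self.members:
            if cid not in self.templates:
                raise ValueError(f"cluster {cid} has members but no template")
        for g, tmpl in self.unclustered.items():
            if len(tmpl) != n_times or tmpl[0] != 0:
                raise ValueError(f"bad unclustered template for {g}")

    @property
    def genes(self) -> list[str]:
        out = []
        for cid in sorted(self.members):
            out.extend(self.members[cid])
        out.extend(self.unclustered)
        return out

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def default_config(seed: int = 0, **overrides) -> SynthConfig:
    return SynthConfig(seed=seed, **overrides)


@dataclass
class PlantedTruth:
    assignment: dict   # gene -> cluster id or UNCLUSTERED
    true_fold_changes: pd.DataFrame  # gene × time, 2^template
    patterns: dict     # cluster id / gene -> planted symbol string


def _gene_templates(cfg: SynthConfig) -> dict:
    out = {}
    for cid, genes in cfg.members.items():
        for g in genes:
            out[g] = np.asarray(cfg.templates[cid], dtype=float)
    for g, tmpl in cfg.unclustered.items():
        out[g] = np.asarray(tmpl, dtype=float)
    return out


def _planted_pattern(tmpl: np.ndarray, deadband: float = 0.05) -> str:
    d = np.diff(tmpl) * np.log10(2.0)
    return "".join(
        "0" if abs(x) < deadband else "+" if x > 0 else "-" for x in d
    )


def generate_ct_table(cfg: SynthConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Emit a tidy CT table and the matching planted truth.

    Deterministic given ``cfg.seed``.  Reference genes get CT = ref_ct + ε;
    target genes get CT = ref_ct + baseline_offset + jitter_gene −
    template_log2fc(t) + ε per well (higher expression ⇒ earlier threshold
    crossing ⇒ lower CT).
    """
    rng = np.random.default_rng(cfg.seed)
    tmpls = _gene_templates(cfg)
    jitter = {g: rng.normal(0.0, cfg.gene_jitter_sd) for g in cfg.genes}
    rows = []
    for gene in list(cfg.genes) + list(REFERENCE_GENES):
        for it, t in enumerate(cfg.times_h):
            for b in range(1, cfg.bio_reps + 1):
                for r in range(1, cfg.tech_reps + 1):
                    eps = rng.normal(0.0, cfg.ct_noise_sd) if cfg.ct_noise_sd else 0.0
                    if gene in REFERENCE_GENES:
                        ct = cfg.ref_ct + eps
                    else:
                        ct = (
                            cfg.ref_ct
                            + cfg.baseline_offset
                            + jitter[gene]
                            - tmpls[gene][it]
                            + eps
                        )
                    rows.append(
                        {
                            "gene": gene,
                            "time_h": float(t),
                            "bio_rep": b,
                            "tech_rep": r,
                            "ct": ct,
                        }
                    )
    table = pd.DataFrame(rows)

    assignment = {}
    for cid, genes in cfg.members.items():
        for g in genes:
            assignment[g] = cid
    for g in cfg.unclustered:
        assignment[g] = UNCLUSTERED
    truth_fc = pd.DataFrame(
        {g: 2.0 ** tmpls[g] for g in cfg.genes},
        index=[float(t) for t in cfg.times_h],
    ).T
    patterns = {cid: _planted_pattern(np.asarray(t)) for cid, t in cfg.templates.items()}
    patterns.update(
        {g: _planted_pattern(np.asarray(t)) for g, t in cfg.unclustered.items()}
    )
    return table, PlantedTruth(
        assignment=assignment, true_fold_changes=truth_fc, patterns=patterns
    )


def generate_pattern_series(
    pattern: str,
    noise: float = 0.0,
    seed: int = 0,
    gene: str = "synthetic",
    step_log2: float = 1.0,
    times_h=TIME_POINTS_H,
) -> ExpressionSeries:
    """A fold-change series whose differenced sign string equals ``pattern``
    at zero noise.  ``pattern`` has one symbol from {+, -, 0} per interval.
    """
    if len(pattern) != len(times_h) - 1:
        raise ValueError(
            f"pattern must have {len(times_h) - 1} symbols, got {len(pattern)}"
        )
    steps = []
    for ch in pattern:
        if ch == "+":
            steps.append(step_log2)
        elif ch == "-":
            steps.append(-step_log2)
        elif ch == "0":
            steps.append(0.0)
        else:
            raise ValueError(f"bad pattern symbol {ch!r}")
    log2fc = np.concatenate([[0.0], np.cumsum(steps)])
    if noise:
        rng = np.random.default_rng(seed)
        log2fc = log2fc + rng.normal(0.0, noise, size=log2fc.shape)
        log2fc[0] = 0.0
    fc = 2.0 ** log2fc
    return ExpressionSeries(
        gene=gene,
        times=np.asarray(times_h, dtype=float),
        fold_change=fc,
        se=np.zeros_like(fc),
        p_vs_control=np.full_like(fc, np.nan),
        n=np.ones(len(fc), dtype=int),
    )


def config_to_json(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    d["times_h"] = list(d["times_h"])
    return d
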