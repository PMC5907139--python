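"""Inference of unknown DUSP-inducing kinases by simulation matching.

For a DUSP whose inducing MAP kinase is unknown (DUSP3, DUSP9, DUSP16,
DUSP23), every non-empty OR-combined subset of {ERK, JNK, p38} is a
candidate induction hypothesis.  Each candidate model is simulated to its
attractor under Herceptin; the DUSP node's trajectory (transient plus one
cycle) is read off as a direction-symbol string and compared to the
experimental pattern descriptor.

Because Boolean time is only ordinally aligned to experimental time, both
symbol strings are run-length compressed (dwell time in a monotone segment
is arbitrary) before computing similarity

    score = 1 − levenshtein(sim, exp) / max(len(sim), len(exp))

with a +0.1 bonus (capped at 1) when the simulated qualitative pattern
class matches the class implied by the experimental string.  Hypotheses
related by the JNK↔p38 symmetry of the scaffold are merged into one
symmetry class; ties are reported jointly, never broken arbitrarily.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import edlib

from .engine import PatternClass, symbol_string
from .models import (
    INFERENCE_TARGETS,
    KINASES,
    UNKNOWN,
    build_model,
    get_regulation_facts,
    simulate_model,
)

__all__ = [
    "InductionHypothesis",
    "AgreementReport",
    "enumerate_hypotheses",
    "score_hypothesis",
    "infer_regulators",
    "edit_similarity",
    "compress_runs",
    "pattern_class_of_symbols",
]

_SWAP = {"JNK": "p38", "p38": "JNK"}


@dataclass(frozen=True)
class InductionHypothesis:
    dusp_id: str
    inducers: frozenset  # non-empty subset of KINASES, OR-combined
    combiner: str = "OR"

    def __post_init__(self):
        if not self.inducers:
            raise ValueError("inducers must be non-empty")

    @property
    def label(self) -> str:
        return "+".join(sorted(self.inducers, key=KINASES.index))

    def swapped(self) -> "InductionHypothesis":
        return InductionHypothesis(
            self.dusp_id,
            frozenset(_SWAP.get(k, k) for k in self.inducers),
            self.combiner,
        )


@dataclass
class AgreementReport:
    hypothesis: InductionHypothesis
    simulated_pattern: str       # compressed symbol string
    simulated_class: str         # PatternClass label of the DUSP node
    experimental_pattern: str    # compressed symbol string
    score: float
    symmetry_class: frozenset = field(default_factory=frozenset)


def enumerate_hypotheses(dusp_id) -> list[InductionHypothesis]:
    """All 7 non-empty inducer subsets, ordered by size then lexicographic
    position (ERK < JNK < p38)."""
    facts = get_regulation_facts(dusp_id)
    if facts.inducers != UNKNOWN:
        raise ValueError(
            f"{facts.dusp_id}: inducers are known; nothing to infer"
        )
    hyps = []
    for size in (1, 2, 3):
        for combo in itertools.combinations(KINASES, size):
            hyps.append(InductionHypothesis(facts.dusp_id, frozenset(combo)))
    return hyps


def compress_runs(s: str) -> str:
    """Collapse consecutive repeated symbols (ordinal-time canonical form)."""
    return re.sub(r"(.)\1+", r"\1", s)


def edit_similarity(a: str, b: str, compress: bool = False) -> float:
    """1 − normalized Levenshtein distance; 1.0 iff the strings match."""
    if compress:
        a, b = compress_runs(a), compress_runs(b)
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def pattern_class_of_symbols(symbols: str) -> str:
    """Qualitative class implied by a direction-symbol string."""
    has_up = "+" in symbols
    has_down = "-" in symbols
    if has_up and has_down:
        return PatternClass.OSCILLATING
    if has_down:
        return PatternClass.ON_THEN_OFF
    if has_up:
        return PatternClass.OFF_THEN_ON
    return PatternClass.CONSTANT_ON


def simulated_signature(dusp_id, inducers) -> tuple[str, str]:
    """(compressed symbol string, PatternClass) of the DUSP node for one
    inducer hypothesis, simulated under Herceptin ON."""
    model = build_model(dusp_id, inducer_hypothesis=set(inducers))
    attractor, classes = simulate_model(model, herceptin=1)
    dusp = model.representative_dusp
    sym = symbol_string(attractor.values(dusp), compress=True)
    return sym, classes[dusp]


def score_hypothesis(
    h: InductionHypothesis, experimental: str, class_bonus: float = 0.1
) -> AgreementReport:
    """Score one hypothesis against an experimental symbol string."""
    sim, sim_class = simulated_signature(h.dusp_id, h.inducers)
    exp = compress_runs(experimental)
    score = edit_similarity(sim, exp)
    if sim_class == pattern_class_of_symbols(exp):
        score = min(1.0, score + class_bonus)
    return AgreementReport(
        hypothesis=h,
        simulated_pattern=sim,
        simulated_class=sim_class,
        experimental_pattern=exp,
        score=score,
    )


def _symmetry_classes(hyps) -> list[frozenset]:
    classes = []
    seen = set()
    for h in hyps:
        if h.inducers in seen:
            continue
        cls = frozenset({h.inducers, h.swapped().inducers})
        seen |= {h.inducers, h.swapped().inducers}
        classes.append(cls)
    return classes


def infer_regulators(
    dusp_id, experimental: str, class_bonus: float = 0.1
) -> list[AgreementReport]:
    """Rank all induction hypotheses against an experimental pattern.

    Members of a JNK↔p38 symmetry class share one report slot set (they are
    dynamically indistinguishable in the scaffold, so their scores coincide
    exactly).  Reports are returned in descending score order, stable within
    ties (enumeration order — size then lexicographic — is preserved).
    """
    hyps = enumerate_hypotheses(dusp_id)
    reports = {h.inducers: score_hypothesis(h, experimental, class_bonus) for h in hyps}
    for cls in _symmetry_classes(hyps):
        members = sorted(cls, key=lambda s: tuple(sorted(s, key=KINASES.index)))
        scores = {reports[m].score for m in members}
        if len(scores) > 1:  # pragma: no cover - guarded by symmetry of scaffold
            raise AssertionError(
                f"symmetry class {members} has unequal scores {scores}"
            )
        for m in members:
            reports[m].symmetry_class = cls
    order = {h.inducers: i for i, h in enumerate(hyps)}
    return sorted(
        reports.values(), key=lambda r: (-r.score, order[r.hypothesis.inducers])
    )


def top_symmetry_classes(reports) -> list[frozenset]:
    """Symmetry classes attaining the maximal score (joint rank 1)."""
    best = max(r.score for r in reports)
    out = []
    for r in reports:
        if r.score == best and r.symmetry_class not in out:
            out.append(r.symmetry_class)
    return out


def report_to_dict(r: AgreementReport) -> dict:
    return {
        "dusp": r.hypothesis.dusp_id,
        "inducers": sorted(r.hypothesis.inducers, key=KINASES.index),
        "symmetry_class": sorted(
            ["+".join(sorted(m, key=KINASES.index)) for m in r.symmetry_class]
        ),
        "simulated_pattern": r.simulated_pattern,
        "simulated_class": r.simulated_class,
        "experimental_pattern": r.experimental_pattern,
        "score": r.score,
    }
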