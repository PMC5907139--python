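"""Per-cluster DUSP regulatory models.

Each modelled DUSP gets a small literature-grounded Boolean scaffold around
the HER2→MAPK axis: Herceptin inhibits HER2; HER2 drives the three MAP
kinases ERK, JNK and p38; the DUSP is transcriptionally induced by the OR of
its inducer kinases and dephosphorylates (``and not DUSP``) its substrate
kinases; apoptosis is triggered by simultaneous JNK and p38 activity, so
``Survival* = not (JNK and p38)``.

A Herceptin-insensitive basal drive (input node ``Basal``, clamped ON) feeds
every substrate kinase.  This keeps each DUSP–kinase negative-feedback loop
engaged after Herceptin shuts HER2 down — without it every loop would
trivially collapse to all-OFF — and, because it is applied uniformly to all
substrates, it preserves the JNK↔p38 symmetry of the scaffold.

Regulation facts (inducers / substrates) follow the literature on MKP
substrate specificity.  For DUSP3, DUSP9, DUSP16 and DUSP23 the inducing
kinase is unknown; building those models requires an explicit inducer
hypothesis (see :mod:`duspboolnet.inference`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .engine import (
    Attractor,
    BooleanNetwork,
    PatternClass,
    classify_node_pattern,
    find_attractor,
    make_initial,
    parse_rules,
)

__all__ = [
    "KINASES",
    "MODELLED_DUSPS",
    "INFERENCE_TARGETS",
    "UNKNOWN",
    "RegulationFacts",
    "ClusterModel",
    "get_regulation_facts",
    "build_model",
    "expected_outcomes",
    "simulate_model",
    "regulation_table",
]

KINASES = ("ERK", "JNK", "p38")

UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class RegulationFacts:
    dusp_id: str
    inducers: frozenset | str  # frozenset of kinases, or UNKNOWN
    substrates: frozenset
    provenance: str  # "known" | "predicted"

    def __post_init__(self):
        if not self.substrates:
            raise ValueError(f"{self.dusp_id}: substrates must be non-empty")


def _facts(dusp, inducers, substrates, provenance):
    ind = UNKNOWN if inducers == UNKNOWN else frozenset(inducers)
    return RegulationFacts(dusp, ind, frozenset(substrates), provenance)


# Literature regulation facts for the eight modelled DUSPs.
_REGULATION = {
    "DUSP1": _facts("DUSP1", {"ERK", "p38"}, {"JNK"}, "known"),
    "DUSP2": _facts("DUSP2", {"ERK", "JNK"}, {"ERK", "p38"}, "known"),
    "DUSP3": _facts("DUSP3", UNKNOWN, {"ERK", "JNK", "p38"}, "predicted"),
    "DUSP4": _facts("DUSP4", {"ERK"}, {"ERK", "JNK"}, "known"),
    "DUSP5": _facts("DUSP5", {"ERK"}, {"ERK"}, "known"),
    "DUSP9": _facts("DUSP9", UNKNOWN, {"ERK"}, "predicted"),
    "DUSP16": _facts("DUSP16", UNKNOWN, {"JNK", "p38"}, "predicted"),
    "DUSP23": _facts("DUSP23", UNKNOWN, {"ERK", "JNK", "p38"}, "predicted"),
}

MODELLED_DUSPS = tuple(_REGULATION)
INFERENCE_TARGETS = tuple(
    d for d, f in _REGULATION.items() if f.inducers == UNKNOWN
)

# Cluster representative mapping (cluster id -> representative DUSP).
CLUSTER_REPRESENTATIVES = {
    1: "DUSP2",
    2: "DUSP9",
    3: "DUSP4",
    4: "DUSP23",
    5: "DUSP5",
    6: "DUSP3",
    7: "DUSP1",
}


def _normalize(dusp_id) -> str:
    if isinstance(dusp_id, int):
        dusp_id = f"DUSP{dusp_id}"
    dusp_id = str(dusp_id).upper().replace("DUSP", "DUSP")
    if not dusp_id.startswith("DUSP"):
        dusp_id = f"DUSP{dusp_id}"
    return dusp_id


def get_regulation_facts(dusp_id) -> RegulationFacts:
    key = _normalize(dusp_id)
    try:
        return _REGULATION[key]
    except KeyError:
        raise KeyError(
            f"{key} is not modelled; modelled DUSPs: {sorted(_REGULATION)}"
        ) from None


@dataclass
class ClusterModel:
    cluster_id: int | str
    representative_dusp: str
    network: BooleanNetwork
    expected: dict = field(default_factory=dict)
    inducers: frozenset = frozenset()
    substrates: frozenset = frozenset()


def _rule_lines(dusp: str, inducers: frozenset, substrates: frozenset) -> str:
    lines = [
        f"# {dusp} regulatory scaffold",
        f"# inducers: {', '.join(sorted(inducers))};"
        f" substrates: {', '.join(sorted(substrates))}",
        "#input: Herceptin Basal",
        "HER2* = not Herceptin",
    ]
    for kinase in KINASES:
        drive = "(HER2 or Basal)" if kinase in substrates else "HER2"
        guard = f" and not {dusp}" if kinase in substrates else ""
        lines.append(f"{kinase}* = {drive}{guard}")
    lines.append(f"{dusp}* = " + " or ".join(sorted(inducers)))
    lines.append("Survival* = not (JNK and p38)")
    return "\n".join(lines) + "\n"


def build_model(dusp_id, inducer_hypothesis=None) -> ClusterModel:
    """Assemble the Boolean scaffold for one DUSP.

    DUSPs with literature-known inducers reject a hypothesis; the four
    inference targets (DUSP3/9/16/23) require a non-empty one.
    """
    facts = get_regulation_facts(dusp_id)
    if facts.inducers == UNKNOWN:
        if not inducer_hypothesis:
            raise ValueError(
                f"{facts.dusp_id}: inducers unknown, an inducer hypothesis "
                "is required"
            )
        inducers = frozenset(inducer_hypothesis)
        bad = inducers - set(KINASES)
        if bad:
            raise ValueError(f"unknown kinase(s) in hypothesis: {sorted(bad)}")
    else:
        if inducer_hypothesis is not None:
            raise ValueError(
                f"{facts.dusp_id}: inducers are known; do not supply a "
                "hypothesis"
            )
        inducers = facts.inducers
    net = parse_rules(_rule_lines(facts.dusp_id, inducers, facts.substrates))
    cluster = next(
        (c for c, rep in CLUSTER_REPRESENTATIVES.items() if rep == facts.dusp_id),
        facts.dusp_id,
    )
    return ClusterModel(
        cluster_id=cluster,
        representative_dusp=facts.dusp_id,
        network=net,
        expected=(
            expected_outcomes(facts.dusp_id)
            if facts.dusp_id in _EXPECTED
            else {}
        ),
        inducers=inducers,
        substrates=facts.substrates,
    )


# Reported qualitative outcomes of the simulations under Herceptin.
_EXPECTED = {
    "DUSP1": {"DUSP1": PatternClass.ON_THEN_OFF, "Survival": PatternClass.CONSTANT_ON},
    "DUSP2": {"DUSP2": PatternClass.OSCILLATING, "Survival": PatternClass.CONSTANT_ON},
    "DUSP4": {"DUSP4": PatternClass.OSCILLATING, "Survival": PatternClass.CONSTANT_ON},
    "DUSP5": {"DUSP5": PatternClass.OSCILLATING, "Survival": PatternClass.CONSTANT_ON},
    "DUSP16": {"Survival": PatternClass.ON_THEN_OFF},
}


def expected_outcomes(dusp_id) -> dict:
    key = _normalize(dusp_id)
    if key not in _REGULATION:
        raise KeyError(f"{key} is not modelled")
    if key not in _EXPECTED:
        raise KeyError(f"no stated qualitative outcome for {key}")
    return dict(_EXPECTED[key])


def simulate_model(
    model: ClusterModel, herceptin: int = 1
) -> tuple[Attractor, dict]:
    """Run the model to its attractor under the given Herceptin clamp.

    The default initial state is all nodes ON: at t = 0 the cells carry
    active HER2 signalling and each measured DUSP sits at its control
    expression level.  Returns the attractor and the pattern class of every
    node.
    """
    clamps = {"Herceptin": herceptin, "Basal": 1}
    init = make_initial(model.network, clamps, default=1)
    attractor = find_attractor(model.network, init, clamps)
    classes = {
        n: classify_node_pattern(attractor, n) for n in model.network.nodes
    }
    return attractor, classes


#: inducer sets used for the shipped rule files of the inference targets
#: (model predictions; regulation only partially known)
PREDICTED_INDUCERS = {
    "DUSP3": frozenset({"JNK"}),
    "DUSP9": frozenset({"JNK"}),
    "DUSP16": frozenset({"ERK"}),
    "DUSP23": frozenset({"JNK"}),
}


def shipped_rule_path(dusp_id):
    """Path of the shipped rule file for one modelled DUSP."""
    from importlib.resources import files

    key = _normalize(dusp_id)
    if key not in _REGULATION:
        raise KeyError(f"{key} is not modelled")
    return files("duspboolnet") / "models" / f"{key.lower()}.bn"


def load_shipped_model(dusp_id) -> BooleanNetwork:
    """Parse the rule file shipped with the package for one DUSP."""
    return parse_rules(shipped_rule_path(dusp_id).read_text(encoding="utf-8"))


def regulation_table():
    """Regulation facts as a tidy DataFrame (for the shipped TSV)."""
    import pandas as pd

    rows = []
    for dusp, f in _REGULATION.items():
        rows.append(
            {
                "dusp": dusp,
                "inducers": (
                    UNKNOWN
                    if f.inducers == UNKNOWN
                    else ",".join(sorted(f.inducers))
                ),
                "substrates": ",".join(sorted(f.substrates)),
                "provenance": f.provenance,
            }
        )
    return pd.DataFrame(rows)
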