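"""DUSP model library: regulation facts, scaffold construction, outcomes."""

import pytest

from duspboolnet.engine import (
    PatternClass,
    classify_node_pattern,
    find_attractor,
    parse_rules,
)
from duspboolnet.models import (
    INFERENCE_TARGETS,
    MODELLED_DUSPS,
    PREDICTED_INDUCERS,
    UNKNOWN,
    build_model,
    expected_outcomes,
    get_regulation_facts,
    load_shipped_model,
    simulate_model,
)

KNOWN = [d for d in MODELLED_DUSPS if d not in INFERENCE_TARGETS]


class TestRegulationFacts:
    def test_dusp2_induced_by_erk_jnk_inhibits_erk_p38(self):
        f = get_regulation_facts("DUSP2")
        assert f.inducers == {"ERK", "JNK"}
        assert f.substrates == {"ERK", "p38"}

    def test_dusp5_erk_loop(self):
        f = get_regulation_facts(5)
        assert f.inducers == {"ERK"} and f.substrates == {"ERK"}

    def test_dusp9_inducers_unknown_substrate_erk(self):
        f = get_regulation_facts("DUSP9")
        assert f.inducers == UNKNOWN
        assert f.substrates == {"ERK"}

    def test_unknown_exactly_for_inference_targets(self):
        assert set(INFERENCE_TARGETS) == {"DUSP3", "DUSP9", "DUSP16", "DUSP23"}
        for d in MODELLED_DUSPS:
            f = get_regulation_facts(d)
            assert (f.inducers == UNKNOWN) == (d in INFERENCE_TARGETS)

    def test_unmodelled_dusp_errors(self):
        with pytest.raises(KeyError):
            get_regulation_facts("DUSP7")


class TestBuildModel:
    def test_hypothesis_for_known_dusp_rejected(self):
        with pytest.raises(ValueError, match="known"):
            build_model("DUSP2", inducer_hypothesis={"ERK"})

    def test_missing_hypothesis_for_unknown_rejected(self):
        with pytest.raises(ValueError, match="hypothesis"):
            build_model("DUSP9")

    def test_empty_hypothesis_rejected(self):
        with pytest.raises(ValueError):
            build_model("DUSP9", inducer_hypothesis=set())

    def test_scaffold_nodes_present(self):
        m = build_model("DUSP2")
        for node in ("Herceptin", "HER2", "ERK", "JNK", "p38", "DUSP2", "Survival"):
            assert node in m.network.nodes

    def test_herceptin_inhibits_her2(self):
        m = build_model("DUSP1")
        assert m.network.rules["HER2"].evaluate({"Herceptin": 1}) == 0
        assert m.network.rules["HER2"].evaluate({"Herceptin": 0}) == 1

    def test_dusp_rule_is_or_of_inducers(self):
        m = build_model("DUSP2")  # induced by ERK or JNK
        r = m.network.rules["DUSP2"]
        assert r.evaluate({"ERK": 1, "JNK": 0}) == 1
        assert r.evaluate({"ERK": 0, "JNK": 1}) == 1
        assert r.evaluate({"ERK": 0, "JNK": 0}) == 0

    def test_survival_is_apoptosis_gate(self):
        m = build_model("DUSP5")
        r = m.network.rules["Survival"]
        assert r.evaluate({"JNK": 1, "p38": 1}) == 0
        for jnk, p38 in ((0, 0), (0, 1), (1, 0)):
            assert r.evaluate({"JNK": jnk, "p38": p38}) == 1


class TestExpectedOutcomes:
    def test_outcome_maps(self):
        assert expected_outcomes("DUSP4") == {
            "DUSP4": PatternClass.OSCILLATING,
            "Survival": PatternClass.CONSTANT_ON,
        }
        assert expected_outcomes("DUSP1")["DUSP1"] == PatternClass.ON_THEN_OFF
        assert expected_outcomes("DUSP16") == {
            "Survival": PatternClass.ON_THEN_OFF
        }

    def test_unmodelled_errors(self):
        with pytest.raises(KeyError):
            expected_outcomes("DUSP7")

    @pytest.mark.parametrize("dusp", KNOWN)
    def test_known_models_reproduce_stated_outcomes(self, dusp):
        m = build_model(dusp)
        _, classes = simulate_model(m, herceptin=1)
        for node, expected in m.expected.items():
            assert classes[node] == expected, (dusp, node)

    def test_dusp16_survival_switches_off(self):
        m = build_model("DUSP16", inducer_hypothesis={"ERK"})
        att, classes = simulate_model(m, herceptin=1)
        assert classes["Survival"] == PatternClass.ON_THEN_OFF
        assert att.transient_length > 0  # finite transient before OFF

    def test_dusp5_oscillates_under_herceptin(self):
        m = build_model("DUSP5")
        _, classes = simulate_model(m, herceptin=1)
        assert classes["DUSP5"] == PatternClass.OSCILLATING


class TestStructuralProperties:
    def test_inhibition_edge_functionally_live(self):
        """Dropping 'and not DUSP5' from ERK's rule kills the oscillation."""
        m = build_model("DUSP5")
        _, classes = simulate_model(m)
        assert classes["ERK"] == PatternClass.OSCILLATING
        pruned = parse_rules(
            m.network.rule_text().replace(" and not DUSP5", "", 1)
        )
        clamps = {"Herceptin": 1, "Basal": 1}
        init = {n: 1 for n in pruned.nodes}
        att = find_attractor(pruned, init, clamps)
        assert classify_node_pattern(att, "ERK") != PatternClass.OSCILLATING

    @pytest.mark.parametrize("dusp", ["DUSP9", "DUSP23"])
    def test_jnk_p38_swap_isomorphism(self, dusp):
        """Swapping JNK and p38 labels leaves the DUSP dynamics unchanged."""
        for hyp in ({"JNK"}, {"p38"}, {"ERK", "JNK"}):
            m = build_model(dusp, inducer_hypothesis=hyp)
            swapped_hyp = {("p38" if k == "JNK" else "JNK" if k == "p38" else k)
                           for k in hyp}
            m2 = build_model(dusp, inducer_hypothesis=swapped_hyp)
            att1, _ = simulate_model(m)
            att2, _ = simulate_model(m2)
            assert att1.values(dusp) == att2.values(dusp)

    def test_drive_free_dusp2_collapses_to_all_off(self):
        """Without any Herceptin-insensitive drive every MAPK node dies."""
        net = parse_rules(
            "#input: Herceptin\n"
            "HER2* = not Herceptin\n"
            "ERK* = HER2 and not DUSP2\n"
            "JNK* = HER2\n"
            "p38* = HER2 and not DUSP2\n"
            "DUSP2* = ERK or JNK\n"
            "Survival* = not (JNK and p38)\n"
        )
        init = {n: 1 for n in net.nodes}
        att = find_attractor(net, init, {"Herceptin": 1})
        for kinase in ("ERK", "JNK", "p38"):
            assert classify_node_pattern(att, kinase) in (
                PatternClass.ON_THEN_OFF,
                PatternClass.CONSTANT_OFF,
            )
            assert att.cycle[0][kinase] == 0 and att.cycle_length == 1


class TestShippedFiles:
    @pytest.mark.parametrize("dusp", MODELLED_DUSPS)
    def test_shipped_rule_file_matches_builder(self, dusp):
        hyp = (
            set(PREDICTED_INDUCERS[dusp]) if dusp in INFERENCE_TARGETS else None
        )
        built = build_model(dusp, inducer_hypothesis=hyp).network
        shipped = load_shipped_model(dusp)
        assert shipped.nodes == built.nodes
        clamps = {"Herceptin": 1, "Basal": 1}
        init = {n: 1 for n in built.nodes}
        a = find_attractor(built, init, clamps)
        b = find_attractor(shipped, init, clamps)
        assert (a.transient, a.cycle) == (b.transient, b.cycle)
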