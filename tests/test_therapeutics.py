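"""Intervention clamping, scenario evaluation, drug classes and screening."""

import math

import pytest

from flydpm.engine import AnalysisConfig, exhaustive_landscape, sampled_landscape
from flydpm.fates import FateProfile, fate_propensities
from flydpm.netio import ClampProfile, parse_fate_classification, parse_network
from flydpm.synthdata import GeneratorSpec, generate_druggability, midgut_demo
from flydpm.therapeutics import (
    Intervention,
    Scenario,
    apply_interventions,
    assess_drug_class,
    evaluate_scenarios,
    parse_scenarios,
    percent_change,
    restrict_druggability,
    screen_combinations,
)


def _profile(p, a, extra=0.0):
    rest = 1.0 - p - a - extra
    return FateProfile({"proliferation": p, "apoptosis": a, "other": extra,
                        "uncharacterized": rest})


# --- apply_interventions ---------------------------------------------------

def test_lof_clamps_zero_gof_clamps_one():
    base = ClampProfile({"EGF": 0.5})
    sc = Scenario("m", [Intervention("mutation_LoF", "Apc2"),
                        Intervention("mutation_GoF", "Ras")])
    out = apply_interventions(base, sc)
    assert out["Apc2"] == 0.0 and out["Ras"] == 1.0 and out["EGF"] == 0.5


def test_later_intervention_wins_on_shared_target():
    base = ClampProfile({})
    sc = Scenario("m", [Intervention("mutation_GoF", "K"),
                        Intervention("drug_inhibit", "K")])
    assert apply_interventions(base, sc)["K"] == 0.0


def test_empty_scenario_is_identity():
    base = ClampProfile({"EGF": 0.25})
    assert apply_interventions(base, Scenario("none")).values == base.values


def test_unknown_target_rejected():
    net = parse_network("A = B\n")
    with pytest.raises(Exception, match="unknown"):
        apply_interventions(ClampProfile({}), Scenario("x", [Intervention("mutation_LoF", "Z")]), net)


def test_apply_idempotent():
    base = ClampProfile({"EGF": 0.5})
    sc = Scenario("m", [Intervention("mutation_LoF", "Apc2")])
    once = apply_interventions(base, sc)
    twice = apply_interventions(once, sc)
    assert once.values == twice.values


# --- percent_change --------------------------------------------------------

@pytest.mark.parametrize(
    "before,after,expected",
    [(0.2, 0.4, 100.0), (0.13, 0.0, -100.0), (0.0, 0.0, 0.0), (0.5, 0.5, 0.0)],
)
def test_percent_change_values(before, after, expected):
    assert percent_change(before, after) == pytest.approx(expected)


def test_percent_change_infinity_sentinel():
    assert math.isinf(percent_change(0.0, 0.1))


# --- scenarios -------------------------------------------------------------

def test_evaluate_scenarios_prepends_control(demo):
    cfg = AnalysisConfig(samples=2_000, seed=31)
    res = evaluate_scenarios(demo.network, demo.normal_clamps,
                             [Scenario("ras", [Intervention("mutation_GoF", "Ras")])],
                             demo.classification, cfg)
    assert list(res) == ["control", "ras"]


def test_control_scenario_equals_plain_da(demo):
    cfg = AnalysisConfig(samples=2_000, seed=31)
    res = evaluate_scenarios(demo.network, demo.normal_clamps, [Scenario("noop")],
                             demo.classification, cfg)
    land = sampled_landscape(demo.network, demo.normal_clamps, cfg)
    plain = fate_propensities(land, demo.classification, node_order=demo.network.nodes)
    assert res["control"].propensities == plain.propensities


def test_mutation_disconnecting_marker_zeroes_fate():
    # LoF of the only path to the apoptosis marker kills that fate exactly
    net = parse_network("INPUT: S\nP = S\nhid = P\n")
    fc = parse_fate_classification("apoptosis\thid=1\n")
    cfg = AnalysisConfig(samples=1_000, seed=2)
    res = evaluate_scenarios(net, ClampProfile({"S": 0.7}),
                             [Scenario("cut", [Intervention("mutation_LoF", "P")])],
                             fc, cfg)
    assert res["control"]["apoptosis"] > 0.5
    assert res["cut"]["apoptosis"] == 0.0


def test_scenario_file_roundtrip():
    scen = parse_scenarios("label\tinterventions\nApcRas\tLoF:Apc2,GoF:Ras\nnone\t\n")
    assert scen[0].label == "ApcRas"
    assert [iv.kind for iv in scen[0].interventions] == ["mutation_LoF", "mutation_GoF"]
    assert scen[1].interventions == []


# --- drug classes ----------------------------------------------------------

def test_class_one_pattern():
    res = assess_drug_class(
        wt_before=_profile(0.130, 0.283), wt_after=_profile(0.130, 0.283),
        mut_before=_profile(0.162, 0.175), mut_after=_profile(0.089, 0.263),
        drug="classone",
    )
    assert res.assigned_class == "I"


def test_class_two_pattern():
    res = assess_drug_class(
        wt_before=_profile(0.130, 0.286), wt_after=_profile(0.191, 0.336),
        mut_before=_profile(0.162, 0.175), mut_after=_profile(0.175, 0.306),
        drug="classtwo",
    )
    assert res.assigned_class == "II"


def test_identical_profiles_indeterminate():
    p = _profile(0.2, 0.3)
    res = assess_drug_class(p, p, p, p)
    assert res.assigned_class == "indeterminate"


def test_fate_set_mismatch_rejected():
    p = _profile(0.2, 0.3)
    q = FateProfile({"proliferation": 1.0})
    with pytest.raises(ValueError, match="fate set"):
        assess_drug_class(p, p, p, q)


# --- screening -------------------------------------------------------------

def test_planted_target_ranks_first(demo):
    drugs = generate_druggability(GeneratorSpec(seed=2), demo.network, planted_target="Ras")
    rep = screen_combinations(demo.network, demo.normal_clamps, drugs,
                              demo.classification, max_size=1,
                              cfg=AnalysisConfig(samples=20_000, seed=3))
    assert rep.best.drugs == ("benefistat",)
    assert rep.best.proliferation_change == pytest.approx(-100.0)
    assert not rep.no_beneficial_target


def test_screen_ranking_invariant_to_row_order(demo):
    from flydpm.netio import DruggabilityTable

    drugs = generate_druggability(GeneratorSpec(seed=2), demo.network, planted_target="Ras")
    reversed_table = DruggabilityTable(list(reversed(drugs.rows)), name="rev")
    cfg = AnalysisConfig(samples=5_000, seed=3)
    a = screen_combinations(demo.network, demo.normal_clamps, drugs,
                            demo.classification, 2, cfg)
    b = screen_combinations(demo.network, demo.normal_clamps, reversed_table,
                            demo.classification, 2, cfg)
    assert [e.drugs for e in a.entries] == [e.drugs for e in b.entries]
    assert [e.score for e in a.entries] == [e.score for e in b.entries]


def test_no_beneficial_target_flag():
    # the only drug activates the proliferation driver: score <= 0
    net = parse_network("INPUT: I\nmyc = I\nhid = NOT I\n")
    fc = parse_fate_classification("apoptosis\thid=1\nproliferation\tmyc=1\n")
    from flydpm.netio import DruggabilityTable, DrugTarget

    drugs = DruggabilityTable([DrugTarget("baddrug", "I", "activate", "direct")])
    rep = screen_combinations(net, ClampProfile({"I": 0.5}), drugs, fc, 1,
                              AnalysisConfig(samples=2_000, seed=5))
    assert rep.no_beneficial_target
    assert all(e.score <= 0 for e in rep.entries)


def test_screen_scores_match_exhaustive_recomputation(demo):
    """Oracle cross-check: recompute each combination's score from exhaustive
    landscapes with hard clamps at the demo corners."""
    drugs = generate_druggability(GeneratorSpec(seed=2), demo.network, planted_target="Ras")
    hard = {n: 1.0 if v >= 0.5 else 0.0 for n, v in demo.normal_clamps.items()}
    cfg = AnalysisConfig(samples=100, seed=1, binarize_threshold=0.5)
    rep = screen_combinations(demo.network, ClampProfile(hard), drugs,
                              demo.classification, 1, cfg, prefer_exhaustive=True)
    from flydpm.therapeutics import interventions_for_drug, _capped

    base_land = exhaustive_landscape(demo.network, {n: int(v) for n, v in hard.items()})
    base = fate_propensities(base_land, demo.classification, node_order=demo.network.nodes)
    for entry in rep.entries:
        clamps = dict(hard)
        for d in entry.drugs:
            for iv in interventions_for_drug(drugs, d):
                clamps[iv.target] = iv.clamp_value
        land = exhaustive_landscape(demo.network, {n: int(v) for n, v in clamps.items()})
        prof = fate_propensities(land, demo.classification, node_order=demo.network.nodes)
        expect = _capped(percent_change(base["apoptosis"], prof["apoptosis"])) - _capped(
            percent_change(base["proliferation"], prof["proliferation"])
        )
        assert entry.score == pytest.approx(expect, abs=1e-9)


def test_restrict_druggability_drops_foreign_targets(isc_net):
    from flydpm import data

    table = data.load_druggability()
    restricted = restrict_druggability(table, isc_net)
    assert "paclitaxel" not in restricted.drugs  # MT_stab only exists post-merge
    assert "trametinib" in restricted.drugs
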