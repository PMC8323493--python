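"""Patient profile parsing, homolog mapping and the end-to-end pipeline."""

import pytest

from flydpm import data
from flydpm.engine import AnalysisConfig
from flydpm.netio import ClampProfile, NetworkFormatError, parse_fate_classification, parse_network
from flydpm.patient import (
    map_to_network,
    parse_patient_profile,
    report_summary_rows,
    run_cohort,
    run_dpm,
)
from flydpm.synthdata import GeneratorSpec, generate_druggability, midgut_demo
from flydpm.therapeutics import percent_change


ROLES = {"KRAS": "oncogene", "APC": "suppressor"}


def test_explicit_effect_column():
    prof = parse_patient_profile("KRAS\tmissense\tGoF\n", patient_id="p1")
    assert prof.mutations[0].effect == "GoF"


def test_effect_inferred_from_role_table():
    prof = parse_patient_profile("APC\ttruncating\n", patient_id="p1", gene_roles=ROLES)
    assert prof.mutations[0].effect == "LoF"


def test_unknown_gene_gets_unknown_effect():
    prof = parse_patient_profile("MYSTERY\tmissense\n", patient_id="p1", gene_roles=ROLES)
    assert prof.mutations[0].effect == "unknown"


def test_bad_variant_class_rejected():
    with pytest.raises(NetworkFormatError, match="variant"):
        parse_patient_profile("KRAS\texplosion\n", patient_id="p1")


def test_empty_patient_file_rejected():
    with pytest.raises(NetworkFormatError, match="empty"):
        parse_patient_profile("# nothing here\n", patient_id="p1")


def test_map_to_network_basics(isc_net):
    prof = parse_patient_profile("KRAS\tmissense\tGoF\n", patient_id="p1")
    ivs, skipped = map_to_network(prof, {"KRAS": "Ras"}, isc_net)
    assert len(ivs) == 1 and ivs[0].target == "Ras" and ivs[0].clamp_value == 1
    assert skipped == []


def test_two_suppressors_collapse_lof_dominates(isc_net):
    text = "G1\ttruncating\tLoF\nG2\tmissense\tGoF\n"
    prof = parse_patient_profile(text, patient_id="p1")
    ivs, _ = map_to_network(prof, {"G1": "Apc2", "G2": "Apc2"}, isc_net)
    assert len(ivs) == 1
    assert ivs[0].kind == "mutation_LoF"  # loss dominates on a shared node


def test_kras_crc_profile_mapping(isc_net):
    prof = data.load_kras_crc_patient()
    assert len(prof.mutations) == 9
    ivs, skipped = map_to_network(prof, data.load_homologs(), isc_net)
    kinds = {iv.target: iv.kind for iv in ivs}
    assert kinds["Ras"] == "mutation_GoF"
    assert kinds["Apc2"] == "mutation_LoF"
    assert set(skipped) == {"TP53", "FBXW7", "SMARCA4"}  # no usable fly homolog
    assert len(ivs) + len(skipped) == 9


def _demo_inputs():
    demo = midgut_demo()
    drugs = generate_druggability(GeneratorSpec(seed=2), demo.network, planted_target="Ras")
    homologs = {"KRAS": "Ras", "APC": "Arm"}
    return demo, drugs, homologs


def test_empty_mutation_list_mutated_equals_control():
    demo, drugs, homologs = _demo_inputs()
    prof = parse_patient_profile("UNKNOWNGENE\tmissense\n", patient_id="nomut")
    rep = run_dpm(demo.network, prof, homologs, drugs, demo.classification,
                  demo.normal_clamps, AnalysisConfig(samples=2_000, seed=9), screen=False)
    assert rep.no_model_relevant_mutations
    assert rep.mutated.propensities == rep.control.propensities


def test_report_percent_changes_recomputable():
    demo, drugs, homologs = _demo_inputs()
    prof = parse_patient_profile("KRAS\tmissense\tGoF\n", patient_id="p-kras")
    rep = run_dpm(demo.network, prof, homologs, drugs, demo.classification,
                  demo.normal_clamps, AnalysisConfig(samples=4_000, seed=9), max_size=2)
    assert rep.screening is not None
    best = rep.screening.best
    assert rep.best_apoptosis_change == percent_change(
        best.before["apoptosis"], best.after["apoptosis"])
    assert rep.best_proliferation_change == percent_change(
        best.before["proliferation"], best.after["proliferation"])


def test_same_seed_reproduces_report():
    demo, drugs, homologs = _demo_inputs()
    prof = parse_patient_profile("KRAS\tmissense\tGoF\n", patient_id="p-kras")
    cfg = AnalysisConfig(samples=2_000, seed=5)
    r1 = run_dpm(demo.network, prof, homologs, drugs, demo.classification,
                 demo.normal_clamps, cfg)
    r2 = run_dpm(demo.network, prof, homologs, drugs, demo.classification,
                 demo.normal_clamps, cfg)
    assert r1.control.propensities == r2.control.propensities
    assert r1.mutated.propensities == r2.mutated.propensities
    assert r1.best_drugs == r2.best_drugs and r1.seed == r2.seed


def test_cohort_order_independent():
    demo, drugs, homologs = _demo_inputs()
    p1 = parse_patient_profile("KRAS\tmissense\tGoF\n", patient_id="p1")
    p2 = parse_patient_profile("APC\ttruncating\tLoF\n", patient_id="p2")
    cfg = AnalysisConfig(samples=2_000, seed=5)
    args = (homologs, drugs, demo.classification, demo.normal_clamps, cfg)
    ab = run_cohort(demo.network, [p1, p2], *args)
    ba = run_cohort(demo.network, [p2, p1], *args)
    assert ab[0].mutated.propensities == ba[1].mutated.propensities
    assert ab[1].mutated.propensities == ba[0].mutated.propensities
    rows = report_summary_rows(ab)
    assert {r["patient"] for r in rows} == {"p1", "p2"}


def test_chemo_extension_enables_taxanes(isc_net):
    ext = data.load_microtubule_extension()
    from flydpm.netio import merge_networks
    from flydpm.therapeutics import restrict_druggability

    merged = merge_networks(isc_net, ext)
    drugs = restrict_druggability(data.load_druggability(), merged)
    assert "paclitaxel" in drugs.drugs
    rep = run_dpm(isc_net, data.load_kras_crc_patient(), data.load_homologs(), drugs,
                  data.load_isc_chemo_fates(), data.load_isc_normal_clamps(),
                  AnalysisConfig(samples=2_000, seed=3),
                  chemo_extension=ext, chemo_base_clamps={"MT_stab": 0.0}, max_size=1)
    assert rep.chemo
    assert rep.screening is not None and rep.best_drugs is not None
    # microtubule stabilization abolishes mitotic competence -> proliferation 0
    taxane = next(e for e in rep.screening.entries if e.drugs == ("paclitaxel",))
    assert taxane.after["proliferation"] == 0.0


def test_oracle_net_report_matches_exhaustive_hand_computation():
    """On a fully hard-clamped toy net the report's propensities must equal
    the exhaustive (enumeration) values exactly."""
    net = parse_network("INPUT: S\nP = S AND NOT D\nD = NOT S\nhid = D\nmyc = P\n")
    fc = parse_fate_classification("apoptosis\thid=1\nproliferation\tmyc=1\n")
    from flydpm.netio import DruggabilityTable, DrugTarget

    drugs = DruggabilityTable([DrugTarget("blocker", "P", "inhibit", "direct")])
    prof = parse_patient_profile("ONC\tmissense\tGoF\n", patient_id="toy")
    rep = run_dpm(net, prof, {"ONC": "S"}, drugs, fc,
                  ClampProfile({"S": 0.0}), AnalysisConfig(samples=3_000, seed=8), max_size=1)
    # control: S clamped 0 -> D=1 -> apoptosis; mutated: S=1 -> P=1 -> proliferation
    assert rep.control["apoptosis"] == 1.0
    assert rep.mutated["proliferation"] == 1.0
    blocker = next(e for e in rep.screening.entries if e.drugs == ("blocker",))
    assert blocker.after["proliferation"] == 0.0
    assert blocker.proliferation_change == -100.0
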