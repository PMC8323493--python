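"""End-to-end personalized run: mutations -> homologs -> therapy screen.

Loads a KRAS-mutant colorectal-cancer mutation profile (eight tumor
suppressors + oncogenic KRAS), maps it onto the fly model through the
homolog table (three genes have no usable homolog and are reported, not
silently dropped), merges the microtubule sub-network so taxane
chemotherapy is representable, and screens drug pairs on top of the mutated
model."""

from flydpm import AnalysisConfig, merge_networks
from flydpm import data
from flydpm.patient import run_dpm
from flydpm.therapeutics import restrict_druggability

net = data.load_isc_network()
ext = data.load_microtubule_extension()
drugs = restrict_druggability(data.load_druggability(), merge_networks(net, ext))

report = run_dpm(
    net, data.load_kras_crc_patient(), data.load_homologs(), drugs,
    data.load_isc_chemo_fates(), data.load_isc_normal_clamps(),
    AnalysisConfig(samples=10_000, seed=21),
    chemo_extension=ext, chemo_base_clamps={"MT_stab": 0.0}, max_size=2,
)

print(f"patient: {report.patient_id}")
print(f"interventions: " + ", ".join(f"{iv.target}={iv.clamp_value}" for iv in report.interventions))
print(f"unmapped genes (no fly homolog): {', '.join(report.skipped_genes)}")
print(f"\n{'':12s}{'apoptosis':>12s}{'proliferation':>15s}")
print(f"{'control':12s}{report.control['apoptosis']:12.3f}{report.control['proliferation']:15.3f}")
print(f"{'mutated':12s}{report.mutated['apoptosis']:12.3f}{report.mutated['proliferation']:15.3f}")
best = report.screening.best
print(f"{'best therapy':12s}{best.after['apoptosis']:12.3f}{best.after['proliferation']:15.3f}")
print(f"\nbest therapy: {' + '.join(best.drugs)} "
      f"(proliferation change {best.proliferation_change:.0f}%)")
if report.targeted_therapy_only:
    print("a single targeted drug already abolishes proliferation; no "
          "combination needed")
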