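"""Single-drug screening against a planted beneficial target.

On the teaching fixture, the synthetic druggability table plants one drug
(benefistat) that inhibits the proliferation driver Ras.  The screen
applies each drug on top of the baseline clamps, measures apoptosis and
proliferation percent changes, and ranks by
score = capped(apoptosis %) - capped(proliferation %)."""

from flydpm import AnalysisConfig, screen_combinations
from flydpm.synthdata import GeneratorSpec, generate_druggability, midgut_demo

demo = midgut_demo()
drugs = generate_druggability(GeneratorSpec(seed=2), demo.network, planted_target="Ras")
report = screen_combinations(demo.network, demo.normal_clamps, drugs,
                             demo.classification, max_size=1,
                             cfg=AnalysisConfig(samples=20_000, seed=13))

print(f"{'rank':>4s}  {'drug':12s}{'score':>8s}{'d_apoptosis%':>14s}{'d_prolif%':>12s}")
for i, entry in enumerate(report.entries, start=1):
    print(f"{i:4d}  {'+'.join(entry.drugs):12s}{entry.score:8.1f}"
          f"{entry.apoptosis_change:14.1f}{entry.proliferation_change:12.1f}")
print("\nThe planted Ras inhibitor abolishes proliferation (-100%) while "
      "raising apoptosis, so it tops the ranking.")
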