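"""Input-perturbation robustness of cell-fate programming.

Perturbs the normal input clamps of the teaching fixture by +/-10%
(multiplicative, uniform), re-samples the landscape per replicate and
reports per-fate SEM across replicates.  Small SEMs mean the network keeps
programming the same fates under input noise — the plausibility check
applied to each cell-type model."""

from flydpm import AnalysisConfig
from flydpm.robustness import robustness_analysis
from flydpm.synthdata import midgut_demo

demo = midgut_demo()
report = robustness_analysis(
    demo.network, demo.normal_clamps, demo.classification,
    AnalysisConfig(samples=10_000, replicates=30, seed=11), fraction=0.1,
)

print(f"{'fate':18s}{'baseline':>10s}{'mean':>10s}{'SD':>10s}{'SEM':>10s}")
for row in report.to_rows():
    print(f"{row['fate']:18s}{row['baseline']:10.3f}{row['mean']:10.3f}"
          f"{row['sd']:10.4f}{row['sem']:10.4f}")
print(f"\nhighest-variation fate: {report.max_sem_fate} "
      f"(SEM {report.sem[report.max_sem_fate]:.4f}) — "
      "fates with SEM near zero are robust to 10% input noise.")
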