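"""Cell-fate propensities of the bundled stem-cell model under three
ambient conditions.

Loads the 48-node / 70-edge intestinal-stem-cell reconstruction, clamps its
nine input stimuli at normal, stress and cancer levels, and prints the
per-fate propensities.  Probabilistic clamps mean each sampled trajectory
draws its inputs ON with the clamp probability, so propensities respond
continuously to input levels."""

from flydpm import AnalysisConfig, compile_network, fate_propensities, sampled_landscape
from flydpm import data

net = data.load_isc_network()
cn = compile_network(net)
fates = data.load_isc_fates()
normal = data.load_isc_normal_clamps()
conditions = {
    "normal": normal,
    "stress": normal.updated(data.load_isc_stress_overrides(), name="stress"),
    "cancer": normal.updated(data.load_isc_cancer_overrides(), name="cancer"),
}

profiles = {}
for label, clamps in conditions.items():
    land = sampled_landscape(cn, clamps, AnalysisConfig(samples=10_000, seed=7))
    profiles[label] = fate_propensities(land, fates, node_order=net.nodes)

header = f"{'fate':18s}" + "".join(f"{c:>10s}" for c in conditions)
print(header)
for fate in fates.fate_names:
    row = f"{fate:18s}" + "".join(f"{profiles[c][fate]:10.3f}" for c in conditions)
    print(row)
print("\nEach column sums to 1: the attractor basins partition the sampled "
      "state space, so fates are exclusive propensities.")
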