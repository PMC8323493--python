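# Stress-condition overrides (synthetic): stimuli perturbed away from the
# normal profile — elevated stress ligands and cytokines.
node	value
ROS	0.6
Egr	0.5
Upd	0.7
EGF	0.6
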