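# Normal-condition input clamps for the ISC reconstruction (synthetic,
# expression-flavored resting levels; regenerate from an expression table via
# flydpm.annotation.derive_input_clamps).
node	value
EGF	0.5
Wg	0.4
Dpp	0.5
Upd	0.4
Dl_ext	0.5
Ilp	0.6
Egr	0.2
Slit	0.3
ROS	0.1
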