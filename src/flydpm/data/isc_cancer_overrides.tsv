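# Cancer-condition overrides (synthetic): oncogenic microenvironment with
# WNT and EGFR stimulation up, BMP down, oxidative stress high.
node	value
Wg	1.0
EGF	1.0
ROS	0.7
Dpp	0.2
Ilp	0.8
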