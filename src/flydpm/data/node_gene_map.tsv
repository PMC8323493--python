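# Network node -> fly gene symbol map for expression annotation.
# ROS is a physiological stimulus, not a gene product: supply it via a
# condition override when deriving clamps.
node	gene
EGF	spi
Wg	wg
Dpp	dpp
Upd	upd1
Dl_ext	Dl
Ilp	Ilp2
Egr	egr
Slit	sli
Apc2	Apc2
Cdc42	Cdc42
hid	hid
SuH	Su_H
pros	pros
dlg1	dlg1
Stat92E	Stat92E
rl	rl
pan	pan
myc	Myc
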