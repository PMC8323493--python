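# Cell-fate classification for the ISC reconstruction (synthetic curation).
# File order is match priority; attractors matching no row are
# "uncharacterized".
fate	markers
apoptosis	hid=1
proliferation	rl=1,myc=1
EB_fate	SuH=1
EE_fate	pros=1
delta_production	Dl=1
loss_of_polarity	dlg1=0,Cdc42=1
multilayering	Yki=1,dlg1=0
extrusion	Mmp1=1
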