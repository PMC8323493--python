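# Druggability table (synthetic curation of PanDrugs-style lookups).
# Targets referencing MT_stab exist only in the microtubule-merged network;
# use flydpm.therapeutics.restrict_druggability to subset for a network.
drug	target	action	mode	note
trametinib	Dsor1	inhibit	direct	MEK kinase inhibitor
zoledronate	Ras	inhibit	indirect	blocks prenylation-dependent Ras membrane anchoring
regorafenib	Raf	inhibit	direct	multi-kinase inhibitor
imatinib	Abl	inhibit	direct	Abl kinase inhibitor
bortezomib	Yki	inhibit	indirect	proteasome inhibition destabilizes pro-growth effectors
bortezomib	foxo	activate	indirect	proteasome inhibition stabilizes foxo
everolimus	Akt1	inhibit	indirect	mTOR-axis inhibition
paclitaxel	MT_stab	activate	direct	stabilizes polymerized microtubules
docetaxel	MT_stab	activate	direct	taxane microtubule stabilizer
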