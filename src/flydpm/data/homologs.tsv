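# Human gene -> fly network node homolog map (synthetic curation; genes with
# no usable homolog in the reconstruction are deliberately absent and will be
# reported as unmapped).
human_gene	fly_node
KRAS	Ras
BRAF	Raf
EGFR	Egfr
APC	Apc2
CTNNB1	Arm
TGFBR2	Tkv
FAT4	Ex
MAPK14	Hep
CDH1	dlg1
MYC	myc
PIK3CA	Pi3K
AKT1	Akt1
STAT3	Stat92E
ABL1	Abl
SMAD4	Mad
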