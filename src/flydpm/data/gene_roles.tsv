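# Oncogene / tumor-suppressor roles used to infer mutation effects
# (oncogene -> gain of function, suppressor -> loss of function).
gene	role
KRAS	oncogene
BRAF	oncogene
EGFR	oncogene
MYC	oncogene
PIK3CA	oncogene
AKT1	oncogene
STAT3	oncogene
ABL1	oncogene
CTNNB1	oncogene
APC	suppressor
TP53	suppressor
FBXW7	suppressor
TGFBR2	suppressor
SMARCA4	suppressor
FAT4	suppressor
MAPK14	suppressor
CDH1	suppressor
SMAD4	suppressor
PTEN	suppressor
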