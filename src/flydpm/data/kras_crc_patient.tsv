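# KRAS-mutant CRC mutation profile (literature-derived gene list; variant
# classes are representative).  Eight tumor suppressors plus one oncogenic
# KRAS mutation.
patient	KRAS-CRC-01
gene	variant_class
APC	truncating
TP53	missense
FBXW7	truncating
TGFBR2	truncating
SMARCA4	truncating
FAT4	truncating
MAPK14	truncating
CDH1	truncating
KRAS	missense
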