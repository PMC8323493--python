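# Long name -> network symbol aliases (FlyBase-style).
alias	symbol
adenomatous polyposis coli 2	Apc2
head involution defective	hid
suppressor of hairless	SuH
Su(H)	SuH
prospero	pros
discs large 1	dlg1
signal-transducer and activator of transcription protein at 92E	Stat92E
rolled	rl
pangolin	pan
dMyc	myc
armadillo	Arm
shaggy	Sgg
yorkie	Yki
basket	Bsk
downstream of raf1	Dsor1
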