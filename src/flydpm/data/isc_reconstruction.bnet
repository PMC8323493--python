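# ISC network reconstruction (synthetic).
#
# A 48-node / 70-edge Boolean model of intestinal-stem-cell signaling in the
# Drosophila midgut, wired from the core vocabulary of the nine pathways that
# govern midgut homeostasis: Notch, BMP (Dpp), EGFR, WNT (Wg), JAK-STAT
# (Upd), JNK, Hippo, Insulin and Robo/Slit.  The exact curated rules of the
# published midgut models are not redistributed here; this file is a
# documented reconstruction with the same structural counts and the same
# input / output vocabulary, intended for testing and demonstration.  Supply
# your own curated rule file to analyze a different model.
#
# Inputs are the pathway ligands/stimuli; outputs follow the ten ISC readout
# nodes (Apc2, Cdc42, hid, Su(H) [SuH], pros, dlg1, Stat92E, rl, pan, myc).

INPUT: EGF Wg Dpp Upd Dl_ext Ilp Egr Slit ROS
OUTPUT: Apc2 Cdc42 hid SuH pros dlg1 Stat92E rl pan myc

# EGFR cascade
Egfr = EGF
Ras = Egfr
Raf = Ras
Dsor1 = Raf
rl = Dsor1

# WNT cascade
Fz = Wg
Dsh = Fz
Sgg = NOT Dsh AND NOT Akt1
Apc2 = NOT Dsh
Arm = Dsh AND NOT Sgg AND NOT Apc2
pan = Arm

# Notch (with cis-inhibition by the cell's own Delta)
N = Dl_ext AND NOT Dl
SuH = N

# JAK-STAT
Dome = Upd
Hop = Dome
Stat92E = Hop

# BMP (JNK antagonizes Mad)
Tkv = Dpp
Mad = Tkv AND NOT Bsk

# JNK stress cascade
Tak1 = Egr OR ROS
Hep = Tak1
Bsk = Hep OR Abl
Jra = Bsk

# Hippo (polarity-activated; Yki-driven growth displaces apical Ex)
Ex = dlg1 AND NOT Yki
Hpo = Ex OR Tak1
Wts = Hpo OR Ex
Yki = NOT Wts AND NOT Sgg

# Insulin (foxo feedback on the receptor)
InR = Ilp AND NOT foxo
Pi3K = InR OR Ras
Akt1 = Pi3K
foxo = NOT Akt1 OR Bsk

# Robo/Slit
Robo2 = Slit
Abl = Robo2

# Effectors / fate markers
hid = (foxo OR Jra OR ROS) AND NOT rl AND NOT Yki
Dl = (rl OR Yki OR Stat92E) AND NOT SuH
Mmp1 = Jra OR Yki
myc = (pan OR Yki OR Stat92E OR Mad) AND NOT foxo
dlg1 = NOT Bsk AND NOT Abl AND NOT Mmp1
Cdc42 = Abl OR Egfr
pros = NOT SuH AND NOT rl AND Mad
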