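# Microtubule sub-network extension (synthetic reconstruction).
#
# Adds 6 nodes and 13 interactions to the ISC reconstruction so that
# taxane-style chemotherapy can be modeled: stabilizing polymerized
# microtubules (MT_stab, a rule-less input that the chemo drug clamps ON)
# blocks mitotic progression (CycB / stg) and promotes apoptosis.
# MT_stab must be clamped to 0 in the resting (no-chemo) condition.

alphaTub = myc
betaTub = myc
MT_poly = alphaTub AND betaTub
CycB = (rl OR Stat92E) AND NOT foxo AND NOT MT_stab
stg = CycB AND MT_poly AND rl AND NOT MT_stab
OVERRIDE OR hid = MT_stab
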