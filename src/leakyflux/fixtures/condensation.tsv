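# Condensation/cleavage toy: A (2C) + B (1C) -> C (3C) -> D (2C) + E (1C),
# with every intermediate exported to its own pool.
@source X Y
@pool PC PD PE
f1	X (ab) -> A (ab)
f2	Y (c) -> B (c)
cond	A (ab) + B (c) -> C (abc)
cleave	C (abc) -> D (ab) + E (c)
expC	C (abc) -> PC (abc)
expD	D (ab) -> PD (ab)
expE	E (c) -> PE (c)
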