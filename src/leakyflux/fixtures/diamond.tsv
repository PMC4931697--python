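# Diamond branch: two routes from A to D, one of which swaps the atom
# order, so the D pool mixes the two labelling patterns flux-weighted.
@source S
@pool P
in	S (ab) -> A (ab)
b1	A (ab) -> B (ab)
b2	A (ab) -> C (ba)
c1	B (ab) -> D (ab)
c2	C (ab) -> D (ab)
out	D (ab) -> P (ab)
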