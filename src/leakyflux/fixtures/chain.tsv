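# Pass-through chain: source -> A -> B -> accumulating pool.
@source S
@pool P
upt	S (ab) -> A (ab)
conv	A (ab) -> B (ab)
exp	B (ab) -> P (ab)
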