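# Central-carbon network around the pyruvate node: glycolysis, oxidative
# PPP (C1 lost as CO2, pentose exported to biosynthesis), lactate
# dehydrogenase, reversible lactate and pyruvate exchange with the medium,
# mitochondrial pyruvate transport, TCA cycle, glutamine entry (lumping all
# non-glucose carbon sources) and cytoplasmic malic enzyme.  This network is
# a documented reconstruction, not a published reaction list.
@source GLC_x GLN_x CO2
@pool LAC_x PYR_x
@symmetric SUC FUM
@normalize HK
HK	GLC_x (abcdef) -> G6P (abcdef)
PPP	G6P (abcdef) -> CO2 (a) + P5P (bcdef)
P5PX	P5P (abcde) ->
EMP	G6P (abcdef) -> PEP (cba) + PEP (def)
PK	PEP (abc) -> PYR_c (abc)
LDH	PYR_c (abc) <-> LAC_c (abc)
LACX	LAC_c (abc) <-> LAC_x (abc)
PYRX	PYR_c (abc) <-> PYR_x (abc)
PT	PYR_c (abc) -> PYR_m (abc)
PDH	PYR_m (abc) -> CO2 (a) + ACCOA (bc)
CS	OAA (abcd) + ACCOA (ef) -> CIT (dcbfea)
IDH	CIT (abcdef) -> AKG (abcde) + CO2 (f)
AKGDH	AKG (abcde) -> SUC (bcde) + CO2 (a)
SDH	SUC (abcd) -> FUM (abcd)
FH	FUM (abcd) -> MAL (abcd)
MDH	MAL (abcd) -> OAA (abcd)
ME1	MAL (abcd) -> PYR_c (abc) + CO2 (d)
GLS	GLN_x (abcde) -> AKG (abcde)
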