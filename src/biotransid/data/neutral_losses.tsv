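# Neutral-loss fragments (NLFs): precursor-minus-fragment mass differences
# evidencing a conjugate or substituent. delta is a formula or a literal Da
# value; radical losses (odd-electron) are flagged.
# label	delta	radical_allowed
glucuronyl	C6H8O6	0
sulfo	SO3	0
sulfate	SO4	0
water	H2O	0
carbon-monoxide	CO	0
carbon-dioxide	CO2	0
formaldehyde	CH2O	0
methylene	CH2	0
methyl	CH3	1
butene	C4H8	0
butenyl	C4H7	1
pentadiene	C5H8	0
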