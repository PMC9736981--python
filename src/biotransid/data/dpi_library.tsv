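# Diagnostic product ions (DPIs). A target is either a literal m/z (matched
# within an absolute Da tolerance; the literature prints fragments at two
# decimals) or an ion formula (matched within a ppm tolerance).
# label	target	mode	tolerance	context
glua-175	175.02	da	0.01	glucuronide
glua-113	113.02	da	0.01	glucuronide
bisulfate-97	96.96	da	0.01	sulfate
sulfite-80	79.96	da	0.01	sulfate
rda-neg-135	135.01	da	0.01	core
rda-pos-137	137.02	da	0.01	core
core-minus-c4h8	265.05	da	0.01	core
core-minus-c5h8	253.05	da	0.01	core
aglycone-anion	C20H17O4	ppm	10	conjugate
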