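# Default biotransformation library (phase I functionalization and phase II
# conjugation) for isoflavone metabolism. Columns:
# name	label	add	remove	phase	max_multiplicity
demethylation	M-CH2	-	CH2	I	1
methylation	M+CH2	CH2	-	II	1
hydroxylation	M+O	O	-	I	3
dehydrogenation	M-H2	-	H2	I	1
reduction	M+H2	H2	-	I	1
hydration	M+H2O	H2O	-	I	1
decarbonylation	M-CO	-	CO	I	1
decarbonylation-hydrogenation	M-CO+H2	H2	CO	I	1
deoxygenation-reduction	M-O+H2	H2	O	I	1
glucuronidation	M+C6H8O6	C6H8O6	-	II	2
sulfation	M+SO3	SO3	-	II	2
N-acetylcysteine conjugation	M+C5H7NO3S	C5H7NO3S	-	II	1
sulfation-reduction	M+SO3+H2	H2O3S	-	II	1
sulfation-deoxygenation-reduction	M+SO3-O+H2	H2O3S	O	II	1
sulfation-dideoxygenation-reduction	M+SO3-O2+H2	H2O3S	O2	II	1
sulfation-dideoxygenation-direduction	M+SO3-O2+H4	H4O3S	O2	II	1
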