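# Monoisotopic atomic masses (Da), fixed so golden tests are bit-stable.
# symbol	mass
C	12.0
H	1.00782503
N	14.00307401
O	15.99491462
S	31.97207117
e-	0.00054858
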