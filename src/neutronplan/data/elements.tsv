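# symbol	Z	A_r (g/mol, CODATA/IUPAC standard atomic weights, 5 significant digits)
H	1	1.0080
C	6	12.011
N	7	14.007
O	8	15.999
F	9	18.998
Na	11	22.990
Mg	12	24.305
Al	13	26.982
Si	14	28.085
P	15	30.974
S	16	32.060
Cl	17	35.450
Ar	18	39.948
K	19	39.098
Ca	20	40.078
Fe	26	55.845
I	53	126.90
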