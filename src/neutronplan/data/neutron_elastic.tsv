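# Elastic scattering cross-section anchors, free-atom values.
# elem	E_eV	sigma_barn
# Smooth log-log interpolation between anchors; resonances are deliberately
# omitted (parametric stand-in, see PROVENANCE.md).
H	1.0e-3	20.4
H	1.0e3	20.4
H	1.0e4	19.8
H	1.0e5	13.0
H	1.0e6	4.26
H	2.0e6	2.90
H	5.0e6	1.53
H	1.0e7	0.94
H	2.2e7	0.45
C	1.0e-3	4.75
C	1.0e5	4.60
C	1.0e6	2.60
C	5.0e6	1.20
C	2.2e7	1.00
N	1.0e-3	10.0
N	1.0e5	8.00
N	1.0e6	2.40
N	5.0e6	1.10
N	2.2e7	0.95
O	1.0e-3	3.85
O	1.0e5	3.80
O	1.0e6	3.20
O	5.0e6	1.30
O	2.2e7	0.90
F	1.0e-3	3.64
F	1.0e5	3.60
F	1.0e6	3.00
F	5.0e6	1.80
F	2.2e7	1.20
Na	1.0e-3	3.28
Na	1.0e5	3.20
Na	1.0e6	3.00
Na	5.0e6	2.00
Na	2.2e7	1.50
Mg	1.0e-3	3.42
Mg	1.0e5	3.40
Mg	1.0e6	2.60
Mg	5.0e6	1.90
Mg	2.2e7	1.60
Al	1.0e-3	1.41
Al	1.0e5	2.50
Al	1.0e6	2.40
Al	5.0e6	2.00
Al	2.2e7	1.60
Si	1.0e-3	2.04
Si	1.0e5	2.70
Si	1.0e6	2.80
Si	5.0e6	2.20
Si	2.2e7	1.70
P	1.0e-3	3.31
P	1.0e5	3.30
P	1.0e6	3.00
P	5.0e6	2.30
P	2.2e7	1.70
S	1.0e-3	1.02
S	1.0e5	2.20
S	1.0e6	2.60
S	5.0e6	2.30
S	2.2e7	1.70
Cl	1.0e-3	15.8
Cl	1.0e5	4.00
Cl	1.0e6	2.80
Cl	5.0e6	2.40
Cl	2.2e7	1.80
Ar	1.0e-3	0.65
Ar	1.0e5	1.50
Ar	1.0e6	2.50
Ar	5.0e6	2.50
Ar	2.2e7	1.80
K	1.0e-3	1.96
K	1.0e5	2.50
K	1.0e6	2.60
K	5.0e6	2.40
K	2.2e7	1.80
Ca	1.0e-3	2.83
Ca	1.0e5	3.00
Ca	1.0e6	1.80
Ca	5.0e6	2.30
Ca	2.2e7	1.90
Fe	1.0e-3	11.35
Fe	1.0e5	6.00
Fe	1.0e6	2.80
Fe	5.0e6	3.20
Fe	2.2e7	2.60
I	1.0e-3	3.60
I	1.0e5	4.50
I	1.0e6	4.50
I	5.0e6	4.00
I	2.2e7	2.80
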