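# Radiative-capture data: 2200 m/s (0.0253 eV) cross section, 1/v extrapolated
# over the whole grid; Q = total capture gamma energy (neutron separation
# energy of the A+1 compound nucleus). See PROVENANCE.md.
# elem	sigma_2200_barn	Q_MeV
H	0.3326	2.2246
C	0.00353	4.946
N	0.0750	10.833
O	0.00019	4.143
F	0.0096	6.601
Na	0.530	6.959
Mg	0.063	7.331
Al	0.231	7.725
Si	0.171	8.474
P	0.172	7.935
S	0.530	8.642
Cl	33.5	8.580
Ar	0.675	6.099
K	2.10	7.800
Ca	0.430	8.363
Fe	2.56	7.646
I	6.20	6.826
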