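# Provenance of packaged physical data

## elements.tsv
CODATA/IUPAC standard atomic weights, rounded to 5 significant digits.

## materials.tsv
- Water, Perspex (PMMA, C5O2H8, 1.19 g/cm3), aluminum: standard handbook
  values.
- Concrete: NIST "ordinary concrete" elemental mass fractions, 2.30 g/cm3.
- Air: NIST dry air near sea level, 1.2048e-3 g/cm3.
- Tissue materials: ICRU Report 44 / ICRP Publication 89 style elemental mass
  fractions and densities. These tables are a reasonable reconstruction, not a
  copy of any proprietary phantom's material file. They reproduce the spot
  values the planning workflow relies on:
    - adipose tissue: H mass fraction 0.114 -> H atom fraction 62.5%
    - water: H atom fraction 66.7%
    - cortical bone: H mass fraction 0.035
  The salivary-gland material uses the ICRU average-soft-tissue composition.

## neutron_elastic.tsv / neutron_capture.tsv
Smooth parametric stand-in for an evaluated neutron library. Elastic anchors
are free-atom point values read off standard evaluated-data plots (e.g.
sigma_el(H) ~ 20.4 b thermal, 4.26 b at 1 MeV, 0.94 b at 10 MeV); log-log
interpolation between anchors, resonances omitted. Capture is 1/v from the
2200 m/s value. Capture Q-values are neutron separation energies of the
compound nucleus (H: 2.2246 MeV deuteron binding energy). Thermal molecular
binding (S(alpha,beta)) is not modelled; a 300 K free-gas target-motion model
is used below 4 eV instead.

## Photon interaction model (in code, physics.py)
- Compton: analytic Klein-Nishina per electron, times Z per atom.
- Photoelectric: parametric sigma = 1.26e-8 * Z^4.5 / E_MeV^3 barn per atom,
  anchored so that the water photoelectric attenuation at 10 keV matches the
  NIST XCOM value (~4.9 cm^2/g).
- Pair production: sigma = 1.25e-3 * Z^2 * ln(E / 2 m_e c^2) barn per atom
  above threshold, anchored to the oxygen value near 10 MeV.
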