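# neutronplan

A voxel Monte Carlo dose engine and treatment-planning toolkit for a
fission-spectrum fast-neutron therapy beam, of the kind delivered at a
reactor-based medical irradiation facility (converter-plate beam, total
neutron fluence rate 3.2·10⁸ cm⁻²s⁻¹ and photon fluence rate
2.9·10⁸ cm⁻²s⁻¹ at the patient position, 9 × 9 cm² reference field).

It is aimed at medical physicists and radiation-transport developers who
want a self-contained, inspectable implementation of the first steps of a
fast-neutron planning system: from a binned source spectrum, through
particle transport in water and anthropomorphic voxel phantoms, to the
planning outputs — depth-dose curves, lateral profiles, dose-volume
histograms (DVH), RBE-weighted doses and isodose contours.

## What it computes

**Transport.** Analog (weight-1) histories with one counter-seeded RNG
stream per history. Neutrons undergo isotropic-in-centre-of-mass elastic
scattering, with E′ = E[(1+α) + (1−α)μ_cm]/2, α = ((A−1)/(A+1))², a 300 K
free-gas target-motion model below 4 eV, and 1/v radiative capture;
capture on hydrogen emits the 2.2246 MeV deuteron-binding gamma. Photons
undergo Klein–Nishina Compton scattering, parametric photoelectric
absorption and pair production. Charged secondaries are not tracked: their
kinetic energy deposits at the interaction site (kerma approximation),
tagged by depositing particle ("proton", "neutron", "electron"), which
yields the per-particle dose separation. Free flights are sampled exactly
across material boundaries by optical-depth accumulation (surface
tracking); Woodcock delta tracking is available as an option.

**Scoring.** History-by-history tallies: for each scoring region and
particle tag the sum and sum of squares of the per-history deposit give
the mean dose per unit primary planar fluence (Gy·cm²) and its standard
error, s_mean = √[(Σx²/n − (Σx/n)²)/(n−1)] / m. Absolute dose rates follow
by multiplying with the facility fluence rate, absolute doses by the
irradiation time. A 58-bin track-length estimator scores the moderated
neutron fluence spectrum per region.

**Geometries.** (1) A solid water phantom: Perspex box
63.5 × 63.5 × 52 cm³ with 2 cm walls, a 12 × 34 cm² entrance window sealed
by two 1.5 mm aluminum plates, and 40 water-equivalent cylindrical
chambers (r = 0.38 cm, h = 1.21 cm, 0.54 cm³) every centimetre from 0.5 to
39.5 cm depth. (2) The same phantom voxelised (enlarged to 64 × 64 × 52 cm³
so that 0.2 × 0.2 × 0.5 cm³ voxels divide it exactly — 10 649 600 voxels),
scored in 8-voxel (0.16 cm³) blocks on the beam axis. (3) Anthropomorphic
voxel phantoms with organ→material projection onto ~30 ICRU/ICRP-style
tissue materials, either loaded from file or generated by the built-in
synthetic head/neck phantom (six labelled salivary-gland ROIs). An optional
schematic concrete treatment room (83 cm walls, 50 cm beam-entry wall,
20 × 30 cm² window) can surround the phantom.

## Worked example

```python
import neutronplan as npl
from neutronplan.transport import TransportConfig, run
from neutronplan.tallies import finalize_dose, to_dose_rate, to_absolute

spectrum = npl.synthetic_medapp_spectrum("neutron", total_rate=3.2e8)
beam = npl.BeamConfig(9.0, 9.0, neutron_spectrum=spectrum)
geometry = npl.build_solid_water_geometry()

result = run(TransportConfig(n_histories=200_000, seed=42), beam, geometry)
dose = finalize_dose(result)
neutron, err = dose.tagged("proton", "neutron")   # twin-chamber "neutron dose"
rate = to_dose_rate(neutron, 3.2e8)               # Gy/s at the facility rate

depths = geometry.chambers.depths
for i in (0, 4, 9, 19):
    print(f"depth {depths[i]:5.1f} cm : {rate[i]:.3e} Gy/s "
          f"(+- {100 * err[i] / neutron[i]:.1f}%)")
print(f"dose after 3 min at 0.5 cm: {to_absolute(rate[0], 180):.3f} Gy")
```

prints

```
depth   0.5 cm : 9.640e-03 Gy/s (+- 8.1%)
depth   4.5 cm : 6.132e-03 Gy/s (+- 9.9%)
depth   9.5 cm : 1.915e-03 Gy/s (+- 16.7%)
depth  19.5 cm : 6.310e-04 Gy/s (+- 32.6%)
dose after 3 min at 0.5 cm: 1.735 Gy
```

i.e. a surface neutron dose rate near 10 mGy/s that falls by roughly a
factor five over the first ten centimetres of water — a typical 2 Gy
fraction takes a few minutes of beam time — with one-standard-deviation
Monte Carlo errors from the history-by-history variance.

The same engine drives the anthropomorphic case (6 × 7 cm² field on the
right submandibular gland of the synthetic head phantom), after which
`cumulative_dvh`, `apply_rbe` (clinical neutron RBE 3 applied after the
physical calculation), `lateral_profile` and `isodose_contours` produce
the planning plots. A `neutronplan` command-line tool wraps the pipeline
(`make-spectrum`, `make-phantom`, `simulate`, `depthdose`, `dvh`,
`isodose`, `compare`).

## Layout

- `src/neutronplan/materials.py` — elements, tissue/structural materials,
  composition conversions (`data/materials.tsv`, user-extensible)
- `src/neutronplan/physics.py` — cross sections and interaction sampling
  (`data/PROVENANCE.md` lists every packaged physical constant)
- `src/neutronplan/spectra.py` — binned spectra, inverse-CDF sampling,
  synthetic facility-like source
- `src/neutronplan/geometry.py` — phantoms, room, voxelisation, phantom
  file I/O, synthetic head generator
- `src/neutronplan/transport.py` + `_kernels.py` — the Monte Carlo engine
  (numba-compiled)
- `src/neutronplan/tallies.py` — dose/fluence finalisation and errors
- `src/neutronplan/planning.py` — depth dose, profiles, DVH, RBE, isodoses
- `src/neutronplan/runio.py`, `cli.py` — run configs, result files, CLI
- `docs/methods.md` — model description, assumptions and limitations
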