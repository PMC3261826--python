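# Methods

This note describes the physical model, the numerical choices and the
limitations of the `neutronplan` dose engine, in the spirit of a model
write-up: what is simulated, what is deliberately simplified, and what the
passing tests do and do not demonstrate about real beams.

## Source model

The treatment beam is a horizontal, parallel, rectangular beam along +x
with a uniform profile; beam divergence (1–2° at the real beamline) and
collimator penumbra are not modelled, so calculated lateral edges are
sharper than measured ones. Primaries are drawn by inverse-CDF sampling
from an energy-binned fluence spectrum; within a bin the energy is uniform
in E (a log-uniform option exists for wide thermal bins — the choice
matters only for bins spanning decades).

The measured facility spectra are not published as tables, so a synthetic
stand-in generator provides:

* **neutrons** — a Watt fission shape, p(E) ∝ exp(−E/a)·sinh√(bE) with
  a = 0.988 MeV and b = 2.249 MeV⁻¹ (thermal-fission parameters; sampled
  mean ≈ 2.0 MeV), carrying 95% of the fluence, plus a 5% thermal
  Maxwellian tail (kT = 0.0253 eV) representing the moderated component of
  a filtered converter-plate beam. 58 log-spaced bins over 1 meV–20 MeV,
  matching the fluence-tally binning.
* **photons** — a soft falling continuum E^−0.7·exp(−E/2 MeV) spanning
  0.1–8 MeV, standing in for the reactor-gamma component.

Both are normalised to the facility totals (3.2·10⁸ and 2.9·10⁸ cm⁻²s⁻¹).
Absolute depth-dose magnitudes therefore carry the synthetic-spectrum
shapes; relative behaviour (attenuation, scatter spread, organ sparing) is
what the package's comparisons rely on. The photon normalisation history
(a transport-calculated 1.8·10⁸ cm⁻²s⁻¹ rescaled to a best estimate of
2.9·10⁸ by matching measured near-surface depth doses, a factor ≈ 1.61) is
available as the `renormalize_photons` least-squares operation over the
0–10 cm window; the matching criterion within that window is this
package's choice (least squares).

## Interaction physics

A deliberately small, fully inspectable reaction set replaces an evaluated
nuclear-data library; every packaged constant is listed in
`src/neutronplan/data/PROVENANCE.md`.

**Neutrons.** Elastic scattering (isotropic in the CM, two-body
kinematics) and 1/v radiative capture. Elastic cross sections are smooth
log-log interpolations through free-atom anchor values (σ_H: 20.4 b
thermal, 4.26 b at 1 MeV, 0.94 b at 10 MeV); resonances are omitted.
Below 4 eV the target nucleus moves: speeds are drawn from the
relative-speed-weighted 300 K Maxwellian with the standard two-component
rejection scheme. This free-gas model replaces the molecular-binding
S(α,β) treatment, which is not reproducible without thermal scattering
libraries. Consequences: the bound-atom enhancement of the thermal H cross
section (≈ 80 b in water vs ≈ 20 b free) is missing, so thermal neutrons
diffuse with a ~3× longer mean free path, leak from the phantom more
often, and are captured less often (measured capture frequency
≈ 0.11 per primary). This depresses the capture-gamma (secondary-photon)
dose: the measured secondary-photon fraction of the total photon dose in
the first centimetres is 4–6% here versus the 10–15% reference; the
acceptance suite reports this deviation rather than asserting the band.
Inelastic channels, (n,p)/(n,α) on N and O are not modelled (the N-14
(n,p) channel contributes a few percent of tissue kerma at thermal
energies, another reason the thermal dose components sit low).

Capture on hydrogen emits one isotropic 2.2246 MeV gamma (deuteron binding
energy); for heavier nuclei the capture-gamma energy (the compound-nucleus
separation energy) deposits locally — the mean free path of those gammas
is tens of cm, so this slightly concentrates a very small dose component.

**Photons.** Klein–Nishina Compton scattering off Z free electrons per
atom (rejection sampling of ε = E′/E; total cross section agrees with the
Thomson limit to < 1%), a parametric photoelectric channel
σ ∝ Z⁴·⁵/E³ anchored to the water attenuation at 10 keV, and pair
production σ ∝ Z²·ln(E/2mₑc²) anchored near 10 MeV, with both annihilation
quanta emitted back-to-back at the interaction point. Rayleigh scattering,
fluorescence and bremsstrahlung are omitted.

**Kerma approximation.** Recoil protons, heavier recoils, photoelectrons,
Compton electrons and pair electrons deposit their kinetic energy at the
interaction site, tagged by particle type. At the energies involved the
charged-particle ranges (≲ 0.1 mm for recoil protons, a few mm for the
fastest electrons) are below or near the voxel size, so this reproduces
the per-particle dose split of a condensed-history calculation except for
a slight sharpening of dose gradients at interfaces and beam edges.
Because the free-gas model exchanges energy with a 300 K bath, individual
voxel tallies can carry ~kT-scale negative net deposits; they are retained
(clipping would bias the mean).

Two reporting groupings expose the tag structure: *lineage* (everything
initiated by a neutron, including capture-gamma dose, vs primary-photon
progeny) and *measured* (recoil dose vs all photon-mediated dose — the
twin-chamber view). RBE weighting is a separate post-processing step:
weighted dose = Σ w_tag·D_tag, default w = 3 for the neutron lineage and 1
for photons, applied after the physical calculation.

## Transport and tallies

Free flights are sampled by optical-depth accumulation across boundaries,
so piecewise media are sampled exactly (verified against a
piecewise-exponential oracle by KS test). The geometry is a first-fit list
of nested axis-aligned boxes, optionally containing a voxel grid; voxel
stepping recomputes face distances per step. A nearest-surface lower bound
lets flights shorter than the distance to any surface skip the boundary
search. Woodcock delta tracking against a global majorant is available as
an option and is tested for agreement with surface tracking.

Default cutoffs: neutrons 0.01 eV, photons 10 keV; the residual energy
deposits locally with the terminating particle's tag. Every history is
audited: E_source + Q_released = E_deposited + E_escaped to ≤ 10⁻⁶
relative (measured ~10⁻¹⁵).

Tallies accumulate per history (not per step), which keeps correlated
secondaries inside one sample — required for correct variance of e.g.
capture-gamma dose. Chamber doses are mass-averaged (regions are
homogeneous water, so mass- and volume-averaging coincide). The pooled
8-voxel blocks of the voxelised phantom are scored as single regions, so
their errors are exact; the `aggregate_voxels` post-operation on finished
grids assumes independent voxels and is an upper bound on the pooled
error. RNG: xorshift128+ seeded via splitmix64, one independent stream per
history, so results are independent of execution order and chunking, and
two runs with the same seed share their primaries.

## Study sizes and the paired room comparison

The acceptance computation compares the solid water phantom with and
without the schematic concrete room using 2·10⁶ histories per arm — sizes
chosen so the whole computation stays within about a minute. At this size
the per-chamber marginal errors are 2–5%, far larger than the ≲ 0.1% room
effect; the comparison is therefore run as a paired design: both arms use
the same seed, histories are identical until a particle reaches the wall
location, and the difference isolates the room-albedo contribution. The
measured maximum relative change for depths ≤ 10 cm is ~0.02%, consistent
with the reference statement that the room matters at below the 2% level.
Driving every chamber's marginal error below 0.5% would need ~2·10⁸
histories per arm; the paired design makes that unnecessary for the
difference itself.

## Synthetic phantoms

The voxelised water phantom samples the solid-box materials at voxel
centres, so the 3 mm aluminum window is rendered 2 mm thick at the 2 mm
grid — a ≲ 1% transmission difference absorbed by the equivalence test's
statistical tolerance (the solid and voxelised depth doses agree within 3
combined standard errors at all 40 chamber depths, with shared primaries).

The synthetic head/neck phantom stands in for a CT-segmented reference
phantom, whose data are not redistributable. It is a layered ellipsoid
model (skin → adipose → muscle → skull with yellow-marrow diploe → CSF →
brain) with a neck (cervical spine with spongiosa and red marrow, spinal
cord, trachea with cartilage rings, oesophagus, thyroid, carotids, lymph
nodes), a face (eyes with lenses, teeth, tongue, mucosa, pituitary) and an
upper torso (lungs, heart, liver, spleen, breasts, thymus), using 30
distinct materials at the default grid (299 × 137 × 337 voxels of
1.775 × 1.775 × 4.84 mm³, x growing patient-right→left, y nose→back,
z feet→head; the upper quarter, 87 slices, covers the head-and-neck
treatment region). The six salivary glands are labelled ROI organs; their
positions are the generator's own choice (the reference case's exact
isocentre is not published), and the body surface is forced to a one-voxel
skin layer. The anatomy is geometric, not tomographic: organ shapes,
interfaces and air cavities are idealised, so head-case results
demonstrate the engine's behaviour (material-dependent dose, trachea
shadowing, contralateral sparing), not patient dosimetry.

## Known limitations

* Absolute dose levels inherit the synthetic spectra; only relative
  comparisons are meaningful against measured curves.
* No S(α,β): thermal fluence and capture-gamma dose are biased low (see
  above); depth doses beyond ~20 cm, where the field is fully
  thermalised, are least reliable.
* No inelastic neutron channels above ~5 MeV (a few percent of fast-dose
  pathways), no electron transport, no Rayleigh/fluorescence.
* The room model is schematic (six slabs and a window); it bounds the
  wall influence but is not a shielding calculation.
* Energy-dependent RBE models are out of scope; the clinical factor 3 is
  a constant applied after transport.
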