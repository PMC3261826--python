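"""Binned source spectra, inverse-CDF sampling, and the rectangular beam.

The therapy beam is a horizontal parallel beam along +x with a uniform
rectangular profile ("no decrease towards the edges"); beam divergence and
penumbra are deliberately not modelled.  The measured facility spectra are
not published as tables, so a synthetic stand-in is provided: a Watt fission
shape with a small thermal Maxwellian tail for neutrons, and a soft
piecewise shape spanning 0.1-8 MeV for photons, each normalised to the
facility's total fluence rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .physics import RandomState

__all__ = [
    "EnergySpectrum",
    "SamplingTable",
    "BeamConfig",
    "build_cdf",
    "sample_primary",
    "synthetic_medapp_spectrum",
    "save_spectrum",
    "load_spectrum",
    "NEUTRON_FLUENCE_RATE",
    "PHOTON_FLUENCE_RATE",
    "N_SPECTRUM_BINS",
]

# facility total fluence rates at the patient position, cm^-2 s^-1
NEUTRON_FLUENCE_RATE = 3.2e8
PHOTON_FLUENCE_RATE = 2.9e8
# the photon rate obtained by integrating the transport-calculated spectrum,
# before renormalisation against measured depth-dose curves
PHOTON_FLUENCE_RATE_UNRENORMALIZED = 1.8e8

N_SPECTRUM_BINS = 58  # matches the energy-binned cell-fluence scorer

WATT_A_MEV = 0.988
WATT_B_PER_MEV = 2.249
THERMAL_KT_EV = 0.0253
THERMAL_FRACTION = 0.05


@dataclass
class EnergySpectrum:
    """Energy-binned fluence-rate spectrum for one particle kind."""

    particle: str                 # "neutron" | "photon"
    edges_ev: np.ndarray          # (nb+1,), ascending
    rate_per_bin: np.ndarray      # (nb,), cm^-2 s^-1

    def __post_init__(self) -> None:
        self.edges_ev = np.asarray(self.edges_ev, dtype=float)
        self.rate_per_bin = np.asarray(self.rate_per_bin, dtype=float)
        if self.edges_ev.ndim != 1 or self.edges_ev.size != self.rate_per_bin.size + 1:
            raise ValueError("edges must have one more entry than bins")
        if np.any(np.diff(self.edges_ev) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.rate_per_bin < 0):
            raise ValueError("bin rates must be non-negative")
        if self.particle not in ("neutron", "photon"):
            raise ValueError(f"unknown particle {self.particle!r}")

    @property
    def total_rate(self) -> float:
        """Total fluence rate, cm^-2 s^-1 (sum over bins)."""
        return float(self.rate_per_bin.sum())

    def rescaled(self, total_rate: float) -> "EnergySpectrum":
        cur = self.total_rate
        if cur <= 0:
            raise ValueError("cannot rescale an all-zero spectrum")
        return EnergySpectrum(self.particle, self.edges_ev.copy(),
                              self.rate_per_bin * (total_rate / cur))


@dataclass
class SamplingTable:
    """Inverse-CDF table: cumulative probability at each bin's upper edge."""

    edges_ev: np.ndarray
    cum: np.ndarray               # (nb,), monotone, cum[-1] == 1
    log_in_bin: bool = False      # within-bin sampling law


def build_cdf(spectrum: EnergySpectrum, log_in_bin: bool = False) -> SamplingTable:
    """Integrate and normalise the spectrum into a sampling CDF."""
    total = spectrum.total_rate
    if total <= 0:
        raise ValueError("all-zero spectrum has no sampling CDF")
    cum = np.cumsum(spectrum.rate_per_bin) / total
    cum[-1] = 1.0
    return SamplingTable(spectrum.edges_ev.copy(), cum, log_in_bin)


@dataclass
class BeamConfig:
    """Rectangular parallel beam along +x with a uniform profile."""

    width: float                 # cm, lateral (y)
    height: float                # cm, vertical (z)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    neutron_spectrum: EnergySpectrum | None = None
    photon_spectrum: EnergySpectrum | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("beam width and height must be > 0")

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def neutron_probability(self) -> float:
        """Probability that a sampled primary is a neutron (by fluence rate)."""
        rn = self.neutron_spectrum.total_rate if self.neutron_spectrum else 0.0
        rg = self.photon_spectrum.total_rate if self.photon_spectrum else 0.0
        if rn + rg <= 0:
            raise ValueError("beam carries no particles")
        return rn / (rn + rg)


def _sample_energy(table: SamplingTable, rng: RandomState) -> float:
    r = rng.uniform()
    ib = int(np.searchsorted(table.cum, r))
    ib = min(ib, table.cum.size - 1)
    lo, hi = table.edges_ev[ib], table.edges_ev[ib + 1]
    f = rng.uniform()
    if table.log_in_bin:
        return float(lo * (hi / lo) ** f)
    return float(lo + (hi - lo) * f)


def sample_primary(beam: BeamConfig, cdf: SamplingTable | dict, rng: RandomState):
    """Sample one primary particle state from the beam.

    ``cdf`` is a single SamplingTable (single-species beam) or a dict
    ``{"neutron": table, "photon": table}`` for a mixed beam.  The position
    is uniform over the aperture, the direction is exactly +x, weight 1.
    """
    from .transport import ParticleState  # deferred: transport builds on spectra

    if isinstance(cdf, dict):
        kind = "neutron" if rng.uniform() < beam.neutron_probability else "photon"
        table = cdf[kind]
    else:
        kind = (beam.neutron_spectrum and "neutron") or "photon"
        table = cdf
    energy = _sample_energy(table, rng)
    cx, cy, cz = beam.center
    y = cy + beam.width * (rng.uniform() - 0.5)
    z = cz + beam.height * (rng.uniform() - 0.5)
    return ParticleState(kind=kind, position=(cx, y, z),
                         direction=(1.0, 0.0, 0.0), energy_ev=energy)


# ----------------------------------------------------------------------------
# synthetic facility-like spectra
# ----------------------------------------------------------------------------

def _watt_density(e_mev: np.ndarray) -> np.ndarray:
    return np.exp(-e_mev / WATT_A_MEV) * np.sinh(np.sqrt(WATT_B_PER_MEV * e_mev))


def synthetic_medapp_spectrum(
    kind: str,
    total_rate: float,
    n_bins: int = N_SPECTRUM_BINS,
    thermal_fraction: float = THERMAL_FRACTION,
) -> EnergySpectrum:
    """Synthetic stand-in for the measured beam spectra.

    Neutrons: Watt fission shape (a = 0.988 MeV, b = 2.249 /MeV) carrying
    ``1 - thermal_fraction`` of the fluence plus a 300 K-ish thermal
    Maxwellian tail, on ``n_bins`` log-spaced bins over 1e-3 eV - 20 MeV.
    Photons: falling piecewise shape spanning 0.1 - 8 MeV.  Normalised so the
    bins sum to ``total_rate``.
    """
    if total_rate <= 0:
        raise ValueError("total_rate must be > 0")
    if kind == "neutron":
        edges = np.geomspace(1.0e-3, 2.0e7, n_bins + 1)
        content = np.zeros(n_bins)
        for i in range(n_bins):
            sub = np.linspace(edges[i], edges[i + 1], 33)
            content[i] = np.trapezoid(_watt_density(sub / 1.0e6), sub / 1.0e6)
        watt_part = content / content.sum() * (1.0 - thermal_fraction)
        thermal = np.zeros(n_bins)
        for i in range(n_bins):
            sub = np.linspace(edges[i], edges[i + 1], 33)
            thermal[i] = np.trapezoid(sub * np.exp(-sub / THERMAL_KT_EV), sub)
        thermal = (thermal / thermal.sum() * thermal_fraction
                   if thermal_fraction > 0 else thermal * 0.0)
        rates = (watt_part + thermal) * total_rate
        return EnergySpectrum("neutron", edges, rates)
    if kind == "photon":
        edges = np.geomspace(1.0e5, 8.0e6, n_bins + 1)
        content = np.zeros(n_bins)
        for i in range(n_bins):
            sub = np.linspace(edges[i], edges[i + 1], 33)
            e_mev = sub / 1.0e6
            # soft reactor-gamma-like continuum
            content[i] = np.trapezoid(e_mev**-0.7 * np.exp(-e_mev / 2.0), e_mev)
        rates = content / content.sum() * total_rate
        return EnergySpectrum("photon", edges, rates)
    raise ValueError(f"unknown particle kind {kind!r}")


# ----------------------------------------------------------------------------
# spectrum files (plain text)
# ----------------------------------------------------------------------------

def save_spectrum(spectrum: EnergySpectrum, path: str | Path) -> None:
    """Write `E_low E_high rate` rows with a two-line header."""
    lines = [f"# particle: {spectrum.particle}",
             f"# total_rate: {spectrum.total_rate:.8e}"]
    for i in range(spectrum.rate_per_bin.size):
        lines.append(f"{spectrum.edges_ev[i]:.8e} {spectrum.edges_ev[i+1]:.8e} "
                     f"{spectrum.rate_per_bin[i]:.8e}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_spectrum(path: str | Path) -> EnergySpectrum:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectrum file not found: {path}")
    particle = None
    lo, hi, rate = [], [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "particle:" in line:
                particle = line.split("particle:")[1].strip()
            continue
        a, b, r = line.split()
        lo.append(float(a))
        hi.append(float(b))
        rate.append(float(r))
    if particle is None or not lo:
        raise ValueError(f"malformed spectrum file: {path}")
    edges = np.array(lo + [hi[-1]])
    return EnergySpectrum(particle, edges, np.array(rate))
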