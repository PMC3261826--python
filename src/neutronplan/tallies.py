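"""Dose and fluence tallies with history-by-history statistical errors.

The transport kernel accumulates, for every scoring region and particle
tag, the sum and sum of squares of the *per-history* deposited energy.
This module turns those accumulators into physical quantities:

* dose per unit primary planar fluence (Gy cm^2), the natural normalisation
  for a parallel beam whose one primary represents a planar fluence of
  1/area per cm^2;
* the one-standard-deviation error of the mean from the history-by-history
  variance formula (per-history batching keeps correlated secondaries
  together, which per-step accumulation would get wrong);
* track-length cell fluence per primary in 58 energy bins;
* absolute dose rates and doses via the facility fluence rates and the
  irradiation time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transport import RunResult, TAG_NAMES

__all__ = [
    "DoseTally",
    "DoseResult",
    "FluenceTally",
    "finalize_dose",
    "finalize_fluence",
    "to_dose_rate",
    "to_absolute",
    "aggregate_voxels",
    "group_doses",
]

EV_TO_J = 1.602176634e-19

# reporting groups over the deposit tags
GROUPINGS = {
    # lineage view: everything started by a neutron vs. by a primary photon
    "lineage": {"neutron": ("proton", "neutron", "electron_n"),
                "photon": ("electron_g",)},
    # twin-chamber view: recoil dose vs. all photon-mediated dose
    "measured": {"neutron": ("proton", "neutron"),
                 "photon": ("electron_n", "electron_g")},
}


@dataclass
class DoseTally:
    """Per-region, per-tag accumulators of per-history deposited energy (eV)."""

    sum_x: np.ndarray          # (n_regions, n_tags)
    sum_x2: np.ndarray
    n_histories: int
    region_mass_g: np.ndarray
    beam_area_cm2: float

    @classmethod
    def from_run(cls, result: RunResult) -> "DoseTally":
        return cls(result.sum_x, result.sum_x2, result.n_histories,
                   result.region_mass_g, result.beam_area_cm2)


@dataclass
class DoseResult:
    """Finalised dose per primary fluence with 1-sigma errors (Gy cm^2)."""

    dose: np.ndarray           # (n_regions, n_tags)
    se: np.ndarray
    tag_names: tuple = TAG_NAMES

    @property
    def total(self) -> np.ndarray:
        return self.dose.sum(axis=-1)

    @property
    def total_se(self) -> np.ndarray:
        # tags within a region share histories; a conservative combined error
        return np.sqrt((self.se**2).sum(axis=-1))

    def tagged(self, *tags: str) -> tuple[np.ndarray, np.ndarray]:
        idx = [self.tag_names.index(t) for t in tags]
        return self.dose[..., idx].sum(axis=-1), np.sqrt(
            (self.se[..., idx] ** 2).sum(axis=-1))


def finalize_dose(tally: DoseTally | RunResult) -> DoseResult:
    """Mean dose per primary planar fluence and its standard error.

    mean deposit m = sum_x / n (eV per history); the standard error of the
    mean is sqrt[(sum_x2/n - m^2) / (n-1)].  Both convert to Gy via the
    region mass and to Gy cm^2 via the beam area (one primary <-> planar
    fluence 1/area).
    """
    if isinstance(tally, RunResult):
        tally = DoseTally.from_run(tally)
    n = tally.n_histories
    if n < 2:
        raise ValueError("need at least 2 histories for an error estimate")
    mass = np.asarray(tally.region_mass_g)
    if np.any(mass <= 0) and not np.all(mass[mass <= 0] == 0):
        raise ValueError("negative region mass")
    m = tally.sum_x / n
    var_mean = np.maximum(tally.sum_x2 / n - m**2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(mass > 0, EV_TO_J / (mass * 1.0e-3), 0.0)[:, None]
    dose = m * scale * tally.beam_area_cm2
    se = np.sqrt(var_mean) * scale * tally.beam_area_cm2
    return DoseResult(dose, se)


@dataclass
class FluenceTally:
    """Per-region track-length accumulators in energy bins (cm)."""

    sum_len: np.ndarray        # (n_regions, n_bins)
    sum_len2: np.ndarray
    n_histories: int
    region_volume_cm3: np.ndarray
    edges_ev: np.ndarray

    @classmethod
    def from_run(cls, result: RunResult) -> "FluenceTally":
        if result.fl_sum is None:
            raise ValueError("run was executed without the fluence tally")
        nfl = result.fl_sum.shape[0]
        return cls(result.fl_sum, result.fl_sum2, result.n_histories,
                   result.region_volume_cm3[:nfl], result.fl_edges_ev)


def finalize_fluence(tally: FluenceTally | RunResult, n: int | None = None):
    """Cell fluence per primary (cm^-2) per energy bin, with 1-sigma error."""
    if isinstance(tally, RunResult):
        tally = FluenceTally.from_run(tally)
    n = n or tally.n_histories
    if n < 2:
        raise ValueError("need at least 2 histories")
    vol = np.asarray(tally.region_volume_cm3)
    if np.any(vol <= 0):
        raise ValueError("zero region volume")
    m = tally.sum_len / n
    var_mean = np.maximum(tally.sum_len2 / n - m**2, 0.0) / (n - 1)
    flu = m / vol[:, None]
    se = np.sqrt(var_mean) / vol[:, None]
    return flu, se


def to_dose_rate(dose_per_fluence_gycm2, fluence_rate_cm2s):
    """Gy cm^2  x  cm^-2 s^-1  ->  Gy/s.

    Dose estimates may carry tiny negative values from the free-gas
    heat-bath exchange; only the fluence rate is sign-checked.
    """
    if fluence_rate_cm2s < 0:
        raise ValueError("fluence rate must be non-negative")
    return np.asarray(dose_per_fluence_gycm2) * fluence_rate_cm2s


def to_absolute(dose_rate_gys, seconds: float):
    """Gy/s x s -> Gy (absolute dose for an irradiation time)."""
    if seconds < 0:
        raise ValueError("irradiation time must be >= 0")
    return np.asarray(dose_rate_gys) * seconds


def aggregate_voxels(dose, se, center, n_lateral: int = 4, n_vertical: int = 2,
                     voxel_volume_cm3: float | None = None,
                     mass=None):
    """Pool a block of voxels around ``center`` (4 lateral x 2 vertical x 1).

    ``dose``/``se`` are (nx, ny, nz) grids; lateral is y, vertical is z.
    Mass-weighted mean; the pooled error assumes independent voxels (an
    upper bound — exact pooled errors come from scoring the block as one
    region).  Returns (pooled dose, pooled se, block volume).
    """
    ix, iy, iz = center
    y0 = iy - n_lateral // 2
    z0 = iz - n_vertical // 2
    nx, ny, nz = dose.shape
    if y0 < 0 or y0 + n_lateral > ny or z0 < 0 or z0 + n_vertical > nz or not (0 <= ix < nx):
        raise ValueError("aggregation block exceeds the grid")
    d = dose[ix, y0:y0 + n_lateral, z0:z0 + n_vertical]
    s = se[ix, y0:y0 + n_lateral, z0:z0 + n_vertical]
    if mass is None:
        w = np.ones_like(d)
    else:
        w = mass[ix, y0:y0 + n_lateral, z0:z0 + n_vertical]
    wt = w.sum()
    pooled = float((w * d).sum() / wt)
    pooled_se = float(np.sqrt(((w * s) ** 2).sum()) / wt)
    vol = None
    if voxel_volume_cm3 is not None:
        vol = n_lateral * n_vertical * voxel_volume_cm3
    return pooled, pooled_se, vol


def group_doses(result: DoseResult, grouping: str = "lineage"):
    """Collapse tagged doses into a named reporting group."""
    groups = GROUPINGS[grouping]
    out = {}
    for name, tags in groups.items():
        out[name] = result.tagged(*tags)
    return out
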