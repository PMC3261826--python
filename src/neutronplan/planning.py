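"""Treatment-planning outputs: depth dose, profiles, DVH, RBE, isodoses.

These operate on finalised dose arrays (per-region tables or voxel grids)
and are deliberately independent of the transport engine, so they can be
applied to any dose grid with matching metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .tallies import aggregate_voxels

__all__ = [
    "DVHCurve",
    "RBEWeights",
    "depth_dose",
    "depth_dose_grid",
    "lateral_profile",
    "edge_decrease",
    "cumulative_dvh",
    "apply_rbe",
    "renormalize_photons",
    "isodose_contours",
    "wall_influence",
]


def depth_dose(depths, dose, se=None) -> pd.DataFrame:
    """Depth-dose series from a chamber (or block) table, ordered by depth."""
    depths = np.asarray(depths, dtype=float)
    dose = np.asarray(dose, dtype=float)
    if depths.size == 0:
        raise ValueError("empty depth-dose selection")
    if se is None:
        se = np.zeros_like(dose)
    order = np.argsort(depths)
    return pd.DataFrame({"depth_cm": depths[order], "dose": dose[order],
                         "se": np.asarray(se, dtype=float)[order]})


def depth_dose_grid(dose, se, origin, voxel_size, center_yz=(0.0, 0.0),
                    n_lateral: int = 4, n_vertical: int = 2) -> pd.DataFrame:
    """On-axis depth-dose from a voxel dose grid.

    For every depth layer the dose is pooled over an ``n_lateral`` (y) x
    ``n_vertical`` (z) voxel block around the beam axis, mirroring the
    8-voxel collection volume used for the voxelised water phantom.
    """
    nx, ny, nz = dose.shape
    vx, vy, vz = voxel_size
    iy = int((center_yz[0] - origin[1]) / vy)
    iz = int((center_yz[1] - origin[2]) / vz)
    iy = min(max(iy, n_lateral // 2), ny - (n_lateral + 1) // 2)
    iz = min(max(iz, n_vertical // 2), nz - (n_vertical + 1) // 2)
    rows = []
    for ix in range(nx):
        d, s, _ = aggregate_voxels(dose, se, (ix, iy, iz), n_lateral, n_vertical)
        rows.append((origin[0] + (ix + 0.5) * vx, d, s))
    return pd.DataFrame(rows, columns=["depth_cm", "dose", "se"])


def lateral_profile(dose, se, slice_iz: int, column_ix: int,
                    origin=(0.0, 0.0, 0.0), voxel_size=(1.0, 1.0, 1.0)) -> pd.DataFrame:
    """Full lateral (row/y) dose profile at one depth column and slice."""
    nx, ny, nz = dose.shape
    if not (0 <= column_ix < nx and 0 <= slice_iz < nz):
        raise IndexError(f"column {column_ix} / slice {slice_iz} out of range")
    prof = dose[column_ix, :, slice_iz]
    prof_se = se[column_ix, :, slice_iz]
    y = origin[1] + (np.arange(ny) + 0.5) * voxel_size[1]
    return pd.DataFrame({"row": np.arange(ny), "y_cm": y,
                         "dose": prof, "se": prof_se})


def edge_decrease(profile: pd.DataFrame, row_outside: int, row_inside: int) -> float:
    """Relative dose decrease (%) between two rows, relative to the inner row.

    Mirrors the beam-edge contrast measure: 100 * (D_in - D_out) / D_in.
    """
    d_in = float(profile.loc[profile["row"] == row_inside, "dose"].iloc[0])
    d_out = float(profile.loc[profile["row"] == row_outside, "dose"].iloc[0])
    if d_in == 0:
        raise ValueError("zero dose at the reference row")
    return 100.0 * (d_in - d_out) / d_in


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram V(D) = volume fraction with dose >= D."""

    dose_edges: np.ndarray       # (n+1,) Gy
    volume_fraction: np.ndarray  # (n+1,), starts at 1, non-increasing, ends 0
    organ: str = ""
    n_voxels: int = 0
    d50: float | None = None     # dose at 50% volume (set when normalised)

    def __post_init__(self) -> None:
        v = self.volume_fraction
        if v[0] != 1.0 or np.any(np.diff(v) > 1e-12) or v[-1] > 1e-12:
            raise ValueError("DVH must start at 1, be non-increasing and end at 0")

    def volume_at(self, dose: float) -> float:
        """Fraction of the organ receiving at least ``dose``."""
        return float(np.interp(dose, self.dose_edges, self.volume_fraction))

    def dose_at_volume(self, fraction: float) -> float:
        """Dose received by at least ``fraction`` of the organ (e.g. D50)."""
        v = self.volume_fraction
        idx = np.argsort(v)
        return float(np.interp(fraction, v[idx], self.dose_edges[idx]))

    def mean_dose(self) -> float:
        """Mean organ dose = integral of V(D) dD."""
        return float(np.trapezoid(self.volume_fraction, self.dose_edges))


def cumulative_dvh(dose, mask, bin_width: float | None = None,
                   organ: str = "", normalize: str = "none") -> DVHCurve:
    """Cumulative DVH of the masked voxels (equal-volume uniform grid).

    ``normalize='d50'`` divides the dose axis by the organ's D50 (dose at
    50% volume), an optional per-organ normalisation for comparing RBE
    variants.
    """
    doses = np.asarray(dose)[np.asarray(mask, dtype=bool)]
    if doses.size == 0:
        raise ValueError("empty organ mask")
    dmax = float(doses.max())
    if bin_width is None:
        bin_width = max(dmax, 1e-30) / 200.0
    edges = np.arange(0.0, dmax + 2 * bin_width, bin_width)
    frac = np.array([(doses >= d).mean() for d in edges])
    frac[0] = 1.0
    curve = DVHCurve(edges, frac, organ, int(doses.size))
    if normalize == "d50":
        d50 = curve.dose_at_volume(0.5)
        if d50 <= 0:
            raise ValueError("D50 is zero; cannot normalise")
        curve = DVHCurve(edges / d50, frac, organ, int(doses.size), d50=d50)
    elif normalize != "none":
        raise ValueError(f"unknown normalisation {normalize!r}")
    return curve


@dataclass
class RBEWeights:
    """Multiplicative biological weights per particle-lineage group.

    The clinical weighting applied after the physical calculation: RBE 3 for
    the neutron lineage (recoils and neutron-induced gammas), 1 for primary
    photons.
    """

    factors: dict = field(default_factory=lambda: {"neutron": 3.0, "photon": 1.0})

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("RBE factors must be > 0")


def apply_rbe(components: dict, weights: RBEWeights | None = None):
    """Weighted dose = sum_tag w_tag * D_tag over lineage components."""
    weights = weights or RBEWeights()
    missing = set(weights.factors) - set(components)
    if missing:
        raise KeyError(f"missing dose component(s): {sorted(missing)}")
    out = None
    for tag, w in weights.factors.items():
        term = w * np.asarray(components[tag], dtype=float)
        out = term if out is None else out + term
    return out


def renormalize_photons(primary_curve, secondary_curve, reference_curve,
                        depths, window=(0.0, 10.0)) -> float:
    """Least-squares scale of the primary-photon depth-dose curve.

    Finds s minimising sum_window (s*P + S - R)^2, i.e. the factor by which
    the primary-photon fluence must be rescaled so that primary + secondary
    photon dose matches the reference in the near-surface window:
    s = sum(P*(R-S)) / sum(P^2).
    """
    depths = np.asarray(depths, dtype=float)
    P = np.asarray(primary_curve, dtype=float)
    S = np.asarray(secondary_curve, dtype=float)
    R = np.asarray(reference_curve, dtype=float)
    sel = (depths >= window[0]) & (depths <= window[1])
    if not sel.any():
        raise ValueError("empty depth window")
    P, S, R = P[sel], S[sel], R[sel]
    denom = float((P * P).sum())
    if denom <= 0:
        raise ValueError("primary curve is zero everywhere in the window")
    return float((P * (R - S)).sum() / denom)


def isodose_contours(dose_slice, prescribed_gy: float, levels_percent,
                     upsample: int = 4, origin=(0.0, 0.0),
                     voxel_size=(1.0, 1.0)) -> dict:
    """Isodose polylines per level (% of the prescribed dose).

    The slice is upsampled with a bicubic spline, then contours are
    extracted with marching squares.  Returns {level: [(N, 2) arrays of
    (ax0, ax1) cm coordinates]}; levels outside the data range yield empty
    lists.
    """
    dose_slice = np.asarray(dose_slice, dtype=float)
    if dose_slice.ndim != 2 or min(dose_slice.shape) < 2:
        raise ValueError("need a 2-D slice of at least 2 x 2")
    if prescribed_gy <= 0:
        raise ValueError("prescribed dose must be > 0")
    fine = ndimage.zoom(dose_slice, upsample, order=3, grid_mode=True,
                        mode="nearest")
    out = {}
    for lv in levels_percent:
        absolute = lv / 100.0 * prescribed_gy
        if absolute < fine.min() or absolute > fine.max():
            out[lv] = []
            continue
        polys = []
        for c in measure.find_contours(fine, absolute):
            # grid_mode zoom subdivides cells: original pixel centre i sits
            # at fine index i*u + (u-1)/2
            idx = (c + 0.5) / upsample - 0.5
            phys = np.empty_like(idx)
            phys[:, 0] = origin[0] + (idx[:, 0] + 0.5) * voxel_size[0]
            phys[:, 1] = origin[1] + (idx[:, 1] + 0.5) * voxel_size[1]
            polys.append(phys)
        out[lv] = polys
    return out


def wall_influence(curve_with_room, curve_without, se_with=None, se_without=None,
                   depths=None) -> pd.DataFrame:
    """Per-depth relative dose change from adding the room, with errors.

    |D_room - D_free| / D_free, with the combined MC error propagated in
    quadrature (relative).
    """
    Dr = np.asarray(curve_with_room, dtype=float)
    Df = np.asarray(curve_without, dtype=float)
    if Dr.shape != Df.shape:
        raise ValueError("curves must share a depth grid")
    if np.any(Df == 0):
        raise ValueError("zero free-field dose")
    rel = np.abs(Dr - Df) / Df
    if se_with is None:
        err = np.zeros_like(rel)
    else:
        err = np.sqrt(np.asarray(se_with) ** 2 + np.asarray(se_without) ** 2) / Df
    data = {"relative_difference": rel, "error": err}
    if depths is not None:
        data = {"depth_cm": np.asarray(depths, dtype=float), **data}
    return pd.DataFrame(data)
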