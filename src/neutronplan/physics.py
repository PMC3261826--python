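"""Simplified neutron/photon interaction physics.

Neutrons undergo isotropic-in-CM elastic scattering (free-gas target motion
at 300 K below a thermal cutoff) and 1/v radiative capture; capture on
hydrogen emits the 2.2246 MeV deuteron-binding gamma, capture on heavier
nuclei deposits the gamma energy locally.  Photons undergo Klein-Nishina
Compton scattering, a parametric photoelectric channel and pair production.
Charged secondaries (recoil protons, electrons) are not transported: their
kinetic energy deposits at the interaction site (kerma approximation) tagged
with the depositing particle type.

Cross sections are smooth parametric stand-ins for an evaluated library,
anchored at published point values (see ``data/PROVENANCE.md``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from . import _kernels
from .materials import ELEMENTS, Material

__all__ = [
    "RandomState",
    "NeutronChannelTable",
    "PhotonChannelTable",
    "PackedPhysics",
    "neutron_channel_table",
    "photon_channel_table",
    "klein_nishina_total",
    "macroscopic_xs",
    "sample_channel",
    "elastic_scatter",
    "capture",
    "compton_sample",
    "build_packed_physics",
    "EGRID_N",
    "EGRID_G",
]

BARN = 1.0e-24          # cm^2
M_EC2_MEV = 0.51099895  # MeV
R_E_CM = 2.8179403e-13  # classical electron radius, cm
H_CAPTURE_GAMMA_MEV = 2.2246
THERMAL_CUTOFF_EV = 4.0
KT_300K_EV = _kernels.KT_300K_EV

# photoelectric: sigma = PE_CONST * Z^4.5 / E_MeV^3  (barn/atom)
PE_CONST = 1.26e-8
# pair production: sigma = PAIR_CONST * Z^2 * ln(E / 2 m_e c^2)  (barn/atom)
PAIR_CONST = 1.25e-3
PAIR_THRESHOLD_MEV = 2.0 * M_EC2_MEV

# energy grids (eV), uniform in log
EGRID_N = np.geomspace(1.0e-3, 2.2e7, 700)
EGRID_G = np.geomspace(1.0e3, 2.2e7, 300)


class RandomState:
    """Seedable RNG driving all sampling (xorshift128+, one stream)."""

    def __init__(self, seed: int, stream: int = 0):
        self.state = _kernels.init_state(seed, stream)

    def uniform(self) -> float:
        return _kernels.rand(self.state)

    def uniform_array(self, n: int) -> np.ndarray:
        return np.array([_kernels.rand(self.state) for _ in range(n)])


# ----------------------------------------------------------------------------
# per-element channel tables
# ----------------------------------------------------------------------------

def _load_anchor_tables():
    el_anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    text = resources.files("neutronplan.data").joinpath("neutron_elastic.tsv").read_text()
    rows: dict[str, list[tuple[float, float]]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, e, s = line.split("\t")
        rows.setdefault(sym, []).append((float(e), float(s)))
    for sym, pts in rows.items():
        pts.sort()
        el_anchors[sym] = (np.array([p[0] for p in pts]), np.array([p[1] for p in pts]))
    cap: dict[str, tuple[float, float]] = {}
    text = resources.files("neutronplan.data").joinpath("neutron_capture.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, s2200, q = line.split("\t")
        cap[sym] = (float(s2200), float(q))
    return el_anchors, cap


_ELASTIC_ANCHORS, _CAPTURE_DATA = _load_anchor_tables()


def sigma_elastic(symbol: str, energy_ev) -> np.ndarray:
    """Microscopic elastic cross section (barn), log-log anchor interpolation."""
    e_pts, s_pts = _ELASTIC_ANCHORS[symbol]
    return np.exp(np.interp(np.log(energy_ev), np.log(e_pts), np.log(s_pts)))


def sigma_capture(symbol: str, energy_ev) -> np.ndarray:
    """Microscopic radiative-capture cross section (barn), strict 1/v."""
    s2200, _q = _CAPTURE_DATA[symbol]
    return s2200 * np.sqrt(0.0253 / np.asarray(energy_ev, dtype=float))


def capture_q_ev(symbol: str) -> float:
    return _CAPTURE_DATA[symbol][1] * 1.0e6


@dataclass
class NeutronChannelTable:
    """Per-element neutron channel data on the common energy grid."""

    symbol: str
    energy_ev: np.ndarray
    elastic_barn: np.ndarray
    capture_barn: np.ndarray
    capture_gamma_mev: float
    capture_multiplicity: int  # 1 for H (emitted), 0 otherwise (local deposit)


@dataclass
class PhotonChannelTable:
    """Per-element photon channel data on the common energy grid."""

    symbol: str
    energy_ev: np.ndarray
    compton_barn: np.ndarray
    photoelectric_barn: np.ndarray
    pair_barn: np.ndarray


def neutron_channel_table(symbol: str) -> NeutronChannelTable:
    el = sigma_elastic(symbol, EGRID_N)
    cap = sigma_capture(symbol, EGRID_N)
    q = _CAPTURE_DATA[symbol][1]
    return NeutronChannelTable(symbol, EGRID_N.copy(), el, cap, q,
                               1 if symbol == "H" else 0)


def klein_nishina_total(energy_mev) -> np.ndarray:
    """Total Compton cross section per electron (barn), Klein-Nishina."""
    k = np.asarray(energy_mev, dtype=float) / M_EC2_MEV
    k = np.maximum(k, 1.0e-9)
    pre = 2.0 * np.pi * R_E_CM**2 / BARN
    t1 = (1.0 + k) / k**2 * (2.0 * (1.0 + k) / (1.0 + 2.0 * k) - np.log1p(2.0 * k) / k)
    t2 = np.log1p(2.0 * k) / (2.0 * k)
    t3 = (1.0 + 3.0 * k) / (1.0 + 2.0 * k) ** 2
    return pre * (t1 + t2 - t3)


def sigma_photoelectric(Z: int, energy_mev) -> np.ndarray:
    return PE_CONST * Z**4.5 / np.asarray(energy_mev, dtype=float) ** 3


def sigma_pair(Z: int, energy_mev) -> np.ndarray:
    e = np.asarray(energy_mev, dtype=float)
    return np.where(e > PAIR_THRESHOLD_MEV,
                    PAIR_CONST * Z**2 * np.log(np.maximum(e / PAIR_THRESHOLD_MEV, 1.0)),
                    0.0)


def photon_channel_table(symbol: str) -> PhotonChannelTable:
    Z = ELEMENTS[symbol].Z
    e_mev = EGRID_G / 1.0e6
    return PhotonChannelTable(symbol, EGRID_G.copy(),
                              Z * klein_nishina_total(e_mev),
                              sigma_photoelectric(Z, e_mev),
                              sigma_pair(Z, e_mev))


# ----------------------------------------------------------------------------
# sampling and cross-section operations
# ----------------------------------------------------------------------------

def macroscopic_xs(material: Material, energy_ev: float, particle_kind: str) -> dict[str, float]:
    """Macroscopic cross sections (1/cm) per channel plus their total.

    Sigma_channel = sum_i N_i sigma_i(E).  Raises for energies outside the
    packaged table range.
    """
    if particle_kind not in ("neutron", "photon"):
        raise ValueError(f"unknown particle kind {particle_kind!r}")
    grid = EGRID_N if particle_kind == "neutron" else EGRID_G
    if not (grid[0] <= energy_ev <= grid[-1]):
        raise ValueError(
            f"energy {energy_ev} eV outside table range [{grid[0]}, {grid[-1]}]")
    if material.is_vacuum:
        keys = ("elastic", "capture") if particle_kind == "neutron" else (
            "compton", "photoelectric", "pair")
        out = {k: 0.0 for k in keys}
        out["total"] = 0.0
        return out
    nd = material.number_densities()
    if particle_kind == "neutron":
        el = sum(n * float(sigma_elastic(s, energy_ev)) for s, n in nd.items()) * BARN
        cap = sum(n * float(sigma_capture(s, energy_ev)) for s, n in nd.items()) * BARN
        return {"elastic": el, "capture": cap, "total": el + cap}
    e_mev = energy_ev / 1.0e6
    co = sum(n * ELEMENTS[s].Z for s, n in nd.items()) * float(
        klein_nishina_total(e_mev)) * BARN
    pe = sum(n * float(sigma_photoelectric(ELEMENTS[s].Z, e_mev)) for s, n in nd.items()) * BARN
    pr = sum(n * float(sigma_pair(ELEMENTS[s].Z, e_mev)) for s, n in nd.items()) * BARN
    return {"compton": co, "photoelectric": pe, "pair": pr, "total": co + pe + pr}


def sample_channel(rng: RandomState, channel_sigma: dict[str, float]) -> str:
    """Draw a channel label with probability Sigma_c / Sigma_total."""
    channels = [(k, v) for k, v in channel_sigma.items() if k != "total"]
    total = sum(v for _k, v in channels)
    if total <= 0.0:
        raise ValueError("all channel cross sections are zero")
    xi = rng.uniform() * total
    acc = 0.0
    for k, v in channels:
        acc += v
        if xi < acc:
            return k
    return channels[-1][0]


def elastic_scatter(energy_ev: float, A: float, rng: RandomState,
                    thermal_cutoff: float = THERMAL_CUTOFF_EV,
                    kT_ev: float = KT_300K_EV) -> tuple[float, float]:
    """Elastic scattering: returns (outgoing energy eV, lab cosine).

    Stationary-target kinematics with isotropic CM above ``thermal_cutoff``;
    300 K free-gas target motion below it.
    """
    if energy_ev <= 0.0:
        raise ValueError("energy must be > 0")
    if A < 1.0:
        raise ValueError("mass number must be >= 1")
    if energy_ev < thermal_cutoff:
        e2, nx, _ny, _nz = _kernels.elastic_free_gas(
            energy_ev, 1.0, 0.0, 0.0, A, kT_ev, rng.state)
    else:
        e2, nx, _ny, _nz = _kernels.elastic_asymptotic(
            energy_ev, 1.0, 0.0, 0.0, A, rng.state)
    return e2, nx


def capture(energy_ev: float, element: str, rng: RandomState):
    """Radiative capture: list of secondary photons (energy eV, unit dir).

    Hydrogen emits one isotropic 2.2246 MeV gamma; for other elements the
    gamma energy deposits locally and the list is empty.
    """
    if element == "H":
        d = _kernels.isotropic_dir(rng.state)
        return [(H_CAPTURE_GAMMA_MEV * 1.0e6, d)]
    return []


def compton_sample(energy_mev: float, rng: RandomState) -> tuple[float, float, float]:
    """Klein-Nishina sample: (scattered photon E', electron T, angle theta)."""
    if energy_mev <= 0.0:
        raise ValueError("energy must be > 0")
    eps = _kernels.compton_sample_eps(energy_mev * 1.0e6, rng.state)
    e_out = energy_mev * eps
    t = energy_mev - e_out
    k = energy_mev / M_EC2_MEV
    mu = 1.0 - (1.0 / eps - 1.0) / k
    mu = min(1.0, max(-1.0, mu))
    return e_out, t, float(np.arccos(mu))


def compton_scattered_energy(energy_mev: float, theta: float) -> float:
    """Deterministic Compton formula E' = E / (1 + (E/mc^2)(1 - cos theta))."""
    return energy_mev / (1.0 + energy_mev / M_EC2_MEV * (1.0 - np.cos(theta)))


# ----------------------------------------------------------------------------
# packed tables for the transport kernel
# ----------------------------------------------------------------------------

@dataclass
class PackedPhysics:
    """Flat cross-section arrays on uniform-log grids for the kernel."""

    materials: list[Material]         # kernel index -> material (0 is vacuum)
    index_of: dict[int, int]          # material_id -> kernel index
    lnE0_n: float
    dln_n: float
    sig_el: np.ndarray                # (n_mat, max_elem, ng_n) macroscopic, 1/cm
    sig_cap: np.ndarray
    sig_tot_n: np.ndarray             # (n_mat, ng_n)
    elem_count: np.ndarray            # (n_mat,)
    elem_A: np.ndarray                # (n_mat, max_elem) atomic mass
    elem_isH: np.ndarray              # (n_mat, max_elem) uint8
    elem_Q: np.ndarray                # (n_mat, max_elem) capture Q, eV
    lnE0_g: float
    dln_g: float
    sig_co: np.ndarray                # (n_mat, ng_g)
    sig_pe: np.ndarray
    sig_pr: np.ndarray
    sig_tot_g: np.ndarray


def build_packed_physics(materials: list[Material]) -> PackedPhysics:
    """Precompute macroscopic cross sections for a list of materials.

    The first entry must be the vacuum material (kernel index 0).
    """
    if not materials[0].is_vacuum:
        raise ValueError("kernel material slot 0 must be vacuum")
    n_mat = len(materials)
    ng_n = EGRID_N.size
    ng_g = EGRID_G.size
    max_elem = max((len(m.mass_fraction) for m in materials), default=1) or 1
    sig_el = np.zeros((n_mat, max_elem, ng_n))
    sig_cap = np.zeros((n_mat, max_elem, ng_n))
    elem_count = np.zeros(n_mat, dtype=np.int64)
    elem_A = np.ones((n_mat, max_elem))
    elem_isH = np.zeros((n_mat, max_elem), dtype=np.uint8)
    elem_Q = np.zeros((n_mat, max_elem))
    sig_co = np.zeros((n_mat, ng_g))
    sig_pe = np.zeros((n_mat, ng_g))
    sig_pr = np.zeros((n_mat, ng_g))
    e_mev = EGRID_G / 1.0e6
    kn = klein_nishina_total(e_mev)
    for mi, mat in enumerate(materials):
        if mat.is_vacuum:
            continue
        nd = mat.number_densities()
        # sort: hydrogen first so channel walk order is deterministic
        symbols = sorted(nd, key=lambda s: ELEMENTS[s].Z)
        elem_count[mi] = len(symbols)
        for j, sym in enumerate(symbols):
            n_i = nd[sym]
            sig_el[mi, j] = n_i * sigma_elastic(sym, EGRID_N) * BARN
            sig_cap[mi, j] = n_i * sigma_capture(sym, EGRID_N) * BARN
            elem_A[mi, j] = ELEMENTS[sym].A_r
            elem_isH[mi, j] = 1 if sym == "H" else 0
            elem_Q[mi, j] = capture_q_ev(sym)
            Z = ELEMENTS[sym].Z
            sig_co[mi] += n_i * Z * kn * BARN
            sig_pe[mi] += n_i * sigma_photoelectric(Z, e_mev) * BARN
            sig_pr[mi] += n_i * sigma_pair(Z, e_mev) * BARN
    sig_tot_n = sig_el.sum(axis=1) + sig_cap.sum(axis=1)
    sig_tot_g = sig_co + sig_pe + sig_pr
    lnE0_n = float(np.log(EGRID_N[0]))
    dln_n = float(np.log(EGRID_N[1] / EGRID_N[0]))
    lnE0_g = float(np.log(EGRID_G[0]))
    dln_g = float(np.log(EGRID_G[1] / EGRID_G[0]))
    return PackedPhysics(
        materials=list(materials),
        index_of={m.material_id: i for i, m in enumerate(materials)},
        lnE0_n=lnE0_n, dln_n=dln_n,
        sig_el=sig_el, sig_cap=sig_cap, sig_tot_n=sig_tot_n,
        elem_count=elem_count, elem_A=elem_A, elem_isH=elem_isH, elem_Q=elem_Q,
        lnE0_g=lnE0_g, dln_g=dln_g,
        sig_co=sig_co, sig_pe=sig_pe, sig_pr=sig_pr, sig_tot_g=sig_tot_g,
    )
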