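"""Monte Carlo transport driver.

Histories are processed one primary at a time with an analog (weight-1)
random walk: piecewise-exponential free flights across material boundaries
(surface tracking; Woodcock delta tracking available as an option), elastic
scattering / capture for neutrons, Compton / photoelectric / pair production
for photons, and a LIFO secondary stack.  Charged-particle energy deposits
locally (kerma approximation) with a particle tag, which realises the
per-particle dose separation of the scorers.

Each history owns an independent, counter-seeded RNG stream, so runs are
bit-reproducible for a given (seed, n_histories) and two runs with the same
seed share their primaries (useful for paired geometry comparisons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import Geometry
from .physics import PackedPhysics, RandomState, build_packed_physics
from .spectra import BeamConfig, build_cdf

__all__ = [
    "ParticleState",
    "TransportConfig",
    "RunResult",
    "TAG_NAMES",
    "free_flight",
    "traverse",
    "transport_history",
    "run",
]

TAG_NAMES = ("proton", "neutron", "electron_n", "electron_g")

FLUENCE_N_BINS = 58
FLUENCE_EDGES_EV = np.geomspace(1.0e-3, 2.0e7, FLUENCE_N_BINS + 1)


@dataclass
class ParticleState:
    """Phase-space state of one particle."""

    kind: str                                   # "neutron" | "photon"
    position: tuple[float, float, float]        # cm
    direction: tuple[float, float, float]       # unit vector
    energy_ev: float
    weight: float = 1.0
    history: int = 0

    def __post_init__(self) -> None:
        norm = math.sqrt(sum(c * c for c in self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"direction norm {norm} != 1")
        if self.energy_ev <= 0:
            raise ValueError("energy must be > 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


@dataclass
class TransportConfig:
    """Run controls: histories, seed, cutoffs, tracking options."""

    n_histories: int = 1000
    seed: int = 1
    neutron_cutoff_ev: float = 0.01   # remaining energy deposits locally
    photon_cutoff_ev: float = 1.0e4
    thermal_cutoff_ev: float = 4.0    # free-gas target motion below this
    kT_ev: float = _kernels.KT_300K_EV
    woodcock: bool = False
    fluence: bool = False             # energy-binned track-length tally
    record_audit: bool = False        # per-history energy bookkeeping
    record_events: bool = False       # per-deposit event log (small runs)
    log_in_bin: bool = False          # within-bin energy sampling law
    history_offset: int = 0           # global index of the first history

    def __post_init__(self) -> None:
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")
        if self.neutron_cutoff_ev < 0 or self.photon_cutoff_ev < 0:
            raise ValueError("cutoffs must be >= 0")


@dataclass
class RunResult:
    """Raw history-by-history tallies of one run (energies in eV)."""

    sum_x: np.ndarray                # (n_regions, n_tags) sum of per-history deposits
    sum_x2: np.ndarray               # (n_regions, n_tags)
    n_histories: int
    seed: int
    beam_area_cm2: float
    region_mass_g: np.ndarray
    region_volume_cm3: np.ndarray
    e_source_ev: float
    q_released_ev: float
    e_deposited_ev: float
    e_escaped_ev: float
    audit: np.ndarray | None = None  # (n_hist, 4): source, Q, deposited, escaped
    fl_sum: np.ndarray | None = None     # (n_fl_regions, 58) track length cm
    fl_sum2: np.ndarray | None = None
    fl_edges_ev: np.ndarray | None = None
    events: list | None = None
    geometry_description: str = ""
    grid_shape: tuple[int, int, int] | None = None

    def dose_grid_shape(self):
        return self.grid_shape


def free_flight(sigma_total: float, rng: RandomState) -> float:
    """Exponential free-flight length (cm); infinite in vacuum."""
    if sigma_total < 0:
        raise ValueError("macroscopic cross section must be >= 0")
    if sigma_total == 0.0:
        return math.inf
    return -math.log(rng.uniform()) / sigma_total


def traverse(position, direction, grid_shape, origin, voxel_size):
    """Ordered (voxel index, chord length) walk of a ray through a grid."""
    norm = math.sqrt(sum(c * c for c in direction))
    if norm < 1e-12:
        raise ValueError("degenerate zero direction")
    u = tuple(c / norm for c in direction)
    gn = np.asarray(grid_shape, dtype=np.int64)
    cap = int(2 * (gn.sum()) + 8)
    out_idx = np.zeros(cap, dtype=np.int64)
    out_len = np.zeros(cap, dtype=np.float64)
    n = _kernels.traverse_grid(position[0], position[1], position[2],
                               u[0], u[1], u[2], gn,
                               np.asarray(origin, dtype=float),
                               np.asarray(voxel_size, dtype=float),
                               out_idx, out_len)
    nyz = gn[1] * gn[2]
    ijk = [(int(f // nyz), int((f % nyz) // gn[2]), int(f % gn[2]))
           for f in out_idx[:n]]
    return ijk, out_len[:n].copy()


_DUMMY_EDGES = np.array([1.0, 2.0])
_DUMMY_CUM = np.array([1.0])


def _kernel_args(config: TransportConfig, beam: BeamConfig | None,
                 geometry: Geometry, physics: PackedPhysics,
                 fixed: ParticleState | None):
    if beam is not None:
        p_neutron = beam.neutron_probability
        if beam.neutron_spectrum is not None:
            tn = build_cdf(beam.neutron_spectrum, config.log_in_bin)
            edges_n, cum_n = tn.edges_ev, tn.cum
        else:
            edges_n, cum_n = _DUMMY_EDGES, _DUMMY_CUM
        if beam.photon_spectrum is not None:
            tg = build_cdf(beam.photon_spectrum, config.log_in_bin)
            edges_g, cum_g = tg.edges_ev, tg.cum
        else:
            edges_g, cum_g = _DUMMY_EDGES, _DUMMY_CUM
        cx, cy, cz = beam.center
        src_x = cx if cx != 0.0 else geometry.source_x
        ylo, yhi = cy - beam.width / 2, cy + beam.width / 2
        zlo, zhi = cz - beam.height / 2, cz + beam.height / 2
        area = beam.area
    else:
        p_neutron = 1.0
        edges_n = edges_g = _DUMMY_EDGES
        cum_n = cum_g = _DUMMY_CUM
        src_x = ylo = yhi = zlo = zhi = 0.0
        area = 1.0
    if fixed is not None:
        fx = (True, _kernels.NEUTRON if fixed.kind == "neutron" else _kernels.PHOTON,
              fixed.energy_ev, *fixed.position, *fixed.direction)
    else:
        fx = (False, 0, 1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0)

    maj_n = physics.sig_tot_n.max(axis=0)
    maj_g = physics.sig_tot_g.max(axis=0)

    ch = geometry.chambers
    if geometry.score_mode == 0 and ch is not None:
        cham = (ch.first_depth, ch.pitch, ch.count, ch.radius, ch.half_height)
    else:
        cham = (0.0, 1.0, 0, 0.0, 0.0)

    if config.fluence:
        fl_mode = 1 if geometry.score_mode == 0 else 2
        n_fl = geometry.n_regions
    else:
        fl_mode = 0
        n_fl = 1
    fl_lnE0 = float(np.log(FLUENCE_EDGES_EV[0]))
    fl_dln = float(np.log(FLUENCE_EDGES_EV[-1] / FLUENCE_EDGES_EV[0])) / FLUENCE_N_BINS

    return dict(
        src=(p_neutron, edges_n, cum_n, edges_g, cum_g, config.log_in_bin,
             src_x, ylo, yhi, zlo, zhi, *fx),
        fl=(fl_mode, fl_lnE0, fl_dln, FLUENCE_N_BINS, n_fl),
        cham=cham, maj=(maj_n, maj_g), area=area,
    )


def _execute(config: TransportConfig, beam, geometry: Geometry,
             physics: PackedPhysics | None = None,
             fixed: ParticleState | None = None) -> RunResult:
    physics = physics or build_packed_physics(geometry.materials)
    a = _kernel_args(config, beam, geometry, physics, fixed)
    n_reg = geometry.n_regions
    sum_x = np.zeros(n_reg * _kernels.N_TAGS)
    sum_x2 = np.zeros(n_reg * _kernels.N_TAGS)
    fl_mode = a["fl"][0]
    n_fl = a["fl"][4]
    fl_sum = np.zeros(n_fl * FLUENCE_N_BINS if fl_mode else 1)
    fl_sum2 = np.zeros_like(fl_sum)
    audit = np.zeros((config.n_histories if config.record_audit else 1, 4))
    cap = max(500000, 12 * config.n_histories) if config.record_events else 1
    events = np.zeros((cap, 5))  # region, tag, energy, x, history

    e_src, q_rel, e_dep, e_esc, n_ev = _kernels.run_histories(
        config.n_histories, config.history_offset, config.seed,
        *a["src"],
        physics.lnE0_n, physics.dln_n, physics.sig_el, physics.sig_cap,
        physics.sig_tot_n,
        physics.elem_count, physics.elem_A, physics.elem_isH, physics.elem_Q,
        physics.lnE0_g, physics.dln_g, physics.sig_co, physics.sig_pe,
        physics.sig_pr, physics.sig_tot_g,
        config.neutron_cutoff_ev, config.photon_cutoff_ev,
        config.thermal_cutoff_ev, config.kT_ev,
        config.woodcock, a["maj"][0], a["maj"][1],
        geometry.boxes_lo, geometry.boxes_hi, geometry.box_mat,
        geometry.grid_mat, geometry.gn, geometry.gorigin, geometry.gvoxel,
        geometry.score_mode, *a["cham"],
        geometry.region_map, n_reg,
        *a["fl"],
        sum_x, sum_x2, fl_sum, fl_sum2, audit, config.record_audit,
        events, cap, config.record_events,
    )
    ev_list = None
    if config.record_events:
        ev_list = [(int(events[i, 0]), TAG_NAMES[int(events[i, 1])], events[i, 2],
                    events[i, 3], int(events[i, 4])) for i in range(n_ev)]
    return RunResult(
        sum_x=sum_x.reshape(n_reg, _kernels.N_TAGS),
        sum_x2=sum_x2.reshape(n_reg, _kernels.N_TAGS),
        n_histories=config.n_histories,
        seed=config.seed,
        beam_area_cm2=a["area"],
        region_mass_g=geometry.region_mass_g,
        region_volume_cm3=geometry.region_volume_cm3,
        e_source_ev=e_src, q_released_ev=q_rel,
        e_deposited_ev=e_dep, e_escaped_ev=e_esc,
        audit=audit if config.record_audit else None,
        fl_sum=fl_sum.reshape(n_fl, FLUENCE_N_BINS) if fl_mode else None,
        fl_sum2=fl_sum2.reshape(n_fl, FLUENCE_N_BINS) if fl_mode else None,
        fl_edges_ev=FLUENCE_EDGES_EV.copy() if fl_mode else None,
        events=ev_list,
        geometry_description=geometry.description,
        grid_shape=geometry.grid_shape,
    )


def transport_history(primary: ParticleState, geometry: Geometry,
                      config: TransportConfig | None = None,
                      physics: PackedPhysics | None = None):
    """Transport a single given primary; returns (deposits, result).

    ``deposits`` is a list of (region index, particle tag, energy eV) in
    deposition order (region -1 = outside any scoring region); the result
    carries the energy audit for the history.
    """
    config = config or TransportConfig()
    cfg = TransportConfig(
        n_histories=1, seed=config.seed,
        neutron_cutoff_ev=config.neutron_cutoff_ev,
        photon_cutoff_ev=config.photon_cutoff_ev,
        thermal_cutoff_ev=config.thermal_cutoff_ev, kT_ev=config.kT_ev,
        woodcock=config.woodcock, record_audit=True, record_events=True,
        history_offset=config.history_offset)
    res = _execute(cfg, None, geometry, physics, fixed=primary)
    deposits = [(r, t, e) for r, t, e, _x, _h in res.events]
    return deposits, res


def run(config: TransportConfig, beam: BeamConfig, geometry: Geometry,
        physics: PackedPhysics | None = None,
        progress=None, n_chunks: int = 10) -> RunResult:
    """Run ``config.n_histories`` primaries of ``beam`` through ``geometry``.

    With a ``progress`` callback the run is split into chunks; per-history
    RNG streams are indexed globally, so chunked results match a single run
    up to floating-point summation order.  ``progress(done, total)`` is
    called after each chunk.
    """
    if progress is None or config.n_histories < n_chunks:
        return _execute(config, beam, geometry, physics)
    physics = physics or build_packed_physics(geometry.materials)
    total = config.n_histories
    edges = np.linspace(0, total, n_chunks + 1).astype(int)
    merged: RunResult | None = None
    for c in range(n_chunks):
        n_c = int(edges[c + 1] - edges[c])
        if n_c == 0:
            continue
        cfg = TransportConfig(
            n_histories=n_c, seed=config.seed,
            neutron_cutoff_ev=config.neutron_cutoff_ev,
            photon_cutoff_ev=config.photon_cutoff_ev,
            thermal_cutoff_ev=config.thermal_cutoff_ev, kT_ev=config.kT_ev,
            woodcock=config.woodcock, fluence=config.fluence,
            log_in_bin=config.log_in_bin,
            history_offset=config.history_offset + int(edges[c]))
        part = _execute(cfg, beam, geometry, physics)
        merged = part if merged is None else _merge(merged, part)
        progress(int(edges[c + 1]), total)
    merged.n_histories = total
    return merged


def _merge(a: RunResult, b: RunResult) -> RunResult:
    a.sum_x = a.sum_x + b.sum_x
    a.sum_x2 = a.sum_x2 + b.sum_x2
    a.n_histories += b.n_histories
    a.e_source_ev += b.e_source_ev
    a.q_released_ev += b.q_released_ev
    a.e_deposited_ev += b.e_deposited_ev
    a.e_escaped_ev += b.e_escaped_ev
    if a.fl_sum is not None and b.fl_sum is not None:
        a.fl_sum = a.fl_sum + b.fl_sum
        a.fl_sum2 = a.fl_sum2 + b.fl_sum2
    return a
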