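"""Shared fixtures: geometries, spectra and session-scoped reference runs.

The heavier Monte Carlo runs are session-scoped so acceptance checks and
unit tests share them instead of re-running the engine.
"""

from __future__ import annotations

import numpy as np
import pytest

import neutronplan as npl
from neutronplan.geometry import ChamberArray, Geometry
from neutronplan.spectra import EnergySpectrum
from neutronplan.transport import TransportConfig, run


@pytest.fixture(scope="session")
def mat_table():
    return npl.load_materials()


@pytest.fixture(scope="session")
def nspec():
    return npl.synthetic_medapp_spectrum("neutron", 3.2e8)


@pytest.fixture(scope="session")
def gspec():
    return npl.synthetic_medapp_spectrum("photon", 2.9e8)


@pytest.fixture(scope="session")
def beam9n(nspec):
    return npl.BeamConfig(9.0, 9.0, neutron_spectrum=nspec)


@pytest.fixture(scope="session")
def solid_geo(mat_table):
    return npl.build_solid_water_geometry(mat_table)


@pytest.fixture(scope="session")
def voxel_geo(mat_table):
    return npl.build_voxel_water_geometry(mat_table)


@pytest.fixture(scope="session")
def solid_run(solid_geo, beam9n):
    """Reference solid-box neutron run, 2e5 histories."""
    return run(TransportConfig(n_histories=200_000, seed=11), beam9n, solid_geo)


@pytest.fixture(scope="session")
def voxel_run(voxel_geo, beam9n):
    """Voxelised-box neutron run with the same seed (shared primaries)."""
    return run(TransportConfig(n_histories=200_000, seed=11), beam9n, voxel_geo)


@pytest.fixture(scope="session")
def room_pair(mat_table, beam9n):
    """Paired runs with/without the concrete room (common random numbers)."""
    free = npl.build_solid_water_geometry(mat_table)
    roomed = npl.build_solid_water_geometry(mat_table, room=npl.RoomShell())
    cfg = TransportConfig(n_histories=200_000, seed=21)
    return run(cfg, beam9n, free), run(cfg, beam9n, roomed)


def monoenergetic(kind: str, energy_ev: float) -> EnergySpectrum:
    """Single-bin spectrum (degenerate, for analytic-oracle beams)."""
    return EnergySpectrum(kind, np.array([energy_ev, energy_ev * (1 + 1e-9)]),
                          np.array([1.0]))


def make_slab_geometry(mat_table, slabs, half_width=200.0):
    """Nested-box geometry of x-slabs (material name, x0, x1), air world.

    Scoring uses a single dummy chamber far outside the slabs, so all
    deposits land in region -1; these geometries exist for event-level
    oracles (collision depths), not for dose scoring.
    """
    names = [name for name, _x0, _x1 in slabs]
    mats = [mat_table[0]] + [mat_table[n] for n in dict.fromkeys(names)] + [mat_table[5]]
    index = {m.name: i for i, m in enumerate(mats)}
    nb = len(slabs) + 1
    lo = np.zeros((nb, 3))
    hi = np.zeros((nb, 3))
    bm = np.zeros(nb, dtype=np.int32)
    for i, (name, x0, x1) in enumerate(slabs):
        lo[i] = (x0, -half_width, -half_width)
        hi[i] = (x1, half_width, half_width)
        bm[i] = index[name]
    lo[-1] = (-50.0, -half_width - 50, -half_width - 50)
    hi[-1] = (slabs[-1][2] + 50.0, half_width + 50, half_width + 50)
    bm[-1] = index["air"]
    return Geometry(
        materials=mats, boxes_lo=lo, boxes_hi=hi, box_mat=bm,
        grid_mat=np.zeros(1, dtype=np.int16),
        gn=np.array([1, 1, 1], dtype=np.int64),
        gorigin=np.zeros(3), gvoxel=np.ones(3),
        score_mode=0, chambers=ChamberArray(first_depth=1.0e6, count=1),
        region_map=np.zeros(1, dtype=np.int32), n_regions=1,
        region_mass_g=np.array([1.0]), region_volume_cm3=np.array([1.0]),
        source_x=-10.0, description="slab stack")


@pytest.fixture(scope="session")
def pencil_water_events(mat_table):
    """2.2246 MeV photon pencil beam into thick water; event log."""
    geo = make_slab_geometry(mat_table, [("water", 0.0, 120.0)])
    beam = npl.BeamConfig(1e-6, 1e-6,
                          photon_spectrum=monoenergetic("photon", 2.2246e6))
    cfg = TransportConfig(n_histories=100_000, seed=31, record_events=True)
    return run(cfg, beam, geo)


@pytest.fixture(scope="session")
def small_head():
    phantom, rois = npl.synthetic_head_phantom(
        seed=3, shape=(48, 44, 64), voxel_size=(0.35, 0.35, 0.6))
    return phantom, rois
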