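"""Transport kernel: traversal, free flights, histories, reproducibility."""

import numpy as np
import pytest
from scipy import stats

import neutronplan as npl
from neutronplan.physics import RandomState, macroscopic_xs
from neutronplan.tallies import finalize_dose
from neutronplan.transport import (ParticleState, TransportConfig, free_flight,
                                   run, transport_history, traverse)

from conftest import make_slab_geometry, monoenergetic


class TestTraverse:
    def test_axis_aligned_uniform_steps(self):
        ijk, lengths = traverse((-1.0, 0.5, 0.5), (1, 0, 0), (10, 5, 5),
                                (0.0, 0.0, 0.0), (0.2, 0.2, 0.2))
        assert len(ijk) == 10
        assert np.allclose(lengths, 0.2, atol=1e-6)
        assert [i for i, _j, _k in ijk] == list(range(10))

    def test_chord_sums_match_analytic_box_chord(self):
        """Random rays: traversed path sums equal the ray-box chord length."""
        rng = np.random.default_rng(4)
        gn = (20, 15, 12)
        voxel = (0.3, 0.4, 0.5)
        hi = np.array(gn) * np.array(voxel)
        for _ in range(1000):
            origin = rng.uniform(-3, -1, 3)
            target = rng.uniform(0.2, 0.8, 3) * hi
            d = target - origin
            d /= np.linalg.norm(d)
            # analytic chord: slab intersection of the grid AABB
            t1 = (0 - origin) / d
            t2 = (hi - origin) / d
            tmin = np.minimum(t1, t2).max()
            tmax = np.maximum(t1, t2).min()
            chord = max(0.0, tmax - tmin)
            _ijk, lengths = traverse(origin, d, gn, (0, 0, 0), voxel)
            assert lengths.sum() == pytest.approx(chord, rel=1e-6, abs=1e-5)

    def test_ray_missing_grid_is_empty(self):
        ijk, lengths = traverse((-1.0, 50.0, 0.5), (1, 0, 0), (10, 5, 5),
                                (0.0, 0.0, 0.0), (0.2, 0.2, 0.2))
        assert len(ijk) == 0

    def test_zero_direction_raises(self):
        with pytest.raises(ValueError):
            traverse((0, 0, 0), (0, 0, 0), (2, 2, 2), (0, 0, 0), (1, 1, 1))


class TestFreeFlight:
    def test_empirical_mean_is_inverse_sigma(self):
        rng = RandomState(1)
        sigma = 0.7
        n = 100_000
        flights = np.array([free_flight(sigma, rng) for _ in range(n)])
        # exponential: mean 1/sigma, sd 1/sigma
        assert abs(flights.mean() - 1 / sigma) < 3 / (sigma * np.sqrt(n))

    def test_vacuum_never_collides(self):
        assert free_flight(0.0, RandomState(2)) == np.inf

    def test_negative_sigma_raises(self):
        with pytest.raises(ValueError):
            free_flight(-1.0, RandomState(3))

    def test_two_slab_first_collision_depth_piecewise_exponential(self, mat_table):
        """Collision depths across a water|Perspex boundary follow the
        piecewise-exponential law with the correct optical-depth carry-over."""
        e0 = 1.0e6
        geo = make_slab_geometry(mat_table, [("water", 0.0, 3.0),
                                             ("perspex", 3.0, 40.0)])
        s1 = macroscopic_xs(mat_table["water"], e0, "photon")["total"]
        s2 = macroscopic_xs(mat_table["perspex"], e0, "photon")["total"]
        beam = npl.BeamConfig(1e-6, 1e-6,
                              photon_spectrum=monoenergetic("photon", e0))
        res = run(TransportConfig(n_histories=20_000, seed=17,
                                  record_events=True), beam, geo)
        first = {}
        for _reg, _tag, _e, x, h in res.events:
            if h not in first:
                first[h] = x
        depths = np.array(sorted(first.values()))
        # condition on the first collision happening inside the slab stack
        # (the surrounding air interacts with ~1e-4 probability)
        depths = depths[(depths >= 0.0) & (depths < 40.0)]

        def cdf(x):
            x = np.asarray(x)
            tau = np.where(x < 3.0, s1 * x, 3.0 * s1 + (x - 3.0) * s2)
            return -np.expm1(-tau) / -np.expm1(-(3 * s1 + 37 * s2))

        d = stats.kstest(depths, cdf)
        assert d.pvalue > 0.01


class TestHistories:
    def test_per_history_energy_audit(self, solid_geo, beam9n):
        cfg = TransportConfig(n_histories=5000, seed=41, record_audit=True)
        res = run(cfg, beam9n, solid_geo)
        a = res.audit
        imbalance = np.abs(a[:, 0] + a[:, 1] - a[:, 2] - a[:, 3]) / (a[:, 0] + a[:, 1])
        assert imbalance.max() < 1e-6

    def test_primary_missing_phantom_deposits_nothing(self, solid_geo):
        p = ParticleState("neutron", (-5.0, 100.0, 100.0), (0.0, 0.0, 1.0), 2.0e6)
        deposits, res = transport_history(p, solid_geo)
        assert all(reg < 0 for reg, _t, _e in deposits)
        assert res.sum_x.sum() == 0.0

    def test_neutron_history_produces_capture_photons(self, solid_geo):
        """Capture frequency rises when the cutoff lets neutrons thermalise."""
        spec = npl.synthetic_medapp_spectrum("neutron", 3.2e8)
        beam = npl.BeamConfig(9.0, 9.0, neutron_spectrum=spec)
        lo = run(TransportConfig(n_histories=5000, seed=43,
                                 neutron_cutoff_ev=0.01), beam, solid_geo)
        hi = run(TransportConfig(n_histories=5000, seed=43,
                                 neutron_cutoff_ev=5.0), beam, solid_geo)
        assert lo.q_released_ev > hi.q_released_ev > 0

    def test_same_seed_bit_identical(self, solid_geo, beam9n):
        cfg = TransportConfig(n_histories=20_000, seed=44)
        a = run(cfg, beam9n, solid_geo)
        b = run(cfg, beam9n, solid_geo)
        assert np.array_equal(a.sum_x, b.sum_x)
        assert np.array_equal(a.sum_x2, b.sum_x2)
        assert a.e_deposited_ev == b.e_deposited_ev

    def test_chunked_run_matches_single_run(self, solid_geo, beam9n):
        """Chunked execution reuses the same per-history streams; results
        agree up to floating-point summation order."""
        cfg = TransportConfig(n_histories=20_000, seed=44)
        single = run(cfg, beam9n, solid_geo)
        chunked = run(cfg, beam9n, solid_geo, progress=lambda d, t: None)
        assert np.allclose(single.sum_x, chunked.sum_x, rtol=1e-12)
        assert np.allclose(single.sum_x2, chunked.sum_x2, rtol=1e-12)
        assert single.n_histories == chunked.n_histories

    def test_different_seeds_statistically_consistent(self, solid_geo, beam9n):
        a = finalize_dose(run(TransportConfig(n_histories=50_000, seed=1),
                              beam9n, solid_geo))
        b = finalize_dose(run(TransportConfig(n_histories=50_000, seed=2),
                              beam9n, solid_geo))
        da, sa = a.tagged("proton", "neutron")
        db, sb = b.tagged("proton", "neutron")
        z = np.abs(da[:10] - db[:10]) / np.sqrt(sa[:10] ** 2 + sb[:10] ** 2)
        assert (z < 3).all()

    def test_error_scales_inverse_sqrt_n(self, solid_geo, beam9n):
        ns = [2000, 20_000, 200_000]
        ses = []
        for n in ns:
            r = finalize_dose(run(TransportConfig(n_histories=n, seed=3),
                                  beam9n, solid_geo))
            ses.append(np.mean(r.total_se[:5] / r.total[:5]))
        slope = np.polyfit(np.log(ns), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.12)

    def test_global_energy_balance(self, solid_run):
        lhs = solid_run.e_source_ev + solid_run.q_released_ev
        rhs = solid_run.e_deposited_ev + solid_run.e_escaped_ev
        assert abs(lhs - rhs) / lhs < 1e-6


class TestWoodcock:
    def test_delta_tracking_matches_surface_tracking(self, voxel_geo, beam9n):
        """Woodcock and surface tracking agree within combined MC errors."""
        a = finalize_dose(run(TransportConfig(n_histories=60_000, seed=51),
                              beam9n, voxel_geo))
        b = finalize_dose(run(TransportConfig(n_histories=60_000, seed=52,
                                              woodcock=True), beam9n, voxel_geo))
        da, sa = a.tagged("proton", "neutron")
        db, sb = b.tagged("proton", "neutron")
        sel = slice(0, 8)  # shallow depths carry the statistics
        z = np.abs(da[sel] - db[sel]) / np.sqrt(sa[sel] ** 2 + sb[sel] ** 2)
        assert (z < 3.5).all()
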