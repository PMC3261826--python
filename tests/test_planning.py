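"""Planning analytics: depth dose, profiles, DVH, RBE, isodoses."""

import numpy as np
import pandas as pd
import pytest

from neutronplan.planning import (DVHCurve, RBEWeights, apply_rbe,
                                  cumulative_dvh, depth_dose, depth_dose_grid,
                                  edge_decrease, isodose_contours,
                                  lateral_profile, renormalize_photons,
                                  wall_influence)


class TestDepthDose:
    def test_uniform_grid_gives_flat_curve(self):
        dose = np.full((20, 8, 4), 3.0)
        df = depth_dose_grid(dose, np.zeros_like(dose), (0, -0.8, -1.0),
                             (0.2, 0.2, 0.5))
        assert np.allclose(df["dose"], 3.0)

    def test_chamber_table_depths(self):
        depths = 0.5 + np.arange(40)
        df = depth_dose(depths, np.ones(40))
        assert df["depth_cm"].iloc[0] == 0.5
        assert df["depth_cm"].iloc[-1] == 39.5

    def test_exponential_field_attenuation_length_recovered(self):
        """exp(-x / lambda) synthetic dose grid: fitted lambda within 2%."""
        lam = 12.0
        nx = 100
        x = (np.arange(nx) + 0.5) * 0.2
        dose = np.tile(np.exp(-x / lam)[:, None, None], (1, 8, 4))
        df = depth_dose_grid(dose, np.zeros_like(dose), (0, -0.8, -1.0),
                             (0.2, 0.2, 0.5))
        slope = np.polyfit(df["depth_cm"], np.log(df["dose"]), 1)[0]
        assert -1 / slope == pytest.approx(lam, rel=0.02)

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            depth_dose(np.array([]), np.array([]))


class TestLateralProfile:
    def test_uniform_field_flat(self):
        dose = np.full((5, 9, 3), 2.0)
        prof = lateral_profile(dose, np.zeros_like(dose), 1, 2)
        assert np.allclose(prof["dose"], 2.0)
        assert edge_decrease(prof, 0, 4) == pytest.approx(0.0)

    def test_edge_decrease_93_percent(self):
        dose = np.ones((3, 50, 3))
        dose[1, 39, 1] = 0.07
        dose[1, 41, 1] = 1.0
        prof = lateral_profile(dose, np.zeros_like(dose), 1, 1)
        assert edge_decrease(prof, 39, 41) == pytest.approx(93.0)

    def test_out_of_range_indices(self):
        dose = np.ones((3, 3, 3))
        with pytest.raises(IndexError):
            lateral_profile(dose, dose, 5, 0)


class TestDVH:
    def test_uniform_organ_steps_at_dose(self):
        dose = np.full((5, 5, 5), 2.0)
        mask = np.zeros_like(dose, dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        curve = cumulative_dvh(dose, mask, bin_width=0.1)
        assert curve.volume_at(0.0) == 1.0
        assert curve.volume_at(1.9) == 1.0
        assert curve.volume_at(2.15) == pytest.approx(0.0, abs=1e-9)
        assert curve.volume_fraction[-1] == 0.0

    def test_four_voxel_median(self):
        dose = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        curve = cumulative_dvh(dose, np.ones_like(dose, dtype=bool),
                               bin_width=0.5)
        assert curve.volume_at(2.5) == pytest.approx(0.5)

    def test_brute_force_equivalence_on_random_masks(self):
        rng = np.random.default_rng(7)
        dose = rng.gamma(2.0, 1.0, size=(10, 10, 10))
        for _ in range(5):
            mask = rng.random((10, 10, 10)) < 0.5
            curve = cumulative_dvh(dose, mask, bin_width=0.05)
            sel = dose[mask]
            for d in rng.uniform(0, dose.max(), 20):
                expected = (sel >= d).mean()
                assert curve.volume_at(d) == pytest.approx(expected, abs=0.02)

    def test_mean_dose_matches_integral_relation(self):
        rng = np.random.default_rng(8)
        dose = rng.uniform(0, 5, (8, 8, 8))
        mask = np.ones_like(dose, dtype=bool)
        curve = cumulative_dvh(dose, mask, bin_width=0.01)
        assert curve.mean_dose() == pytest.approx(dose.mean(), rel=0.01)

    def test_d50_normalisation_option(self):
        dose = np.linspace(0, 10, 1000).reshape(10, 10, 10)
        curve = cumulative_dvh(dose, np.ones_like(dose, dtype=bool),
                               normalize="d50")
        assert curve.d50 == pytest.approx(5.0, rel=0.02)
        assert curve.dose_at_volume(0.5) == pytest.approx(1.0, rel=0.02)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            cumulative_dvh(np.ones((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            DVHCurve(np.array([0.0, 1.0, 2.0]), np.array([1.0, 1.1, 0.0]))


class TestRBE:
    def test_unit_weights_identity(self):
        comps = {"neutron": np.array([1.0, 2.0]), "photon": np.array([3.0, 1.0])}
        w = RBEWeights({"neutron": 1.0, "photon": 1.0})
        assert np.allclose(apply_rbe(comps, w), [4.0, 3.0])

    def test_pure_neutron_tripled(self):
        comps = {"neutron": np.array([2.0]), "photon": np.array([0.0])}
        assert apply_rbe(comps)[0] == pytest.approx(6.0)

    def test_mixed_field_effective_factor(self):
        # 60% neutron / 40% photon with RBE (3, 1): weighted / physical = 2.2
        comps = {"neutron": np.array([0.6]), "photon": np.array([0.4])}
        assert apply_rbe(comps)[0] == pytest.approx(2.2)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(1)
        comps = {"neutron": rng.random(5), "photon": rng.random(5)}
        wa = RBEWeights({"neutron": 2.0, "photon": 0.5})
        wb = RBEWeights({"neutron": 1.0, "photon": 0.5})
        wab = RBEWeights({"neutron": 3.0, "photon": 1.0})
        assert np.allclose(apply_rbe(comps, wa) + apply_rbe(comps, wb),
                           apply_rbe(comps, wab))

    def test_missing_component_raises(self):
        with pytest.raises(KeyError):
            apply_rbe({"neutron": np.ones(2)})

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            RBEWeights({"neutron": 0.0, "photon": 1.0})


class TestRenormalizePhotons:
    depths = np.arange(0.5, 15.0)

    def test_reference_equals_sum_gives_unity(self):
        P = np.exp(-self.depths / 8)
        S = 0.1 * np.exp(-self.depths / 5)
        assert renormalize_photons(P, S, P + S, self.depths) == pytest.approx(1.0)

    def test_doubled_primary_gives_two(self):
        P = np.exp(-self.depths / 8)
        S = 0.1 * np.exp(-self.depths / 5)
        assert renormalize_photons(P, S, 2 * P + S, self.depths) == pytest.approx(2.0)

    def test_invariant_under_common_rescale(self):
        rng = np.random.default_rng(2)
        P, S, R = rng.random((3, self.depths.size)) + 0.1
        s1 = renormalize_photons(P, S, R, self.depths)
        s2 = renormalize_photons(5 * P, 5 * S, 5 * R, self.depths)
        assert s1 == pytest.approx(s2)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            renormalize_photons([1.0], [0.0], [1.0], [20.0], window=(0, 10))

    def test_zero_primary_raises(self):
        with pytest.raises(ValueError):
            renormalize_photons(np.zeros(5), np.ones(5), np.ones(5),
                                self.depths[:5])


class TestIsodose:
    @staticmethod
    def _poly_area(poly):
        x, y = poly[:, 0], poly[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))

    def test_radial_dose_contours_closed_and_ordered(self):
        y, x = np.mgrid[0:40, 0:40]
        dose = 2.0 * np.exp(-((x - 20) ** 2 + (y - 20) ** 2) / 120.0)
        contours = isodose_contours(dose, 2.0, [20, 50, 80])
        areas = {}
        for lv, polys in contours.items():
            assert len(polys) == 1
            poly = polys[0]
            assert np.allclose(poly[0], poly[-1], atol=1e-9)  # closed
            areas[lv] = self._poly_area(poly)
        assert areas[20] > areas[50] > areas[80]

    def test_constant_slice_has_no_contours(self):
        contours = isodose_contours(np.full((8, 8), 1.0), 2.0, [10, 49, 150])
        assert all(len(v) == 0 for v in contours.values())

    def test_linear_ramp_mid_level_line(self):
        ramp = np.tile(np.linspace(0, 2, 21)[:, None], (1, 9))
        contours = isodose_contours(ramp, 2.0, [50], voxel_size=(1.0, 1.0))
        (poly,) = contours[50]
        # the 50% line of a 0..2 ramp over 21 rows sits at the midpoint
        mid = np.median(poly[:, 0])
        expected = 0.5 + 10.0  # index 10 -> centre-of-voxel coordinate
        assert mid == pytest.approx(expected, abs=0.25)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            isodose_contours(np.ones((1, 5)), 2.0, [50])
        with pytest.raises(ValueError):
            isodose_contours(np.ones((5, 5)), 0.0, [50])


class TestWallInfluence:
    def test_identical_curves_zero(self):
        c = np.array([1.0, 2.0, 3.0])
        df = wall_influence(c, c)
        assert np.allclose(df["relative_difference"], 0.0)

    def test_constructed_five_percent_offset(self):
        c = np.array([1.0, 2.0, 3.0])
        df = wall_influence(1.05 * c, c, 0.01 * c, 0.01 * c)
        assert np.allclose(df["relative_difference"], 0.05)
        assert np.allclose(df["error"], np.sqrt(2) * 0.01, rtol=1e-6)

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            wall_influence(np.ones(3), np.zeros(3))

    def test_mismatched_grids_raise(self):
        with pytest.raises(ValueError):
            wall_influence(np.ones(3), np.ones(4))
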