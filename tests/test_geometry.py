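"""Phantom construction, voxelisation, phantom files, synthetic head."""

import numpy as np
import pytest

import neutronplan as npl
from neutronplan.geometry import (ChamberArray, SolidBoxPhantom, chamber_depths,
                                  chamber_volume, crop_upper, load_voxel_phantom,
                                  save_voxel_phantom, synthetic_head_phantom,
                                  voxelise_box)


class TestVoxeliseBox:
    def test_enlarged_water_box_exceeds_ten_million_voxels(self):
        ph = voxelise_box((64.0, 64.0, 52.0), (0.2, 0.2, 0.5))
        assert ph.shape == (320, 320, 104)
        assert ph.n_voxels == 10_649_600
        assert ph.n_voxels > 10**7

    def test_single_voxel(self):
        assert voxelise_box((1.0, 1.0, 1.0), (1.0, 1.0, 1.0)).n_voxels == 1

    def test_non_integral_division_raises(self):
        with pytest.raises(ValueError):
            voxelise_box((63.5, 64.0, 52.0), (0.2, 0.2, 0.5))


class TestChambers:
    def test_forty_chambers_reach_39_5_cm(self):
        d = chamber_depths(0.5, 1.0, 40)
        assert d.size == 40
        assert d[-1] == pytest.approx(39.5)

    def test_single_chamber(self):
        assert chamber_depths(0.5, 1.0, 1).tolist() == [0.5]

    def test_eleven_chambers(self):
        d = chamber_depths(0.5, 1.0, 11)
        assert d.size == 11 and d.max() == pytest.approx(10.5)

    def test_non_positive_pitch_raises(self):
        with pytest.raises(ValueError):
            chamber_depths(0.5, 0.0, 4)

    def test_chamber_volume_matches_printed_value(self):
        v = chamber_volume(0.38, 1.21)
        assert v == pytest.approx(0.549, abs=1e-3)
        assert round(v, 2) == 0.55 or abs(v - 0.54) < 0.01

    def test_volume_degenerate_and_unit(self):
        assert chamber_volume(1.0, 0.0) == 0.0
        assert chamber_volume(1.0, 1.0) == pytest.approx(np.pi)

    def test_chambers_fit_inside_water(self):
        with pytest.raises(ValueError):
            SolidBoxPhantom(chambers=ChamberArray(count=100))

    def test_chamber_array_non_perturbing_volume(self):
        ph = SolidBoxPhantom()
        water_vol = np.prod(ph.water_interior)
        frac = ph.chambers.count * ph.chambers.volume / water_vol
        assert frac < 1e-3  # < 0.1 % of the water volume


class TestPhantomFiles:
    def test_round_trip(self, tmp_path, small_head):
        phantom, _rois = small_head
        g = tmp_path / "head.vox"
        m = tmp_path / "head.organs"
        save_voxel_phantom(phantom, g, m)
        back = load_voxel_phantom(g, m)
        assert back.shape == phantom.shape
        assert np.array_equal(back.ids, phantom.ids)
        assert back.voxel_size == pytest.approx(phantom.voxel_size)
        assert back.organ_map == phantom.organ_map

    def test_unmapped_id_error_names_the_id(self, tmp_path, small_head):
        phantom, _ = small_head
        g = tmp_path / "head.vox"
        m = tmp_path / "head.organs"
        save_voxel_phantom(phantom, g, m)
        # drop one organ from the map
        lines = [ln for ln in m.read_text().splitlines() if not ln.startswith("21 ")]
        m.write_text("\n".join(lines))
        with pytest.raises(KeyError, match="21"):
            load_voxel_phantom(g, m)

    def test_payload_shape_mismatch(self, tmp_path, small_head):
        phantom, _ = small_head
        g = tmp_path / "head.vox"
        save_voxel_phantom(phantom, g)
        data = g.read_bytes()
        g.write_bytes(data[:-10])
        with pytest.raises(ValueError, match="payload"):
            load_voxel_phantom(g)


class TestCropUpper:
    def test_crop_87_of_337(self):
        ph = voxelise_box((6.0, 6.0, 337 * 0.5), (1.0, 1.0, 0.5))
        out = crop_upper(ph, 87)
        assert out.shape == (6, 6, 87)
        assert out.n_voxels == 6 * 6 * 87
        assert out.origin[2] == pytest.approx((337 - 87) * 0.5)

    def test_identity_crop(self):
        ph = voxelise_box((2.0, 2.0, 2.0), (1.0, 1.0, 1.0))
        assert crop_upper(ph, 2).shape == ph.shape

    def test_invalid_counts(self):
        ph = voxelise_box((2.0, 2.0, 2.0), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            crop_upper(ph, 0)
        with pytest.raises(ValueError):
            crop_upper(ph, 3)


class TestSyntheticHead:
    def test_default_phantom_projects_onto_30_materials(self, tmp_path):
        phantom, _rois = synthetic_head_phantom(seed=0)
        g = tmp_path / "full_head.vox"
        m = tmp_path / "full_head.organs"
        save_voxel_phantom(phantom, g, m)
        back = load_voxel_phantom(g, m)
        mats = np.unique(back.material_ids())
        assert mats.size == 30

    def test_outermost_tissue_is_skin(self, small_head):
        phantom, _ = small_head
        mats = phantom.material_ids()
        for j in range(0, phantom.shape[1], 7):
            for k in range(0, phantom.shape[2], 9):
                line = mats[:, j, k]
                nz = np.nonzero(line)[0]
                if nz.size:
                    assert line[nz[0]] == 19 and line[nz[-1]] == 19

    def test_gland_masks_disjoint_and_nonempty(self, small_head):
        _phantom, rois = small_head
        glands = [g for g in rois if g != "body"]
        assert len(glands) == 6
        total = np.zeros_like(rois[glands[0]], dtype=int)
        for g in glands:
            assert rois[g].sum() > 0, g
            total += rois[g]
        assert total.max() == 1  # pairwise disjoint

    def test_trachea_is_low_density_air(self, small_head, mat_table):
        phantom, _ = small_head
        mats = phantom.material_ids()
        assert (mats == 5).sum() > 0
        assert mat_table[5].density < 0.01

    def test_deterministic_under_seed(self):
        a, _ = synthetic_head_phantom(seed=9, shape=(42, 42, 62))
        b, _ = synthetic_head_phantom(seed=9, shape=(42, 42, 62))
        assert np.array_equal(a.ids, b.ids)

    def test_too_small_shape_raises(self):
        with pytest.raises(ValueError):
            synthetic_head_phantom(shape=(10, 10, 10))


class TestPointLookup:
    def test_every_point_resolves_to_one_material(self, solid_geo):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.uniform([-150, -200, -200], [300, 200, 200])
            m = solid_geo.material_at(p)  # raises outside the world
            assert m.name in {"water", "perspex", "aluminum", "air"}

    def test_expected_materials_at_known_points(self, solid_geo):
        assert solid_geo.material_at((5.0, 0.0, 0.0)).name == "water"
        assert solid_geo.material_at((-1.0, 20.0, 0.0)).name == "perspex"
        assert solid_geo.material_at((-0.1, 0.0, 0.0)).name == "aluminum"
        assert solid_geo.material_at((-1.0, 0.0, 0.0)).name == "air"

    def test_voxelised_box_matches_solid_at_centres(self, solid_geo, voxel_geo):
        rng = np.random.default_rng(1)
        for _ in range(300):
            p = rng.uniform([0.5, -25, -20], [55, 25, 20])  # inside the water
            assert voxel_geo.material_at(p).name == solid_geo.material_at(p).name
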