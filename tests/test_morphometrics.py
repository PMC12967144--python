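import numpy as np
import pytest

from conftest import digital_ball
from vemmorph.morphometrics import (
    compute_com,
    compute_surface_area,
    compute_volume,
    integrated_density,
    morphometry_dataframe,
    morphometry_table,
    normalized_chromosomal_intensity,
)
from vemmorph.volio import LabelVolume, ObjectRecord, VoxelGrid

VOX30 = (30.0, 30.0, 30.0)


class TestVolume:
    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        assert compute_volume(mask, VOX30) == pytest.approx(2.7e-5)

    def test_cube(self):
        assert compute_volume(np.ones((10, 10, 10), bool), VOX30) == pytest.approx(0.027)

    def test_ball_matches_exhaustive_count(self):
        ball = digital_ball(20)
        expected = int(ball.sum()) * 27e3 / 1e9  # brute-force voxel count oracle
        assert compute_volume(ball, VOX30) == pytest.approx(expected, rel=0)

    def test_anisotropic_voxels(self):
        mask = np.ones((2, 3, 4), bool)
        assert compute_volume(mask, (90, 60, 30)) == pytest.approx(24 * 90 * 60 * 30 / 1e9)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            compute_volume(np.zeros((3, 3, 3), bool), VOX30)

    def test_additivity_under_label_split(self):
        rng = np.random.default_rng(0)
        blob = rng.random((8, 8, 8)) > 0.5
        half = blob.copy()
        half[:4] = False
        other = blob & ~half
        assert half.any() and other.any()
        total = compute_volume(blob, VOX30)
        assert compute_volume(half, VOX30) + compute_volume(other, VOX30) == pytest.approx(
            total, rel=0
        )


class TestSurfaceArea:
    def test_cube_within_two_percent(self):
        a = compute_surface_area(np.ones((10, 10, 10), bool), VOX30)
        assert a == pytest.approx(6 * 0.3**2, rel=0.02)

    def test_sphere_within_five_percent(self):
        ball = digital_ball(25)
        analytic = 4 * np.pi * (25 * 30 / 1000) ** 2
        assert compute_surface_area(ball, VOX30) == pytest.approx(analytic, rel=0.05)

    def test_convergence_with_radius(self):
        errs = []
        for r in (10, 20, 40):
            a = compute_surface_area(digital_ball(r), VOX30)
            analytic = 4 * np.pi * (r * 30 / 1000) ** 2
            errs.append(abs(a - analytic) / analytic)
        assert errs[0] > errs[1] > errs[2]

    def test_single_voxel_bounded(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        a = compute_surface_area(mask, VOX30)
        assert 0 < a <= 1.2 * 6 * 30 * 30 / 1e6

    def test_mesh_method_available(self):
        ball = digital_ball(12)
        a_mesh = compute_surface_area(ball, VOX30, method="mesh")
        analytic = 4 * np.pi * (12 * 30 / 1000) ** 2
        assert a_mesh == pytest.approx(analytic, rel=0.15)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            compute_surface_area(np.zeros((3, 3, 3), bool), VOX30)


class TestCom:
    def test_symmetric_cube_centre(self):
        com = compute_com(np.ones((10, 10, 10), bool), VOX30)
        assert (com.x, com.y, com.z) == (150.0, 150.0, 150.0)

    def test_two_voxel_midpoint(self):
        mask = np.zeros((1, 1, 3), bool)
        mask[0, 0, 0] = mask[0, 0, 2] = True
        com = compute_com(mask, VOX30)
        assert com.x == pytest.approx(1.5 * 30)

    def test_random_blob_matches_bruteforce_mean(self):
        rng = np.random.default_rng(3)
        blob = rng.random((6, 7, 8)) > 0.6
        com = compute_com(blob, (90, 60, 30))
        zz, yy, xx = np.nonzero(blob)
        assert com.x == pytest.approx((xx.mean() + 0.5) * 30)
        assert com.y == pytest.approx((yy.mean() + 0.5) * 60)
        assert com.z == pytest.approx((zz.mean() + 0.5) * 90)

    @pytest.mark.parametrize("shift", [(1, 0, 0), (0, 2, 1), (2, 3, 4)])
    def test_translation_equivariance(self, shift):
        rng = np.random.default_rng(9)
        blob = rng.random((5, 5, 5)) > 0.5
        big = np.zeros((12, 12, 12), bool)
        big[1:6, 1:6, 1:6] = blob
        moved = np.roll(big, shift, axis=(0, 1, 2))
        c0, c1 = compute_com(big, (90, 60, 30)), compute_com(moved, (90, 60, 30))
        dk, dj, di = shift
        assert c1.z - c0.z == pytest.approx(dk * 90)
        assert c1.y - c0.y == pytest.approx(dj * 60)
        assert c1.x - c0.x == pytest.approx(di * 30)


class TestIntensity:
    def test_constant_intensity(self):
        mask = np.zeros((5, 5, 5), bool)
        mask.flat[:100] = True
        intensity = np.full((5, 5, 5), 50.0)
        assert integrated_density(intensity, mask) == 5000

    def test_zero_intensity(self):
        assert integrated_density(np.zeros((3, 3, 3)), np.ones((3, 3, 3), bool)) == 0

    def test_matches_bruteforce_and_slicewise_sum(self):
        rng = np.random.default_rng(7)
        vol = rng.integers(0, 255, (6, 6, 6)).astype(float)
        mask = rng.random((6, 6, 6)) > 0.5
        direct = integrated_density(vol, mask)
        brute = sum(vol[k, j, i] for k, j, i in zip(*np.nonzero(mask)))
        slicewise = sum(vol[k][mask[k]].sum() for k in range(6))
        assert direct == pytest.approx(brute)
        assert direct == pytest.approx(slicewise)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            integrated_density(np.zeros((3, 3, 3)), np.ones((4, 4, 4), bool))


class TestNormalizedIntensity:
    def test_single_chromosome_is_one(self):
        assert normalized_chromosomal_intensity({5: 123.0}) == {5: 1.0}

    def test_equal_densities(self):
        out = normalized_chromosomal_intensity({i: 10.0 for i in range(4)})
        assert all(v == pytest.approx(0.25) for v in out.values())

    def test_random_fractions_sum_to_one_order_invariant(self):
        rng = np.random.default_rng(1)
        dens = {i: float(v) for i, v in enumerate(rng.uniform(1, 100, 12))}
        out = normalized_chromosomal_intensity(dens)
        total = sum(dens.values())
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-9)
        for k in dens:
            assert out[k] == pytest.approx(dens[k] / total)
        reordered = normalized_chromosomal_intensity(dict(reversed(list(dens.items()))))
        assert reordered == out

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            normalized_chromosomal_intensity({1: 0.0, 2: 0.0})


def _toy_scene():
    labels = np.zeros((10, 10, 10), dtype=np.uint16)
    labels[1:9, 1:9, 1:9] = 1
    labels[3:5, 3:5, 3:5] = 2
    labels[6:8, 6:8, 6:8] = 3
    index = {
        1: ObjectRecord("cell"),
        2: ObjectRecord("mitochondrion", parent_cell_id=1),
        3: ObjectRecord("vesicle", parent_cell_id=1, truncated=True),
    }
    return LabelVolume(labels=labels, voxel_size=(30, 30, 30), object_index=index)


class TestMorphometryTable:
    def test_exact_voxel_volumes_and_flags(self):
        recs = morphometry_table(_toy_scene())
        assert len(recs) == 3
        by_id = {r.object_id: r for r in recs}
        # the cell's territory includes its children
        assert by_id[1].voxel_count == 8**3
        assert by_id[2].volume == pytest.approx(8 * 2.7e-5)
        assert by_id[3].truncated  # flagged, not dropped
        assert by_id[2].sa_v_ratio == pytest.approx(by_id[2].surface_area / by_id[2].volume)

    def test_labels_only_has_null_intensity(self):
        recs = morphometry_table(_toy_scene())
        assert all(r.integrated_density is None and r.mean_intensity is None for r in recs)

    def test_intensity_fields(self):
        scene = _toy_scene()
        grid = VoxelGrid(data=np.full((10, 10, 10), 7, dtype=np.uint8), voxel_size=(30, 30, 30))
        recs = morphometry_table(scene, grid)
        by_id = {r.object_id: r for r in recs}
        assert by_id[2].integrated_density == 7 * 8
        assert by_id[2].mean_intensity == pytest.approx(7.0)

    def test_mean_intensity_invariant_to_voxel_size(self):
        scene = _toy_scene()
        grid = VoxelGrid(data=np.random.default_rng(0).integers(0, 255, (10, 10, 10)).astype(np.uint8),
                         voxel_size=(30, 30, 30))
        r30 = {m.object_id: m.mean_intensity for m in morphometry_table(scene, grid)}
        scene90 = LabelVolume(labels=scene.labels, voxel_size=(90, 90, 90),
                              object_index=scene.object_index)
        grid90 = VoxelGrid(data=grid.data, voxel_size=(90, 90, 90))
        r90 = {m.object_id: m.mean_intensity for m in morphometry_table(scene90, grid90)}
        assert r30 == pytest.approx(r90)

    def test_dataframe_form(self):
        df = morphometry_dataframe(_toy_scene())
        assert list(df["object_id"]) == [1, 2, 3]
        assert {"volume", "surface_area", "com_x_nm"} <= set(df.columns)
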