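import numpy as np
import pytest

from conftest import digital_ball
from vemmorph.density_maps import (
    AlignmentTransform,
    align_to_major_axes,
    hotspot_map,
    regional_density_3x3,
    stack_phase_heatmaps,
)

VOX = (90.0, 90.0, 90.0)


def _ellipsoid(semis_vox, shape=None, center=None, rotate=None):
    a, b, c = semis_vox  # x, y, z semi-axes in voxels
    if shape is None:
        m = int(max(semis_vox)) + 3
        shape = (2 * m + 1,) * 3
    if center is None:
        center = tuple(s // 2 for s in shape)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    x, y, z = xx - center[2], yy - center[1], zz - center[0]
    if rotate is not None:
        x, y, z = rotate(x, y, z)
    return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0


class TestAlignment:
    def test_rotated_ellipsoid_orders_variances(self):
        # ellipsoid with a>b>c rotated 30 deg in the xy plane
        th = np.deg2rad(30)

        def rot(x, y, z):
            return x * np.cos(th) + y * np.sin(th), -x * np.sin(th) + y * np.cos(th), z

        mask = _ellipsoid((20, 12, 7), rotate=rot)
        tr = align_to_major_axes(mask, VOX)
        v = tr.axis_variance
        assert v[0] > v[1] > v[2]
        assert not tr.degenerate
        assert np.allclose(tr.rotation @ tr.rotation.T, np.eye(3), atol=1e-9)
        # aligned coordinates have descending variance along x, y, z
        from vemmorph.density_maps import _mask_coords_xyz

        aligned = tr.apply(_mask_coords_xyz(mask, VOX))
        var = aligned.var(axis=0)
        assert var[0] > var[1] > var[2]

    def test_axis_aligned_ellipsoid_identity_up_to_sign(self):
        mask = _ellipsoid((18, 11, 6))
        tr = align_to_major_axes(mask, VOX)
        assert np.allclose(np.abs(tr.rotation), np.eye(3), atol=1e-6)

    def test_ball_is_degenerate_identity(self):
        tr = align_to_major_axes(digital_ball(12), VOX)
        assert tr.degenerate
        assert np.array_equal(tr.rotation, np.eye(3))

    def test_idempotence(self):
        mask = _ellipsoid((18, 11, 6))
        tr = align_to_major_axes(mask, VOX)
        # re-aligning an already axis-aligned mask: rotation ~ identity up to sign
        tr2 = align_to_major_axes(mask, VOX)
        assert np.allclose(np.abs(tr2.rotation @ tr.rotation.T), np.eye(3), atol=1e-6)


def _identity_transform():
    return AlignmentTransform(
        rotation=np.eye(3), translation=np.zeros(3), axis_variance=(3.0, 2.0, 1.0)
    )


def _box_cell(nx=30, ny=24, nz=6):
    mask = np.zeros((nz + 2, ny + 2, nx + 2), bool)
    mask[1 : nz + 1, 1 : ny + 1, 1 : nx + 1] = True
    return mask


class TestRegionalDensity:
    def test_one_centroid_per_region(self):
        mask = _box_cell()
        tr = _identity_transform()
        # region centres of the projected bounding box
        xs = 90 * (1 + np.array([5, 15, 25]))
        ys = 90 * (1 + np.array([4, 12, 20]))
        cen = np.array([[x, y, 3 * 90] for y in ys for x in xs], dtype=float)
        grid = regional_density_3x3(cen, mask, tr, VOX)
        assert np.array_equal(grid.counts, np.ones((3, 3)))
        assert grid.density.min() > 0

    def test_top_left_octant_argmax(self):
        mask = _box_cell()
        tr = _identity_transform()
        rng = np.random.default_rng(0)
        cen = np.column_stack(
            [
                rng.uniform(90, 90 * 8, 20),  # low x
                rng.uniform(90, 90 * 7, 20),  # low y
                rng.uniform(90, 90 * 5, 20),
            ]
        )
        grid = regional_density_3x3(cen, mask, tr, VOX)
        assert np.unravel_index(np.argmax(grid.counts), (3, 3)) == (0, 0)

    def test_matches_bruteforce_binning(self):
        mask = _box_cell()
        tr = _identity_transform()
        rng = np.random.default_rng(1)
        n = 40
        cen = np.column_stack(
            [rng.uniform(100, 30 * 90, n), rng.uniform(100, 24 * 90, n), rng.uniform(100, 500, n)]
        )
        grid = regional_density_3x3(cen, mask, tr, VOX)
        # brute-force O(n) loop over centroids with the same box edges
        counts = np.zeros((3, 3))
        xe, ye = grid.x_edges, grid.y_edges
        for x, y, _ in cen:
            ix = min(2, max(0, int(np.searchsorted(xe, x, side="right")) - 1))
            iy = min(2, max(0, int(np.searchsorted(ye, y, side="right")) - 1))
            counts[iy, ix] += 1
        assert np.array_equal(grid.counts, counts)
        assert grid.counts.sum() == n  # conservation

    def test_outside_mask_centroid_flagged_but_counted(self):
        mask = _box_cell()
        tr = _identity_transform()
        cen = np.array([[45.0, 45.0, 45.0], [900.0, 900.0, 300.0]])  # first voxel is outside box
        grid = regional_density_3x3(cen, mask, tr, VOX, centroid_ids=[10, 11])
        assert grid.counts.sum() == 2
        assert grid.outside_mask_ids == [10]

    def test_rigid_rotation_invariance(self):
        # an asymmetric blob: half-ellipsoid (skewed along every axis)
        base = _ellipsoid((16, 10, 6), shape=(21, 29, 41), center=(9, 13, 19))
        bump = _ellipsoid((6, 5, 4), shape=(21, 29, 41), center=(12, 19, 29))
        mask = base | bump
        rng = np.random.default_rng(2)
        zz, yy, xx = np.nonzero(mask)
        pick = rng.choice(len(zz), 25, replace=False)
        cen = np.column_stack(
            [(xx[pick] + 0.5) * 90, (yy[pick] + 0.5) * 90, (zz[pick] + 0.5) * 90]
        )
        tr = align_to_major_axes(mask, VOX)
        g1 = regional_density_3x3(cen, mask, tr, VOX)
        # rotate the whole scene by 90 deg in the xy plane
        mask_r = np.rot90(mask, k=1, axes=(1, 2))
        nzr, nyr, nxr = mask_r.shape
        # voxel (k, j, i) -> (k, nx-1-i, j) under np.rot90(axes=(1, 2))
        kk = (cen[:, 2] / 90 - 0.5).round().astype(int)
        jj = (cen[:, 1] / 90 - 0.5).round().astype(int)
        ii = (cen[:, 0] / 90 - 0.5).round().astype(int)
        jr, ir = mask.shape[2] - 1 - ii, jj
        cen_r = np.column_stack([(ir + 0.5) * 90, (jr + 0.5) * 90, (kk + 0.5) * 90])
        tr_r = align_to_major_axes(mask_r, VOX)
        g2 = regional_density_3x3(cen_r, mask_r, tr_r, VOX)
        assert np.array_equal(g1.counts, g2.counts)
        assert np.allclose(g1.density, g2.density, rtol=1e-6)


class TestHotspot:
    def test_single_centroid_unimodal_peak(self):
        mask = _box_cell()
        tr = _identity_transform()
        cen = np.array([[900.0, 700.0, 300.0]])
        hot = hotspot_map(cen, mask, tr, VOX, bandwidth=200.0)
        iy, ix = np.unravel_index(np.argmax(hot.field), hot.field.shape)
        assert hot.x_centers[ix] == pytest.approx(900.0, abs=hot.x_centers[1] - hot.x_centers[0])
        assert hot.y_centers[iy] == pytest.approx(700.0, abs=hot.y_centers[1] - hot.y_centers[0])

    def test_two_clusters_equal_height(self):
        mask = _box_cell(nx=40, ny=20)
        tr = _identity_transform()
        a = np.array([900.0, 900.0, 300.0])
        b = np.array([2700.0, 900.0, 300.0])
        offsets = np.array([[0, 0, 0], [60, 0, 0], [-60, 0, 0], [0, 60, 0], [0, -60, 0]])
        cen = np.vstack([a + offsets, b + offsets]).astype(float)
        hot = hotspot_map(cen, mask, tr, VOX, bandwidth=150.0)
        mid = len(hot.x_centers) // 2
        left = hot.field[:, :mid].max()
        right = hot.field[:, mid:].max()
        assert left == pytest.approx(right, rel=0.05)

    def test_integral_close_to_count(self):
        mask = _box_cell()
        tr = _identity_transform()
        rng = np.random.default_rng(3)
        cen = np.column_stack(
            [rng.uniform(600, 2100, 30), rng.uniform(600, 1500, 30), rng.uniform(90, 400, 30)]
        )
        hot = hotspot_map(cen, mask, tr, VOX, bandwidth=120.0)
        assert hot.integral() == pytest.approx(30, rel=0.02)

    def test_zero_centroids_error(self):
        with pytest.raises(ValueError):
            hotspot_map(np.empty((0, 3)), _box_cell(), _identity_transform(), VOX)


class TestStacking:
    def _grid(self, dens, cls="mitochondrion"):
        from vemmorph.density_maps import DensityGrid

        return DensityGrid(
            density=np.asarray(dens, float),
            counts=np.ones((3, 3)),
            region_area_um2=np.ones((3, 3)),
            organelle_class=cls,
            cell_id=1,
            x_edges=np.linspace(0, 1, 4),
            y_edges=np.linspace(0, 1, 4),
        )

    def test_single_cell_is_its_own_mean(self):
        g = self._grid(np.arange(9).reshape(3, 3))
        out = stack_phase_heatmaps([g])
        assert np.array_equal(out.density, g.density)

    def test_two_identical_grids(self):
        g = self._grid(np.arange(9).reshape(3, 3))
        out = stack_phase_heatmaps([g, g])
        assert np.array_equal(out.density, g.density)

    def test_mixed_classes_error(self):
        with pytest.raises(ValueError, match="mixed organelle"):
            stack_phase_heatmaps([self._grid(np.ones((3, 3))), self._grid(np.ones((3, 3)), cls="ER")])
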