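"""Aligned, z-projected regional organelle density maps.

Cells imaged in arbitrary orientations are first rotated into a canonical
frame where the x-axis is the longest cell axis and the y-axis the second
longest (principal axes of the voxel-coordinate covariance).  Organelle
centroids are then projected along z and binned into a 3×3 grid spanning
the projected cell's bounding box; densities are voxel-corrected — counts
divided by the physical projected cell area (μm²) inside each region, so
stacks acquired at different binning remain comparable.  Kernel-density
hotspot maps use the same aligned projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volio import NM2_PER_UM2, Point3D

__all__ = [
    "AlignmentTransform",
    "DensityGrid",
    "HotspotMap",
    "align_to_major_axes",
    "regional_density_3x3",
    "hotspot_map",
    "stack_phase_heatmaps",
]

DEGENERACY_RTOL = 0.01  # eigenvalues all within 1% -> isotropic, keep identity


@dataclass
class AlignmentTransform:
    """Rigid transform into the major-axis frame.

    ``apply`` maps physical (x, y, z) nm points to aligned coordinates via
    ``R @ (p − center)``; after it, coordinate variance is non-increasing
    along x, y, z.  Axis signs follow the convention that the coordinate
    skewness is ≥ 0 (ties resolve to +), which pins the orientation for
    asymmetric cells.
    """

    rotation: np.ndarray  # (3, 3) orthonormal, rows = new axes
    translation: np.ndarray  # nm; aligned = R @ (p - translation)
    axis_variance: tuple[float, float, float]  # nm², sorted descending
    degenerate: bool = False

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.translation) @ self.rotation.T


def _mask_coords_xyz(mask: np.ndarray, voxel_size) -> np.ndarray:
    """Physical (x, y, z) nm coordinates of mask voxel centres."""
    sz, sy, sx = voxel_size
    zz, yy, xx = np.nonzero(np.asarray(mask).astype(bool))
    return np.column_stack([(xx + 0.5) * sx, (yy + 0.5) * sy, (zz + 0.5) * sz])


def align_to_major_axes(cell_mask: np.ndarray, voxel_size) -> AlignmentTransform:
    """Principal-axis alignment of a cell mask.

    Eigen-decomposes the covariance of member-voxel physical coordinates;
    eigenvectors ordered by descending eigenvalue become the new x, y, z.
    A near-isotropic mask (all eigenvalues within 1% of each other) yields
    the identity rotation with the ``degenerate`` flag set.
    """
    coords = _mask_coords_xyz(cell_mask, voxel_size)
    if len(coords) == 0:
        raise ValueError("empty cell mask")
    center = coords.mean(axis=0)
    centered = coords - center
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals, kind="stable")[::-1]
    evals = evals[order]
    if evals[0] > 0 and (evals[0] - evals[-1]) / evals[0] < DEGENERACY_RTOL:
        return AlignmentTransform(
            rotation=np.eye(3),
            translation=center,
            axis_variance=tuple(float(v) for v in evals),
            degenerate=True,
        )
    rot = evecs[:, order].T  # rows are the new axes
    # sign convention: per-axis skewness of the projected cloud >= 0
    proj = centered @ rot.T
    for i in range(3):
        sk = np.mean(proj[:, i] ** 3)
        if sk < 0:
            rot[i] *= -1.0
    if np.linalg.det(rot) < 0:  # keep a right-handed frame; flip least-skewed axis
        sk = [abs(np.mean((centered @ rot.T)[:, i] ** 3)) for i in range(3)]
        rot[int(np.argmin(sk))] *= -1.0
    return AlignmentTransform(
        rotation=rot,
        translation=center,
        axis_variance=tuple(float(v) for v in evals),
        degenerate=False,
    )


@dataclass
class DensityGrid:
    """3×3 voxel-corrected regional density map of one cell (or a phase mean).

    ``counts[iy, ix]`` is the raw centroid count in region (iy, ix) of the
    aligned z-projection (iy indexes y from its minimum, ix indexes x);
    ``density`` divides by the projected cell area (μm²) within the region.
    The raw counts always sum to the number of centroids supplied.
    """

    density: np.ndarray  # (3, 3), count per μm² projected cell area
    counts: np.ndarray  # (3, 3) raw centroid counts
    region_area_um2: np.ndarray  # (3, 3)
    organelle_class: str
    cell_id: int | None
    x_edges: np.ndarray  # aligned nm
    y_edges: np.ndarray
    outside_mask_ids: list[int] = field(default_factory=list)


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def regional_density_3x3(
    centroids: np.ndarray,
    cell_mask: np.ndarray,
    transform: AlignmentTransform,
    voxel_size,
    organelle_class: str = "",
    cell_id: int | None = None,
    centroid_ids: list[int] | None = None,
) -> DensityGrid:
    """Bin organelle centroids into a 3×3 grid over the aligned projection.

    ``centroids`` are physical (x, y, z) nm points in the same frame as the
    mask.  The projected cell's bounding box is split into nine equal
    rectangles; each centroid lands in exactly one (outside-the-box points,
    which can only come from centroids outside the cell mask, are counted
    in the nearest region and reported in ``outside_mask_ids``).  The
    projected area per region is measured by rasterising the projected
    cell voxels at the native voxel pitch — this is the voxel correction
    that makes differently binned stacks comparable.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    cell_pts = _mask_coords_xyz(cell_mask, voxel_size)
    cell_xy = transform.apply(cell_pts)[:, :2]
    cen_xy = transform.apply(centroids)[:, :2]
    xmin, ymin = cell_xy.min(axis=0)
    xmax, ymax = cell_xy.max(axis=0)
    x_edges = np.linspace(xmin, xmax, 4)
    y_edges = np.linspace(ymin, ymax, 4)

    ix = _bin_index(cen_xy[:, 0], x_edges)
    iy = _bin_index(cen_xy[:, 1], y_edges)
    counts = np.zeros((3, 3), dtype=float)
    np.add.at(counts, (iy, ix), 1.0)

    # projected cell area per region: occupancy raster at the voxel pitch
    pix = float(min(voxel_size))
    nx_pix = max(1, int(np.ceil((xmax - xmin) / pix)))
    ny_pix = max(1, int(np.ceil((ymax - ymin) / pix)))
    occ, gx, gy = np.histogram2d(
        cell_xy[:, 0], cell_xy[:, 1], bins=[nx_pix, ny_pix], range=[[xmin, xmax], [ymin, ymax]]
    )
    occupied = occ > 0
    px_cx = 0.5 * (gx[:-1] + gx[1:])
    px_cy = 0.5 * (gy[:-1] + gy[1:])
    rx = _bin_index(px_cx, x_edges)
    ry = _bin_index(px_cy, y_edges)
    pix_area_um2 = (gx[1] - gx[0]) * (gy[1] - gy[0]) / NM2_PER_UM2
    area = np.zeros((3, 3), dtype=float)
    for i in range(3):
        for j in range(3):
            area[j, i] = occupied[np.ix_(rx == i, ry == j)].sum() * pix_area_um2

    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(area > 0, counts / area, 0.0)
    # a populated region with zero measured projected area can only arise
    # from flagged outside-mask centroids; fall back to the rectangle area
    rect_area = (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0]) / NM2_PER_UM2
    bad = (area == 0) & (counts > 0)
    density[bad] = counts[bad] / rect_area

    # flag centroids whose voxel lies outside the cell mask
    mask = np.asarray(cell_mask).astype(bool)
    sz, sy, sx = voxel_size
    kk = np.clip((centroids[:, 2] / sz).astype(int), 0, mask.shape[0] - 1)
    jj = np.clip((centroids[:, 1] / sy).astype(int), 0, mask.shape[1] - 1)
    ii = np.clip((centroids[:, 0] / sx).astype(int), 0, mask.shape[2] - 1)
    inside = mask[kk, jj, ii]
    ids = centroid_ids if centroid_ids is not None else list(range(len(centroids)))
    outside = [ids[i] for i in np.flatnonzero(~inside)]

    return DensityGrid(
        density=density,
        counts=counts,
        region_area_um2=area,
        organelle_class=organelle_class,
        cell_id=cell_id,
        x_edges=x_edges,
        y_edges=y_edges,
        outside_mask_ids=outside,
    )


@dataclass
class HotspotMap:
    """Gaussian kernel density of projected centroids on a 64×64 grid.

    ``field[iy, ix]`` has units counts/nm² and integrates to the centroid
    count when the kernels lie inside the evaluation window.
    """

    field: np.ndarray
    x_centers: np.ndarray  # aligned nm
    y_centers: np.ndarray
    bandwidth: tuple[float, float]
    organelle_class: str = ""

    def integral(self) -> float:
        dx = self.x_centers[1] - self.x_centers[0] if len(self.x_centers) > 1 else 1.0
        dy = self.y_centers[1] - self.y_centers[0] if len(self.y_centers) > 1 else 1.0
        return float(self.field.sum() * dx * dy)


def hotspot_map(
    centroids: np.ndarray,
    cell_mask: np.ndarray,
    transform: AlignmentTransform,
    voxel_size,
    bandwidth: float | tuple[float, float] | None = None,
    grid_size: int = 64,
    organelle_class: str = "",
) -> HotspotMap:
    """Kernel-density hotspot map of organelle centroids.

    Centroids are projected in the aligned frame and smoothed with a
    Gaussian kernel on a ``grid_size``² grid over the projected cell
    bounding box.  Default bandwidth per axis is Silverman's rule
    (σ·n^(−1/6) for two dimensions); a fixed override keeps maps
    comparable across cells.
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if len(centroids) == 0:
        raise ValueError("need at least one centroid for a hotspot map")
    cell_xy = transform.apply(_mask_coords_xyz(cell_mask, voxel_size))[:, :2]
    pts = transform.apply(centroids)[:, :2]
    xmin, ymin = cell_xy.min(axis=0)
    xmax, ymax = cell_xy.max(axis=0)
    n = len(pts)
    if bandwidth is None:
        fallback = 0.05 * float(np.hypot(xmax - xmin, ymax - ymin))
        hx = float(pts[:, 0].std(ddof=1)) * n ** (-1 / 6) if n > 1 else 0.0
        hy = float(pts[:, 1].std(ddof=1)) * n ** (-1 / 6) if n > 1 else 0.0
        hx = hx if hx > 0 else fallback
        hy = hy if hy > 0 else fallback
    else:
        hx, hy = (bandwidth, bandwidth) if np.isscalar(bandwidth) else bandwidth
    xc = np.linspace(xmin, xmax, grid_size)
    yc = np.linspace(ymin, ymax, grid_size)
    gx, gy = np.meshgrid(xc, yc)  # field indexed [iy, ix]
    field = np.zeros_like(gx)
    norm = 1.0 / (2 * np.pi * hx * hy)
    for px, py in pts:
        field += norm * np.exp(-0.5 * (((gx - px) / hx) ** 2 + ((gy - py) / hy) ** 2))
    return HotspotMap(field=field, x_centers=xc, y_centers=yc, bandwidth=(hx, hy), organelle_class=organelle_class)


def stack_phase_heatmaps(grids: list[DensityGrid]) -> DensityGrid:
    """Element-wise mean density grid over cells of one phase.

    All grids must describe the same organelle class.
    """
    if not grids:
        raise ValueError("need at least one density grid")
    classes = {g.organelle_class for g in grids}
    if len(classes) > 1:
        raise ValueError(f"mixed organelle classes: {sorted(classes)}")
    density = np.mean([g.density for g in grids], axis=0)
    counts = np.mean([g.counts for g in grids], axis=0)
    area = np.mean([g.region_area_um2 for g in grids], axis=0)
    return DensityGrid(
        density=density,
        counts=counts,
        region_area_um2=area,
        organelle_class=grids[0].organelle_class,
        cell_id=None,
        x_edges=grids[0].x_edges,
        y_edges=grids[0].y_edges,
    )
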