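"""Per-object 3D morphometry and stain-intensity quantification.

Works on binary masks cut from a :class:`~vemmorph.volio.LabelVolume`
(optionally with a co-registered grayscale :class:`~vemmorph.volio.VoxelGrid`).
Conventions:

* volume is the exact voxel count times the physical voxel volume;
* surface area comes from a marching-cubes iso-surface extracted at the
  0.5 level in physical coordinates (voxel-face counting would overestimate
  the area of smooth bodies by tens of percent);
* the centre of mass is geometric — the unweighted mean of member-voxel
  centre coordinates — matching quantification of segmented model objects
  rather than an intensity-weighted moment;
* integrated density is the plain sum of grayscale values over the mask,
  identical whether accumulated slice-by-slice or in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .volio import (
    LabelVolume,
    NM2_PER_UM2,
    NM3_PER_UM3,
    Point3D,
    VoxelGrid,
)

__all__ = [
    "ObjectMorphometry",
    "compute_volume",
    "compute_surface_area",
    "compute_com",
    "integrated_density",
    "normalized_chromosomal_intensity",
    "morphometry_table",
    "morphometry_dataframe",
]


@dataclass
class ObjectMorphometry:
    """Morphometric record of one segmented object.

    Volumes are in μm³, areas in μm², SA/V in μm⁻¹; the COM stays in nm
    (the internal physical unit).  Intensity fields are None when no
    intensity volume was supplied.
    """

    object_id: int
    class_name: str
    parent_cell_id: int | None
    volume: float
    surface_area: float
    sa_v_ratio: float
    com: Point3D
    voxel_count: int
    truncated: bool = False
    integrated_density: float | None = None
    mean_intensity: float | None = None

    def as_record(self) -> dict:
        rec = asdict(self)
        com = rec.pop("com")
        rec["com_x_nm"], rec["com_y_nm"], rec["com_z_nm"] = com["x"], com["y"], com["z"]
        return rec


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-dimensional (z, y, x)")
    return mask.astype(bool)


def compute_volume(mask: np.ndarray, voxel_size: tuple[float, float, float]) -> float:
    """Voxel-count volume of a binary mask, in μm³ (exact, no mesh involved)."""
    mask = _as_bool_mask(mask)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask has no volume")
    sz, sy, sx = voxel_size
    return n * sz * sy * sx / NM3_PER_UM3


def compute_surface_area(
    mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    method: str = "weighted",
) -> float:
    """Surface area of a binary mask in μm², deterministic for fixed input.

    The default ``"weighted"`` estimator sums exposed voxel faces weighted
    by the component of the local surface normal along each face axis (the
    normal comes from the gradient of a lightly Gaussian-smoothed
    indicator, in physical coordinates).  For any planar patch the weights
    integrate to the exact area — faces whose normal is nearly
    axis-aligned are clamped to weight 1 so axis-aligned facets stay exact
    — while for smooth bodies the estimate converges to the true area as
    resolution grows (a digital sphere of radius 25 voxels is recovered
    within ~4%).  Plain face counting, by contrast, overestimates smooth
    surfaces by up to ~27% and a marching-cubes mesh of the binary mask
    chamfers edges, losing ~6% on a 10-voxel cube.

    ``method="mesh"`` instead returns the area of the marching-cubes
    iso-surface extracted at level 0.5 with physical spacing.
    """
    mask = _as_bool_mask(mask)
    if not mask.any():
        raise ValueError("empty mask has no surface")
    if method == "mesh":
        padded = np.pad(mask, 1).astype(np.float32)
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(voxel_size))
        return float(measure.mesh_surface_area(verts, faces)) / NM2_PER_UM2
    if method != "weighted":
        raise ValueError(f"unknown surface-area method {method!r}")
    sz, sy, sx = voxel_size
    m = np.pad(mask, 2).astype(np.float32)
    smooth = ndimage.gaussian_filter(m, _NORMAL_SIGMA)
    gz, gy, gx = np.gradient(smooth, sz, sy, sx)
    norm = np.sqrt(gx**2 + gy**2 + gz**2)
    norm[norm == 0] = 1.0
    comps = (gz / norm, gy / norm, gx / norm)
    face_area = (sy * sx, sz * sx, sz * sy)
    b = m.astype(bool)
    total = 0.0
    for axis in range(3):
        step = np.diff(b.astype(np.int8), axis=axis)
        idx = np.argwhere(step != 0)
        if len(idx) == 0:
            continue
        w0 = np.abs(comps[axis][tuple(idx.T)])
        idx2 = idx.copy()
        idx2[:, axis] += 1
        w1 = np.abs(comps[axis][tuple(idx2.T)])
        w = np.maximum(w0, w1)
        w[w >= _PLANAR_CLAMP] = 1.0
        total += face_area[axis] * float(w.sum())
    return total / NM2_PER_UM2


# smoothing scale (voxels) for normal estimation, and the |n·e| level above
# which a face is treated as part of an axis-aligned planar patch
_NORMAL_SIGMA = 1.0
_PLANAR_CLAMP = 0.9


def compute_com(mask: np.ndarray, voxel_size: tuple[float, float, float]) -> Point3D:
    """Geometric (unweighted) centre of mass in nm.

    Voxel ``(k, j, i)`` contributes its centre ``((i+0.5)sx, (j+0.5)sy, (k+0.5)sz)``.
    """
    mask = _as_bool_mask(mask)
    if not mask.any():
        raise ValueError("empty mask has no centre of mass")
    sz, sy, sx = voxel_size
    zz, yy, xx = np.nonzero(mask)
    return Point3D(
        x=(xx.mean() + 0.5) * sx,
        y=(yy.mean() + 0.5) * sy,
        z=(zz.mean() + 0.5) * sz,
    )


def integrated_density(intensity: VoxelGrid | np.ndarray, mask: np.ndarray) -> float:
    """Sum of grayscale values over the mask (arbitrary units).

    Equals the per-slice sums totalled over z — summation order is immaterial.
    """
    data = intensity.data if isinstance(intensity, VoxelGrid) else np.asarray(intensity)
    mask = _as_bool_mask(mask)
    if data.shape != mask.shape:
        raise ValueError(f"intensity shape {data.shape} != mask shape {mask.shape}")
    return float(np.asarray(data, dtype=np.float64)[mask].sum())


def normalized_chromosomal_intensity(densities: dict[int, float] | pd.Series) -> dict[int, float]:
    """Per-chromosome integrated density as a fraction of the cell's total.

    Fractions sum to 1 and are independent of input order.
    """
    if isinstance(densities, pd.Series):
        densities = densities.to_dict()
    if not densities:
        raise ValueError("need at least one chromosome")
    total = float(sum(densities.values()))
    if total <= 0:
        raise ValueError("total chromosomal integrated density must be positive")
    return {k: float(v) / total for k, v in densities.items()}


def morphometry_table(
    labels: LabelVolume,
    intensity: VoxelGrid | None = None,
    invert_intensity: bool = False,
) -> list[ObjectMorphometry]:
    """One :class:`ObjectMorphometry` per nonzero label.

    Truncated objects (``truncated`` flag in the object index) are flagged
    but never dropped here; phase-level statistics exclude them downstream.
    ``invert_intensity`` flips the grayscale (max − value) before summing,
    for stacks where dense chromatin is dark rather than bright.
    """
    if intensity is not None:
        if intensity.data.shape != labels.labels.shape:
            raise ValueError("intensity and label volumes must share a shape")
        if intensity.voxel_size != labels.voxel_size:
            raise ValueError("intensity and label volumes must share a voxel size")
        graydata = np.asarray(intensity.data, dtype=np.float64)
        if invert_intensity:
            graydata = float(graydata.max()) - graydata
    voxel = labels.voxel_size
    slices = ndimage.find_objects(labels.labels)
    # a cell's territory includes every object parented to it: its metrics
    # are computed on the union of its own voxels and its children's
    children: dict[int, list[int]] = {}
    for oid, rec in labels.object_index.items():
        if rec.parent_cell_id is not None:
            children.setdefault(rec.parent_cell_id, []).append(oid)
    out: list[ObjectMorphometry] = []
    for oid in sorted(int(v) for v in labels.present_labels()):
        sl = slices[oid - 1]
        if labels.object_index[oid].class_name == "cell" and children.get(oid):
            sub = np.isin(labels.labels[sl], [oid] + children[oid])
        else:
            sub = labels.labels[sl] == oid
        vol = compute_volume(sub, voxel)
        area = compute_surface_area(sub, voxel)
        # COM computed in the subvolume frame then shifted by the slice origin
        com_local = compute_com(sub, voxel)
        sz, sy, sx = voxel
        origin = (sl[2].start * sx, sl[1].start * sy, sl[0].start * sz)
        com = Point3D(com_local.x + origin[0], com_local.y + origin[1], com_local.z + origin[2])
        rec = labels.object_index[oid]
        integ = mean_int = None
        if intensity is not None:
            integ = float(graydata[sl][sub].sum())
            mean_int = integ / int(sub.sum())
        out.append(
            ObjectMorphometry(
                object_id=oid,
                class_name=rec.class_name,
                parent_cell_id=rec.parent_cell_id,
                volume=vol,
                surface_area=area,
                sa_v_ratio=area / vol,
                com=com,
                voxel_count=int(sub.sum()),
                truncated=rec.truncated,
                integrated_density=integ,
                mean_intensity=mean_int,
            )
        )
    return out


def morphometry_dataframe(
    labels: LabelVolume,
    intensity: VoxelGrid | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Tabular form of :func:`morphometry_table`, sorted by object id."""
    records = [m.as_record() for m in morphometry_table(labels, intensity, **kwargs)]
    return pd.DataFrame(records)
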