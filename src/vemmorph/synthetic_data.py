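"""Synthetic phantom generator: label + intensity volumes with ground truth.

The phantoms emulate the statistical structure of segmented SBF-SEM stacks
of dividing hair-follicle cells: an ellipsoidal cell containing a nucleus
and/or discrete chromosomes, organelle populations (mitochondria, ER
fragments, vesicles) whose counts and volumes vary by mitotic phase, and a
stain model in which denser chromatin yields higher grayscale values plus
Gaussian noise.  Every generated object comes with a ground-truth record
(class, realised voxel volume, COM), so each downstream analysis stage can
be validated closed-loop.

The chromosome complement follows the diploid sheep karyotype: 26 autosome
pairs (3 metacentric + 23 acrocentric) plus a submetacentric X and a small
acrocentric Y — 54 chromosomes in total.

Default acquisition geometry is 30×30×30 nm voxels; the generator is
normally run at 90 nm (the same physical scene binned by a factor of
three), which is the resolution the packaged tests and examples use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .karyotype import ChromatidRecord
from .volio import LabelVolume, NM3_PER_UM3, NM_PER_UM, ObjectRecord, PHASES, VoxelGrid

__all__ = [
    "TemplateChromosome",
    "OrganellePopulation",
    "PhantomSpec",
    "PackingError",
    "default_ovine_template",
    "template_chromatids",
    "generate_chromatid",
    "generate_phantom_cell",
    "generate_phase_series",
    "sample_phase_morphometry",
    "DEFAULT_PHASE_EFFECTS",
]

#: Stain model (uint8 grayscale): denser chromatin is brighter.  Arbitrary
#: but fixed values; not calibrated to any physical contrast mechanism.
DEFAULT_STAIN = {
    "background": 30,
    "cytoplasm": 100,
    "nucleus": 140,
    "ER": 150,
    "vesicle": 160,
    "mitochondrion": 170,
    "chromosome": 200,
}
DEFAULT_STAIN_NOISE_SD = 8.0


class PackingError(RuntimeError):
    """Raised when requested objects cannot be placed without overlap."""


@dataclass(frozen=True)
class TemplateChromosome:
    name: str  # "1".."26", "X", "Y"
    volume: float  # μm³ (per chromatid)
    centromere_class: str
    arm_ratio: float


def default_ovine_template() -> list[TemplateChromosome]:
    """Diploid sheep chromosome template: 26 autosome pairs + X + Y.

    Pair volumes are fixed defaults chosen to respect the karyotypic volume
    ranges (metacentric pairs largest; acrocentric groups I > 3 μm³,
    II 2–3 μm³, III < 2 μm³; submetacentric X among the large chromosomes;
    Y smallest) — they are generator conventions, not measurements.
    """
    meta = [9.0, 8.2, 7.5]
    acro_I = [4.8, 4.5, 4.1, 3.8, 3.5, 3.2]
    acro_II = [2.9, 2.8, 2.7, 2.5, 2.4, 2.3, 2.2, 2.1]
    acro_III = [1.9, 1.8, 1.6, 1.5, 1.4, 1.2, 1.1, 1.0, 0.8]
    entries = []
    num = 1
    for v in meta:
        entries.append(TemplateChromosome(str(num), v, "metacentric", 1.3))
        num += 1
    for v in acro_I + acro_II + acro_III:
        entries.append(TemplateChromosome(str(num), v, "acrocentric", 5.0))
        num += 1
    entries.append(TemplateChromosome("X", 4.2, "submetacentric", 2.2))
    entries.append(TemplateChromosome("Y", 0.5, "acrocentric", 5.0))
    return entries


def template_chromatids(
    template: list[TemplateChromosome] | None = None,
    volume_noise: float = 0.015,
    seed: int = 0,
) -> tuple[list[ChromatidRecord], dict[int, str]]:
    """Realise a template as individual chromatids with volume noise.

    Each autosome entry is duplicated into two homologous chromatids; X and
    Y appear once each (54 records for the default template).  Volumes get
    independent multiplicative noise uniform in ``±volume_noise`` — the
    default ±1.5% keeps homolog volumes closer than the tightest gap
    between neighbouring template pairs, so pairing is unambiguous.
    Returns the records plus the ground-truth map object_id -> template name.
    """
    if template is None:
        template = default_ovine_template()
    rng = np.random.default_rng(seed)
    recs: list[ChromatidRecord] = []
    truth: dict[int, str] = {}
    oid = 1
    for entry in template:
        copies = 1 if entry.name in ("X", "Y") else 2
        for _ in range(copies):
            v = entry.volume * (1.0 + rng.uniform(-volume_noise, volume_noise))
            recs.append(
                ChromatidRecord(
                    object_id=oid,
                    volume=float(v),
                    centromere_class=entry.centromere_class,
                    surface_area=4.84 * float(v) ** (2 / 3),  # sphere-like scaling placeholder
                )
            )
            truth[oid] = entry.name
            oid += 1
    return recs, truth


# ---------------------------------------------------------------------------
# voxel realisation of a single chromatid


def generate_chromatid(
    volume_um3: float,
    arm_ratio: float,
    voxel_size=(90.0, 90.0, 90.0),
    seed: int = 0,
    aspect: float = 10.0,
    waist_depth: float = 0.45,
    bend_deg: float = 35.0,
) -> np.ndarray:
    """Voxelise a bent-rod chromatid with a centromeric waist.

    The rod is a tube of length L and radius R (L = ``aspect``·R) around a
    two-segment polyline bent by ``bend_deg`` at the waist, which sits at
    arclength fraction ``1/(1+arm_ratio)``; the radius dips by
    ``waist_depth`` at the waist.  The realised voxel volume is calibrated
    to within 5% of the target by rescaling R.  Deterministic per seed
    (the seed only randomises the in-plane bend orientation).
    """
    if arm_ratio < 1:
        raise ValueError("arm_ratio must be >= 1")
    voxel_size = tuple(float(v) for v in voxel_size)
    vox_vol = voxel_size[0] * voxel_size[1] * voxel_size[2]
    target_nm3 = volume_um3 * NM3_PER_UM3
    if target_nm3 < 50 * vox_vol:
        raise ValueError(
            f"target volume {volume_um3} μm³ is below resolution (needs ≥ 50 voxels)"
        )
    rng = np.random.default_rng(seed)
    R = (target_nm3 / (np.pi * aspect)) ** (1 / 3)
    L = aspect * R
    f = 1.0 / (1.0 + arm_ratio)  # short-arm fraction
    theta = np.deg2rad(bend_deg)
    phi = rng.uniform(0, 2 * np.pi)
    # polyline in physical nm: waist at origin, arms along bent directions
    d1 = np.array([np.cos(theta / 2), np.sin(theta / 2) * np.cos(phi), np.sin(theta / 2) * np.sin(phi)])
    d2 = np.array([np.cos(theta / 2), -np.sin(theta / 2) * np.cos(phi), -np.sin(theta / 2) * np.sin(phi)])
    p_start = -f * L * d1
    p_end = (1 - f) * L * d2

    step = 0.5 * min(voxel_size)
    n1 = max(2, int(np.ceil(f * L / step)))
    n2 = max(2, int(np.ceil((1 - f) * L / step)))
    seg1 = p_start + np.linspace(0, 1, n1)[:, None] * (np.zeros(3) - p_start)
    seg2 = np.linspace(0, 1, n2)[:, None] * p_end
    poly = np.vstack([seg1, seg2[1:]])
    arcs = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(poly, axis=0), axis=1))])
    s_frac = arcs / arcs[-1]
    waist_w = 0.08  # waist width as a fraction of arclength

    def radius_profile(scale: float) -> np.ndarray:
        return scale * R * (1.0 - waist_depth * np.exp(-(((s_frac - f) / waist_w) ** 2)))

    sz, sy, sx = voxel_size
    margin = 1.6 * R
    lo = poly.min(axis=0) - margin
    hi = poly.max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / s)) + 1 for i, s in enumerate((sx, sy, sz)))
    # voxel centre coordinates in the local physical frame, indexed (z, y, x)
    xs = lo[0] + (np.arange(shape[0]) + 0.5) * sx
    ys = lo[1] + (np.arange(shape[1]) + 0.5) * sy
    zs = lo[2] + (np.arange(shape[2]) + 0.5) * sz
    gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
    coords = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    tree = cKDTree(poly)
    dist, idx = tree.query(coords, workers=-1)

    scale = 1.0
    for _ in range(6):
        mask_flat = dist <= radius_profile(scale)[idx]
        realised = mask_flat.sum() * vox_vol
        rel = realised / target_nm3
        if abs(rel - 1.0) <= 0.05:
            break
        scale /= np.sqrt(rel)
    mask = mask_flat.reshape(len(zs), len(ys), len(xs))
    if not mask.any():
        raise ValueError("chromatid voxelisation produced an empty mask")
    return mask


# ---------------------------------------------------------------------------
# whole-cell phantom


@dataclass(frozen=True)
class OrganellePopulation:
    """One organelle class population within a phantom cell."""

    count: int
    mean_volume_um3: float
    volume_cv: float = 0.25
    pattern: str = "uniform"  # uniform | central_hotspot | cortical | clustered
    cluster_k: int = 3

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.mean_volume_um3 <= 0:
            raise ValueError("mean fragment volume must be positive")
        if self.pattern not in ("uniform", "central_hotspot", "cortical", "clustered"):
            raise ValueError(f"unknown spatial pattern {self.pattern!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom cell.

    Defaults describe the reference scene: a 15×15×12 μm cell imaged at
    30 nm isotropic voxels.  ``binned(3)`` gives the same physical scene at
    90 nm, the resolution used throughout the packaged tests.
    """

    seed: int = 0
    voxel_size: tuple[float, float, float] = (30.0, 30.0, 30.0)  # nm (sz, sy, sx)
    phase: str = "metaphase"
    cell_semi_axes_um: tuple[float, float, float] = (7.5, 7.5, 6.0)  # (x, y, z)
    chromosome_volumes_um3: tuple[float, ...] = ()
    chromosome_displacement_um: float = 1.5
    displacement_cv: float = 0.08
    organelles: dict = field(default_factory=dict)  # class -> OrganellePopulation
    stain: dict = field(default_factory=lambda: dict(DEFAULT_STAIN))
    stain_noise_sd: float = DEFAULT_STAIN_NOISE_SD
    margin_um: float = 0.5

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.stain_noise_sd < 0:
            raise ValueError("stain noise s.d. must be >= 0")
        if any(v <= 0 for v in self.chromosome_volumes_um3):
            raise ValueError("chromosome volumes must be positive")

    @property
    def has_nucleus(self) -> bool:
        # nuclear envelope persists through prophase; gone from metaphase on
        return self.phase in ("non_dividing", "prophase_I", "prophase_II", "prophase_III")

    def binned(self, factor: int = 3) -> "PhantomSpec":
        return replace(self, voxel_size=tuple(v * factor for v in self.voxel_size))


def _ellipsoid_mask(shape_zyx, center_xyz_nm, semi_xyz_nm, voxel_size) -> np.ndarray:
    sz, sy, sx = voxel_size
    nz, ny, nx = shape_zyx
    zc = (np.arange(nz) + 0.5) * sz
    yc = (np.arange(ny) + 0.5) * sy
    xc = (np.arange(nx) + 0.5) * sx
    gz, gy, gx = np.meshgrid(zc, yc, xc, indexing="ij")
    cx, cy, cz = center_xyz_nm
    ax, ay, az = semi_xyz_nm
    return ((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2 + ((gz - cz) / az) ** 2 <= 1.0


def _local_ellipsoid(semi_xyz_nm, voxel_size, rng) -> np.ndarray:
    """Small axis-aligned ellipsoid mask with a random axis permutation."""
    sz, sy, sx = voxel_size
    ax, ay, az = semi_xyz_nm
    perm = rng.permutation(3)
    semis = np.array([ax, ay, az])[perm]
    nx = max(1, int(np.ceil(2 * semis[0] / sx)) + 1)
    ny = max(1, int(np.ceil(2 * semis[1] / sy)) + 1)
    nz = max(1, int(np.ceil(2 * semis[2] / sz)) + 1)
    xc = (np.arange(nx) - (nx - 1) / 2) * sx
    yc = (np.arange(ny) - (ny - 1) / 2) * sy
    zc = (np.arange(nz) - (nz - 1) / 2) * sz
    gz, gy, gx = np.meshgrid(zc, yc, xc, indexing="ij")
    return (gx / semis[0]) ** 2 + (gy / semis[1]) ** 2 + (gz / semis[2]) ** 2 <= 1.0


def _stamp(labels, region_ok, local_mask, center_idx_zyx, object_id) -> tuple[bool, np.ndarray]:
    """Stamp local_mask into labels at the given centre if all target voxels
    are free (region_ok) — returns (success, (z,y,x) voxel indices)."""
    lz, ly, lx = local_mask.shape
    z0 = center_idx_zyx[0] - lz // 2
    y0 = center_idx_zyx[1] - ly // 2
    x0 = center_idx_zyx[2] - lx // 2
    if z0 < 0 or y0 < 0 or x0 < 0:
        return False, None
    if z0 + lz > labels.shape[0] or y0 + ly > labels.shape[1] or x0 + lx > labels.shape[2]:
        return False, None
    sl = (slice(z0, z0 + lz), slice(y0, y0 + ly), slice(x0, x0 + lx))
    if not region_ok[sl][local_mask].all():
        return False, None
    labels[sl][local_mask] = object_id
    zz, yy, xx = np.nonzero(local_mask)
    return True, (zz + z0, yy + y0, xx + x0)


def _sample_position(pattern, rng, cell_center, semi_nm, cluster_centers=None):
    """One candidate (x, y, z) position inside the cell for a given pattern."""
    if pattern == "uniform":
        while True:
            u = rng.uniform(-1, 1, 3)
            if (u**2).sum() <= 1:
                return cell_center + 0.85 * u * semi_nm
    if pattern == "central_hotspot":
        return cell_center + rng.normal(0.0, 0.18, 3) * semi_nm
    if pattern == "cortical":
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        return cell_center + rng.uniform(0.7, 0.88) * v * semi_nm
    if pattern == "clustered":
        c = cluster_centers[rng.integers(len(cluster_centers))]
        return c + rng.normal(0.0, 0.8 * NM_PER_UM, 3)
    raise ValueError(pattern)


def generate_phantom_cell(spec: PhantomSpec) -> tuple[VoxelGrid, LabelVolume, pd.DataFrame]:
    """Generate one phantom cell: intensity volume, label volume, ground truth.

    Objects never overlap; chromosomes sit inside the nucleus while the
    nuclear envelope persists (non-dividing and prophase) and free in the
    cytoplasm from metaphase on.  The ground-truth table records, for every
    label, its class, target and realised volume, voxel count and realised
    COM.  Output is bit-identical for identical specs (one seeded RNG
    drives both geometry and stain noise).  Unplaceable objects raise
    :class:`PackingError` with packing diagnostics.
    """
    rng = np.random.default_rng(spec.seed)
    sz, sy, sx = spec.voxel_size
    ax, ay, az = (s * NM_PER_UM for s in spec.cell_semi_axes_um)
    m = spec.margin_um * NM_PER_UM
    shape = (
        int(np.ceil(2 * (az + m) / sz)),
        int(np.ceil(2 * (ay + m) / sy)),
        int(np.ceil(2 * (ax + m) / sx)),
    )
    center = np.array([ax + m, ay + m, az + m])  # (x, y, z) nm
    semi_nm = np.array([ax, ay, az])
    labels = np.zeros(shape, dtype=np.uint16)
    cell_mask = _ellipsoid_mask(shape, center, semi_nm, spec.voxel_size)
    labels[cell_mask] = 1
    index: dict[int, ObjectRecord] = {1: ObjectRecord("cell", None, False)}
    vox_vol = sz * sy * sx
    truth_rows: list[dict] = []

    next_id = 2
    if spec.has_nucleus:
        nuc_semi = 0.55 * semi_nm
        nuc_mask = _ellipsoid_mask(shape, center, nuc_semi, spec.voxel_size)
        labels[nuc_mask] = 2
        index[2] = ObjectRecord("nucleus", 1, False)
        next_id = 3

    chrom_region_label = 2 if spec.has_nucleus else 1
    region_semi = 0.55 * semi_nm if spec.has_nucleus else semi_nm

    def place(obj_class, local_mask, pattern, parent_region_label, target_vol, radius_nm=None,
              cluster_centers=None):
        nonlocal next_id
        oid = next_id
        region_ok = labels == parent_region_label
        free = float(region_ok.sum()) * vox_vol / NM3_PER_UM3
        if radius_nm is not None:
            # one jittered target radius per object; failed attempts probe
            # radii alternating symmetrically around it (no upward bias)
            r0 = abs(rng.normal(radius_nm, spec.displacement_cv * max(radius_nm, NM_PER_UM)))
        for attempt in range(400):
            if radius_nm is not None:
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                step = 0.15 * NM_PER_UM * ((attempt + 1) // 2)
                r = max(0.0, r0 + ((-1) ** attempt) * step)
                pos = center + r * v
            else:
                pos = _sample_position(pattern, rng, center, region_semi if parent_region_label == 2 else semi_nm,
                                       cluster_centers)
            cidx = (int(pos[2] / sz), int(pos[1] / sy), int(pos[0] / sx))
            if not (0 <= cidx[0] < shape[0] and 0 <= cidx[1] < shape[1] and 0 <= cidx[2] < shape[2]):
                continue
            ok, _ = _stamp(labels, region_ok, local_mask, cidx, oid)
            if ok:
                next_id += 1
                return oid
        raise PackingError(
            f"could not place {obj_class} (id {oid}, {int(local_mask.sum())} voxels, "
            f"pattern {pattern!r}) after 400 attempts; free {obj_class}-region volume "
            f"{free:.1f} μm³"
        )

    # chromosomes: ellipsoidal bodies at the phase's radial displacement
    for v_um3 in spec.chromosome_volumes_um3:
        shape_ratios = np.array([1.8, 1.0, 0.7]) * (1.0 + rng.uniform(-0.1, 0.1, 3))
        c = (3.0 * v_um3 * NM3_PER_UM3 / (4 * np.pi * np.prod(shape_ratios))) ** (1 / 3)
        local = _local_ellipsoid(tuple(c * shape_ratios), spec.voxel_size, rng)
        disp = spec.chromosome_displacement_um * NM_PER_UM
        oid = place("chromosome", local, "radial", chrom_region_label, v_um3, radius_nm=disp)
        index[oid] = ObjectRecord("chromosome", 1, False)
        truth_rows.append(
            _truth_row(oid, "chromosome", spec.phase, v_um3, labels == oid, spec.voxel_size, "radial")
        )

    # organelles in the cytoplasm
    for cls in sorted(spec.organelles):
        pop: OrganellePopulation = spec.organelles[cls]
        cluster_centers = None
        if pop.pattern == "clustered":
            cluster_centers = [
                _sample_position("uniform", rng, center, semi_nm) for _ in range(pop.cluster_k)
            ]
        for _ in range(pop.count):
            v = pop.mean_volume_um3 * rng.lognormal(mean=0.0, sigma=pop.volume_cv)
            r = (3.0 * v * NM3_PER_UM3 / (4 * np.pi)) ** (1 / 3)
            ratios = np.array([1.0, 1.0, 1.0]) + rng.uniform(-0.15, 0.25, 3)
            ratios /= np.prod(ratios) ** (1 / 3)  # shape jitter, volume preserved
            local = _local_ellipsoid(tuple(r * ratios), spec.voxel_size, rng)
            oid = place(cls, local, pop.pattern, 1, v, cluster_centers=cluster_centers)
            index[oid] = ObjectRecord(cls, 1, False)
            truth_rows.append(
                _truth_row(oid, cls, spec.phase, v, labels == oid, spec.voxel_size, pop.pattern)
            )

    # container truth is taken from the final labels: the cell's volume is
    # the full ellipsoid (it contains every child object), while the
    # nucleus excludes the chromosomes carved out of it — matching what
    # morphometry measures on the label volume
    truth_rows.insert(0, _truth_row(1, "cell", spec.phase, None, cell_mask, spec.voxel_size, None))
    if spec.has_nucleus:
        truth_rows.insert(1, _truth_row(2, "nucleus", spec.phase, None, labels == 2, spec.voxel_size, None))

    label_volume = LabelVolume(labels=labels, voxel_size=spec.voxel_size, object_index=index)

    # stain model: per-class mean + Gaussian noise, uint8
    intensity = np.full(shape, float(spec.stain["background"]), dtype=np.float32)
    intensity[labels == 1] = spec.stain["cytoplasm"]
    for oid, rec in index.items():
        if rec.class_name in ("nucleus", "chromosome", "mitochondrion", "ER", "vesicle"):
            intensity[labels == oid] = spec.stain[rec.class_name]
    intensity += rng.normal(0.0, spec.stain_noise_sd, size=shape).astype(np.float32)
    grid = VoxelGrid(
        data=np.clip(np.rint(intensity), 0, 255).astype(np.uint8),
        voxel_size=spec.voxel_size,
    )
    truth = pd.DataFrame(truth_rows)
    return grid, label_volume, truth


def _truth_row(oid, cls, phase, target_vol, mask, voxel_size, pattern) -> dict:
    sz, sy, sx = voxel_size
    zz, yy, xx = np.nonzero(mask)
    n = len(zz)
    return {
        "object_id": oid,
        "class": cls,
        "phase": phase,
        "pattern": pattern,
        "target_volume_um3": target_vol,
        "true_volume_um3": n * sz * sy * sx / NM3_PER_UM3,
        "voxel_count": n,
        "com_x_nm": (xx.mean() + 0.5) * sx,
        "com_y_nm": (yy.mean() + 0.5) * sy,
        "com_z_nm": (zz.mean() + 0.5) * sz,
    }


# ---------------------------------------------------------------------------
# phase series


#: Per-phase effect multipliers on the base populations, encoding the
#: trends the analysis is designed to detect: mitochondrial volume/count
#: rising through prophase and peaking around metaphase with a central
#: concentration at telophase; ER fragment counts dipping to metaphase then
#: rebounding; vesicles peaking at metaphase; chromosomal displacement
#: increasing monotonically from prophase to cytokinesis; dividing cells
#: larger than non-dividing ones.
DEFAULT_PHASE_EFFECTS: dict[str, dict] = {
    "non_dividing": dict(cell_scale=1.00, nuc_scale=1.00, mito_count=1.0, mito_vol=1.0,
                         er_count=1.2, er_vol=1.0, ves_count=0.8, ves_vol=1.0,
                         displacement_um=0.0, mito_pattern="uniform"),
    "prophase_I": dict(cell_scale=1.30, nuc_scale=1.30, mito_count=1.0, mito_vol=1.1,
                       er_count=1.1, er_vol=1.05, ves_count=0.9, ves_vol=1.0,
                       displacement_um=2.0, mito_pattern="uniform"),
    "prophase_II": dict(cell_scale=1.30, nuc_scale=1.20, mito_count=1.25, mito_vol=1.5,
                        er_count=1.0, er_vol=1.1, ves_count=1.0, ves_vol=1.05,
                        displacement_um=2.4, mito_pattern="uniform"),
    "prophase_III": dict(cell_scale=1.28, nuc_scale=1.10, mito_count=1.5, mito_vol=1.9,
                         er_count=0.9, er_vol=1.15, ves_count=1.1, ves_vol=1.1,
                         displacement_um=2.8, mito_pattern="uniform"),
    "metaphase": dict(cell_scale=1.20, nuc_scale=None, mito_count=1.75, mito_vol=1.95,
                      er_count=0.8, er_vol=1.2, ves_count=1.5, ves_vol=1.4,
                      displacement_um=3.2, mito_pattern="uniform"),
    "anaphase": dict(cell_scale=1.20, nuc_scale=None, mito_count=1.7, mito_vol=1.9,
                     er_count=1.5, er_vol=1.6, ves_count=1.2, ves_vol=1.2,
                     displacement_um=3.6, mito_pattern="clustered"),
    "telophase": dict(cell_scale=1.18, nuc_scale=None, mito_count=1.7, mito_vol=1.9,
                      er_count=1.6, er_vol=1.6, ves_count=0.9, ves_vol=1.0,
                      displacement_um=4.1, mito_pattern="central_hotspot"),
    "cytokinesis": dict(cell_scale=1.18, nuc_scale=None, mito_count=1.6, mito_vol=1.85,
                        er_count=1.6, er_vol=1.55, ves_count=0.85, ves_vol=0.95,
                        displacement_um=4.6, mito_pattern="clustered"),
}

#: Base (multiplier = 1) populations for the reference scene.
BASE_ORGANELLES = {
    "mitochondrion": dict(count=40, mean_volume_um3=0.15),
    "ER": dict(count=50, mean_volume_um3=0.05),
    "vesicle": dict(count=35, mean_volume_um3=0.02),
}
#: Chromosome body volumes used in whole-cell phantoms (a mid-size subset
#: of the karyotype; the full 54-chromatid template is exercised through
#: template_chromatids / generate_chromatid instead).
PHANTOM_CHROMOSOME_VOLUMES = (2.9, 2.5, 2.1, 1.8, 1.5, 1.2, 1.1, 1.0, 0.8, 0.5)


def _spec_for_phase(base: PhantomSpec, phase: str, effects: dict, seed: int) -> PhantomSpec:
    eff = effects[phase]
    orgs = {}
    for cls, b in BASE_ORGANELLES.items():
        key = {"mitochondrion": "mito", "ER": "er", "vesicle": "ves"}[cls]
        pattern = eff.get("mito_pattern", "uniform") if cls == "mitochondrion" else "uniform"
        # per-fragment volume scales with combined volume (count handled separately)
        orgs[cls] = OrganellePopulation(
            count=int(round(b["count"] * eff[f"{key}_count"])),
            mean_volume_um3=b["mean_volume_um3"] * eff[f"{key}_vol"] / eff[f"{key}_count"],
            pattern=pattern,
        )
    scale = eff["cell_scale"] ** (1 / 3)
    # non-dividing cells carry no discrete chromosomes (chromatin is not
    # condensed); dividing phases get the mid-size chromosome subset
    chrom = () if phase == "non_dividing" else PHANTOM_CHROMOSOME_VOLUMES
    return replace(
        base,
        seed=seed,
        phase=phase,
        cell_semi_axes_um=tuple(s * scale for s in base.cell_semi_axes_um),
        chromosome_volumes_um3=chrom,
        chromosome_displacement_um=eff["displacement_um"],
        organelles=orgs,
    )


def generate_phase_series(
    base_spec: PhantomSpec | None = None,
    effects: dict[str, dict] | None = None,
    seed: int = 0,
    phases: list[str] | None = None,
    cells_per_phase: int = 1,
) -> dict[str, list[tuple[VoxelGrid, LabelVolume, pd.DataFrame]]]:
    """Generate phantom cells across mitotic phases with planted trends.

    ``effects`` gives per-phase multipliers on organelle count/volume, cell
    size and chromosomal displacement (defaults plant the reference
    trends).  Each cell gets an independent child seed derived from
    ``seed``; output is deterministic.
    """
    if base_spec is None:
        base_spec = PhantomSpec(voxel_size=(90.0, 90.0, 90.0))
    effects = effects or DEFAULT_PHASE_EFFECTS
    phases = phases or [p for p in PHASES if p in effects]
    rng = np.random.default_rng(seed)
    out: dict[str, list] = {}
    for phase in phases:
        out[phase] = []
        for _ in range(cells_per_phase):
            child = int(rng.integers(0, 2**31 - 1))
            spec = _spec_for_phase(base_spec, phase, effects, child)
            out[phase].append(generate_phantom_cell(spec))
    return out


def sample_phase_morphometry(
    n_cells: dict[str, int],
    seed: int = 0,
    effects: dict[str, dict] | None = None,
    base_spec: PhantomSpec | None = None,
    cell_volume_cv: float = 0.02,
) -> pd.DataFrame:
    """Sample per-cell summary morphometry from the phantom distributions.

    This is the generator's distribution-level mode: per-cell quantities
    (cell/nuclear volume, organelle counts and combined volumes, mean
    chromosomal displacement) are drawn from the same per-phase parameters
    that drive the voxel phantoms, without voxelising anything — suitable
    for power and type-I simulations that need hundreds of cells.
    ``cell_volume_cv`` is the per-axis relative jitter on the cell
    semi-axes (volume c.v. ≈ 3× that).
    """
    effects = effects or DEFAULT_PHASE_EFFECTS
    base_spec = base_spec or PhantomSpec(voxel_size=(90.0, 90.0, 90.0))
    rng = np.random.default_rng(seed)
    base_cell_vol = 4 / 3 * np.pi * np.prod(base_spec.cell_semi_axes_um)
    rows = []
    cid = 1
    for phase in [p for p in PHASES if p in n_cells]:
        eff = effects[phase]
        for _ in range(n_cells[phase]):
            jitter = (1.0 + rng.normal(0.0, cell_volume_cv)) ** 3
            cell_vol = base_cell_vol * eff["cell_scale"] * jitter
            nuc_vol = (
                0.55**3 * base_cell_vol * eff["nuc_scale"] * (1.0 + rng.normal(0.0, 3 * cell_volume_cv))
                if eff["nuc_scale"] is not None
                else np.nan
            )
            row = {"cell_id": cid, "phase": phase, "cell_volume_um3": cell_vol, "nuclear_volume_um3": nuc_vol}
            for cls, b in BASE_ORGANELLES.items():
                key = {"mitochondrion": "mito", "ER": "er", "vesicle": "ves"}[cls]
                count = int(rng.poisson(b["count"] * eff[f"{key}_count"]))
                comb = b["count"] * b["mean_volume_um3"] * eff[f"{key}_vol"] * (1.0 + rng.normal(0.0, 0.1))
                row[f"{cls}_count"] = count
                row[f"{cls}_volume_um3"] = comb
            d = eff["displacement_um"]
            row["chromosome_displacement_um"] = (
                float(np.mean(np.abs(rng.normal(d, base_spec.displacement_cv * max(d, 1.0), 10))))
                if d > 0
                else np.nan
            )
            rows.append(row)
            cid += 1
    return pd.DataFrame(rows)
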