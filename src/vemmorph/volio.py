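"""Volume and table I/O with shared coordinate and unit conventions.

All arrays are indexed ``(z, y, x)`` and voxel sizes are carried as
``(sz, sy, sx)`` in nanometres.  The physical coordinate of the centre of
voxel ``(k, j, i)`` is ``((i + 0.5) * sx, (j + 0.5) * sy, (k + 0.5) * sz)``,
with the origin at the corner of voxel (0, 0, 0).  Every physical quantity
is kept internally in nm / nm^2 / nm^3 and converted to micrometre units
exactly once, at reporting boundaries.

Volumes are stored as multipage TIFF (with a JSON sidecar carrying the
voxel size and object index) or as HDF5 (datasets ``/labels`` and/or
``/intensity`` with attribute ``voxel_size_nm``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

OBJECT_CLASSES = ("cell", "nucleus", "chromosome", "mitochondrion", "ER", "vesicle")

#: Mitotic phases in chronological order, non-dividing first.
PHASES = (
    "non_dividing",
    "prophase_I",
    "prophase_II",
    "prophase_III",
    "metaphase",
    "anaphase",
    "telophase",
    "cytokinesis",
)

NM3_PER_UM3 = 1e9
NM2_PER_UM2 = 1e6
NM_PER_UM = 1e3


class VolumeIOError(ValueError):
    """Raised for malformed volumes or missing metadata."""


@dataclass(frozen=True)
class Point3D:
    """A point in physical coordinates (nm), origin at the (0,0,0) voxel corner."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("Point3D coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class VoxelGrid:
    """A 3D grayscale volume with per-axis voxel size in nm, indexed (z, y, x)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]  # (sz, sy, sx) nm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeIOError("volume must be 3-dimensional (z, y, x)")
        if min(self.data.shape) < 1:
            raise VolumeIOError("volume must have extent >= 1 along each axis")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise VolumeIOError("voxel sizes must be three positive values (sz, sy, sx) in nm")

    @property
    def voxel_volume_nm3(self) -> float:
        sz, sy, sx = self.voxel_size
        return sz * sy * sx


@dataclass(frozen=True)
class ObjectRecord:
    """Object-index entry: semantic class, owning cell and truncation status."""

    class_name: str
    parent_cell_id: int | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.class_name not in OBJECT_CLASSES:
            raise VolumeIOError(
                f"unknown object class {self.class_name!r}; expected one of {OBJECT_CLASSES}"
            )


@dataclass
class LabelVolume:
    """Integer label volume (0 = background) plus the object index.

    Every nonzero label must appear in ``object_index``; the parent of a
    non-cell object must either be null or a cell ID present in the index.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    object_index: dict[int, ObjectRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeIOError("label volume must be 3-dimensional (z, y, x)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeIOError("label volume must have an integer dtype")
        if self.labels.min() < 0:
            raise VolumeIOError("labels must be non-negative (0 = background)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise VolumeIOError("voxel sizes must be three positive values (sz, sy, sx) in nm")
        self.object_index = {int(k): v for k, v in self.object_index.items()}
        self.validate()

    def validate(self) -> None:
        present = self.present_labels()
        missing = [int(l) for l in present if int(l) not in self.object_index]
        if missing:
            raise VolumeIOError(f"labels missing from object_index: {missing[:10]}")
        cells = {i for i, rec in self.object_index.items() if rec.class_name == "cell"}
        for oid, rec in self.object_index.items():
            if rec.class_name != "cell" and rec.parent_cell_id is not None:
                if rec.parent_cell_id not in cells:
                    raise VolumeIOError(
                        f"object {oid}: parent_cell_id {rec.parent_cell_id} is not a cell in the index"
                    )

    def present_labels(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals != 0]

    @property
    def voxel_volume_nm3(self) -> float:
        sz, sy, sx = self.voxel_size
        return sz * sy * sx

    def mask(self, object_id: int) -> np.ndarray:
        return self.labels == object_id


@dataclass
class PhaseAnnotation:
    """Mapping cell_id -> mitotic phase; every analysed cell has exactly one phase."""

    phases: dict[int, str]

    def __post_init__(self) -> None:
        self.phases = {int(k): str(v) for k, v in self.phases.items()}
        bad = sorted(set(self.phases.values()) - set(PHASES))
        if bad:
            raise VolumeIOError(f"unknown phase labels: {bad}; expected one of {PHASES}")

    def __getitem__(self, cell_id: int) -> str:
        return self.phases[cell_id]

    def get(self, cell_id: int, default: str | None = None) -> str | None:
        return self.phases.get(cell_id, default)


# ---------------------------------------------------------------------------
# volume I/O


def _object_index_to_json(index: Mapping[int, ObjectRecord]) -> str:
    return json.dumps(
        {
            str(k): {
                "class": v.class_name,
                "parent_cell_id": v.parent_cell_id,
                "truncated": bool(v.truncated),
            }
            for k, v in index.items()
        }
    )


def _object_index_from_json(payload: str | Mapping) -> dict[int, ObjectRecord]:
    raw = json.loads(payload) if isinstance(payload, str) else payload
    return {
        int(k): ObjectRecord(
            class_name=v["class"],
            parent_cell_id=None if v.get("parent_cell_id") is None else int(v["parent_cell_id"]),
            truncated=bool(v.get("truncated", False)),
        )
        for k, v in raw.items()
    }


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(path: str | Path, volume: VoxelGrid | LabelVolume) -> None:
    """Write a volume to TIFF (+ JSON sidecar) or HDF5, preserving metadata exactly."""
    path = Path(path)
    is_labels = isinstance(volume, LabelVolume)
    data = volume.labels if is_labels else volume.data
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("labels" if is_labels else "intensity", data=data)
            ds.attrs["voxel_size_nm"] = np.asarray(volume.voxel_size, dtype=float)
            if is_labels:
                ds.attrs["object_index_json"] = _object_index_to_json(volume.object_index)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data)
        sidecar = {"voxel_size_nm": list(volume.voxel_size), "kind": "labels" if is_labels else "intensity"}
        if is_labels:
            sidecar["object_index"] = json.loads(_object_index_to_json(volume.object_index))
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    else:
        raise VolumeIOError(f"unsupported volume format: {path.suffix!r} (use .tif/.tiff/.h5/.hdf5)")


def read_volume(path: str | Path, format_hint: str | None = None) -> VoxelGrid | LabelVolume:
    """Read a volume written by :func:`write_volume`.

    ``format_hint`` may be ``"labels"`` or ``"intensity"`` to force the
    interpretation; otherwise the stored metadata decides.  A missing voxel
    size is an error — it is never silently assumed to be 1 nm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            name = None
            if format_hint == "labels" or (format_hint is None and "labels" in f):
                name = "labels"
            elif format_hint == "intensity" or (format_hint is None and "intensity" in f):
                name = "intensity"
            if name is None or name not in f:
                raise VolumeIOError(f"no usable dataset in {path} (expected /labels or /intensity)")
            ds = f[name]
            if "voxel_size_nm" not in ds.attrs:
                raise VolumeIOError(f"voxel size required but missing in {path}")
            voxel = tuple(float(v) for v in ds.attrs["voxel_size_nm"])
            data = ds[()]
            if name == "labels":
                if not np.issubdtype(data.dtype, np.integer):
                    raise VolumeIOError("labels dataset must be integer-typed")
                index = _object_index_from_json(ds.attrs.get("object_index_json", "{}"))
                return LabelVolume(labels=data, voxel_size=voxel, object_index=index)
            return VoxelGrid(data=data, voxel_size=voxel)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
        sidecar_file = _sidecar_path(path)
        if not sidecar_file.exists():
            raise VolumeIOError(f"voxel size required: no sidecar {sidecar_file.name} next to {path.name}")
        sidecar = json.loads(sidecar_file.read_text())
        if "voxel_size_nm" not in sidecar:
            raise VolumeIOError(f"voxel size required but missing in {sidecar_file}")
        voxel = tuple(float(v) for v in sidecar["voxel_size_nm"])
        kind = format_hint or sidecar.get("kind", "intensity")
        if kind == "labels":
            if not np.issubdtype(data.dtype, np.integer):
                raise VolumeIOError("non-integer data cannot be interpreted as labels")
            index = _object_index_from_json(sidecar.get("object_index", {}))
            return LabelVolume(labels=data, voxel_size=voxel, object_index=index)
        return VoxelGrid(data=data, voxel_size=voxel)
    raise VolumeIOError(f"unsupported volume format: {path.suffix!r}")


# ---------------------------------------------------------------------------
# table I/O


def write_table(records: Iterable[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write records as CSV with header; deterministic row order.

    Rows are sorted by ``cell_id`` then ``object_id`` where those columns
    exist.  Numeric formatting is locale-independent (dot decimal separator).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(list(records))
    sort_cols = [c for c in ("cell_id", "object_id") if c in df.columns]
    if sort_cols and len(df):
        df = df.sort_values(sort_cols, kind="stable")
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_phase_annotation(annotation: PhaseAnnotation, path: str | Path) -> None:
    rows = [{"cell_id": cid, "phase": ph} for cid, ph in sorted(annotation.phases.items())]
    write_table(rows, path)


def read_phase_annotation(path: str | Path) -> PhaseAnnotation:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return PhaseAnnotation(phases=json.loads(path.read_text()))
    df = read_table(path)
    return PhaseAnnotation(phases=dict(zip(df["cell_id"], df["phase"])))
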