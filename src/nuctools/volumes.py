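"""3D label/probability volumes with physical voxel spacing, and file I/O.

Volumes are indexed ``(z, y, x)`` everywhere — one TIFF page per z-slice —
and carry their voxel spacing in µm. Two on-disk formats are supported:

* multipage grayscale TIFF (spacing stored as ImageJ metadata where the
  dtype permits, otherwise as a JSON ImageDescription tag);
* HDF5 with a single named 3D dataset (spacing stored in the
  ``element_size_um`` attribute, the convention used by ilastik/PlantSeg).

Spacing resolution is strict: an explicit argument wins over file metadata,
and a volume without either raises — physical quantities must never be
computed against a silently assumed calibration.
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

__all__ = [
    "VoxelSpacing",
    "LabelVolume",
    "ProbabilityVolume",
    "read_volume",
    "write_volume",
    "write_table",
]

_TIFF_META_PREFIX = "nuctools:"


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical size of one voxel in µm along z, y, x."""

    dz: float
    dy: float
    dx: float

    def __post_init__(self) -> None:
        for name in ("dz", "dy", "dx"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"voxel spacing {name}={v!r} must be finite and > 0")
            object.__setattr__(self, name, v)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.dz * self.dy * self.dx

    def as_array(self) -> np.ndarray:
        return np.asarray([self.dz, self.dy, self.dx], dtype=float)


def _check_3d(voxels: np.ndarray) -> np.ndarray:
    voxels = np.asarray(voxels)
    if voxels.ndim != 3:
        raise ValueError(f"expected a 3D (z, y, x) array, got shape {voxels.shape}")
    return voxels


@dataclass
class LabelVolume:
    """3D grid of instance IDs; 0 is background, IDs need not be contiguous."""

    voxels: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.voxels = _check_3d(self.voxels)
        if not np.issubdtype(self.voxels.dtype, np.integer):
            if np.issubdtype(self.voxels.dtype, np.bool_):
                self.voxels = self.voxels.astype(np.uint8)
            else:
                raise TypeError(f"label voxels must be integer, got {self.voxels.dtype}")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("label voxels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def ids(self) -> np.ndarray:
        """Sorted positive instance IDs present in the volume."""
        u = np.unique(self.voxels)
        return u[u > 0]

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.voxels.copy(), self.spacing)


@dataclass
class ProbabilityVolume:
    """3D grid of reals in [0, 1], e.g. a cell-boundary prediction."""

    voxels: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.voxels = _check_3d(self.voxels).astype(np.float32, copy=False)
        if self.voxels.size:
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < 0.0 or hi > 1.0:
                raise ValueError(f"probability voxels outside [0, 1]: range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


Volume = LabelVolume | ProbabilityVolume


def _label_dtype(max_id: int) -> np.dtype:
    for dt in (np.uint8, np.uint16, np.uint32, np.uint64):
        if max_id <= np.iinfo(dt).max:
            return np.dtype(dt)
    raise ValueError(f"label ID {max_id} exceeds supported integer width")


def _wrap(voxels: np.ndarray, spacing: VoxelSpacing) -> Volume:
    if np.issubdtype(voxels.dtype, np.integer) or np.issubdtype(voxels.dtype, np.bool_):
        return LabelVolume(voxels.astype(np.int64, copy=False), spacing)
    return ProbabilityVolume(voxels, spacing)


def _tiff_spacing(tif: tifffile.TiffFile) -> VoxelSpacing | None:
    # self-written JSON tag takes priority, then ImageJ spacing + resolution
    desc = tif.pages[0].description or ""
    if desc.startswith(_TIFF_META_PREFIX):
        meta = json.loads(desc[len(_TIFF_META_PREFIX):])
        return VoxelSpacing(*meta["spacing_um_zyx"])
    ij = tif.imagej_metadata
    if ij is not None and "spacing" in ij:
        dz = float(ij["spacing"])
        page = tif.pages[0]
        try:
            xres = page.tags["XResolution"].value
            yres = page.tags["YResolution"].value
            dx = xres[1] / xres[0]
            dy = yres[1] / yres[0]
        except (KeyError, ZeroDivisionError):
            return None
        return VoxelSpacing(dz, dy, dx)
    return None


def read_volume(
    path: str | Path,
    dataset_key: str | None = None,
    spacing: VoxelSpacing | None = None,
) -> Volume:
    """Read a 3D volume from TIFF or HDF5.

    Integer data yields a :class:`LabelVolume`; floating-point data in
    [0, 1] yields a :class:`ProbabilityVolume`. ``spacing`` overrides any
    spacing recorded in the file; if neither is available the read fails.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffix = path.suffix.lower()
    if suffix in {".h5", ".hdf5", ".hdf"}:
        with h5py.File(path, "r") as f:
            key = dataset_key
            if key is None:
                dsets = [k for k in f.keys() if isinstance(f[k], h5py.Dataset)]
                if len(dsets) != 1:
                    raise KeyError(
                        f"{path}: dataset_key required, file holds {len(dsets)} datasets"
                    )
                key = dsets[0]
            if key not in f:
                raise KeyError(f"{path}: no dataset {key!r}")
            ds = f[key]
            voxels = ds[()]
            if spacing is None and "element_size_um" in ds.attrs:
                spacing = VoxelSpacing(*np.asarray(ds.attrs["element_size_um"], float))
    else:
        with tifffile.TiffFile(path) as tif:
            voxels = tif.asarray()
            if spacing is None:
                spacing = _tiff_spacing(tif)
    if spacing is None:
        raise ValueError(f"{path}: no voxel spacing in file and none supplied")
    return _wrap(np.asarray(voxels), spacing)


def write_volume(
    volume: Volume,
    path: str | Path,
    dataset_key: str | None = None,
) -> None:
    """Write a volume to TIFF or HDF5 so :func:`read_volume` round-trips it.

    Labels are stored as the narrowest unsigned integer that holds the
    maximum ID; probabilities as 32-bit floats.
    """
    path = Path(path)
    sp = volume.spacing
    if isinstance(volume, LabelVolume):
        data = volume.voxels.astype(_label_dtype(int(volume.voxels.max(initial=0))))
    else:
        data = volume.voxels.astype(np.float32, copy=False)

    suffix = path.suffix.lower()
    if suffix in {".h5", ".hdf5", ".hdf"}:
        key = dataset_key or "exported_data"
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(key, data=data, compression="gzip")
            ds.attrs["element_size_um"] = sp.as_array()
    else:
        desc = _TIFF_META_PREFIX + json.dumps(
            {"spacing_um_zyx": [sp.dz, sp.dy, sp.dx]}
        )
        # one grayscale page per z-slice, never an RGB interpretation
        tifffile.imwrite(path, data, photometric="minisblack", description=desc)


def write_table(
    rows: Iterable[Mapping[str, object]],
    path: str | Path,
    schema: Sequence[str],
) -> None:
    """Write records to CSV with the header exactly ``schema``.

    Rows are sorted by the first schema column for a stable on-disk order;
    a record missing any schema column is rejected.
    """
    schema = list(schema)
    records = []
    for row in rows:
        row = dict(row)
        missing = [c for c in schema if c not in row]
        if missing:
            raise ValueError(f"record missing columns {missing}: {row}")
        records.append({c: row[c] for c in schema})
    df = pd.DataFrame.from_records(records, columns=schema)
    if len(df):
        df = df.sort_values(schema[0], kind="stable")
    df.to_csv(path, index=False)
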