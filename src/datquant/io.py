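"""Reading and writing 3D count volumes and subject manifests.

SPECT scans are stored as NIfTI-1 volumes whose voxel values are photon
counts; subjects are listed in a CSV manifest with columns
``subject_id,stage,path``.  Stage labels follow the three-group clinical
scheme: ``healthy``, ``mild`` (Hoehn–Yahr 1–3) and ``severe``
(Hoehn–Yahr 4–5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

STAGES = ("healthy", "mild", "severe")

MANIFEST_COLUMNS = ("subject_id", "stage", "path")


@dataclass
class Volume:
    """A 3D grid of non-negative photon counts with physical voxel spacing.

    Axis 2 is the axial (slice) direction; ``spacing`` is (dx, dy, dz) in
    mm, dz being the single-slice thickness.
    """

    counts: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 3:
            raise ValueError(f"Volume must be 3D, got {self.counts.ndim}D")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("Volume counts must be finite")
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("Volume counts must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz


def read_volume(path: str | Path) -> Volume:
    """Load a 3D NIfTI count volume.

    Negative voxel values (possible after filtered reconstruction) are
    clamped to zero with a warning; counts are physically non-negative.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {img.shape}")
    data = np.asanyarray(img.dataobj).astype(np.float64)
    n_neg = int((data < 0).sum())
    if n_neg:
        warnings.warn(f"{path}: clamped {n_neg} negative voxel(s) to 0", stacklevel=2)
        data = np.clip(data, 0.0, None)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(counts=data, spacing=spacing)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI-1, int32 when counts are integral."""
    data = volume.counts
    if data.size and np.array_equal(data, np.rint(data)) and data.max() < 2**31:
        data = data.astype(np.int32)
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a subject manifest CSV (subject_id, stage, path).

    Returns an empty frame (with a warning) for an empty file; raises on
    unknown stage labels, naming the offenders.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty manifest", stacklevel=2)
        return pd.DataFrame(columns=list(MANIFEST_COLUMNS))
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    bad = sorted(set(df["stage"]) - set(STAGES))
    if bad:
        raise ValueError(
            f"{path}: unknown stage label(s) {bad}; expected one of {list(STAGES)}"
        )
    return df[list(MANIFEST_COLUMNS)].copy()


def write_manifest(records: pd.DataFrame, path: str | Path) -> None:
    records[list(MANIFEST_COLUMNS)].to_csv(path, index=False)
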