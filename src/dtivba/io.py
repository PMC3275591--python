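"""Reading and writing the standard on-disk formats of the pipeline.

Volumes are NIfTI-1 (``.nii``/``.nii.gz``), gradient tables are FSL-dialect
``.bval``/``.bvec`` text files, and the subject manifest is a CSV with one
row per animal (id, group, birth weight, thirteen neurobehavioral items).
Gradient directions are interpreted in image coordinates; no scanner-frame
reorientation is applied.  Voxel indices are 0-based everywhere, and every
mask or label map consumed alongside a DWI must share its grid shape and
voxel size — a mismatch is an error, never a silent resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .gradients import GradientScheme, read_bval_bvec, write_bval_bvec

__all__ = [
    "DWIVolume",
    "SubjectRecord",
    "SCORE_REGISTRY",
    "GROUP_LABELS",
    "read_dwi",
    "write_dwi",
    "read_volume",
    "write_volume",
    "read_manifest",
    "write_manifest",
]

GROUP_LABELS = ("control", "IUGR")

#: The neurobehavioral test battery: item name -> (kind, (low, high) or None).
#: ``score`` items are ordinal 0-3; ``count`` items are non-negative integers;
#: ``continuous`` items are non-negative reals (mm or seconds).
SCORE_REGISTRY: dict[str, tuple[str, tuple[float, float] | None]] = {
    "posture": ("score", (0, 3)),
    "righting_reflex": ("count", (0, 12)),
    "tone": ("score", (0, 3)),
    "locomotion": ("score", (0, 3)),
    "circular_motion": ("score", (0, 3)),
    "intensity": ("score", (0, 3)),
    "duration": ("score", (0, 3)),
    "lineal_movement": ("count", (0, 10)),
    "fore_hindpaw_distance": ("continuous", (0, np.inf)),
    "sucking_swallowing": ("score", (0, 3)),
    "head_turn": ("score", (0, 3)),
    "smelling_test": ("score", (0, 3)),
    "smelling_test_time": ("continuous", (0, np.inf)),
}


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted image with its gradient scheme.

    ``data`` is indexed ``(x, y, z, measurement)``; the measurement axis must
    match the scheme length.  ``affine`` is the NIfTI voxel-to-world matrix
    (defaults to a diagonal scaling by the voxel size).
    """

    data: np.ndarray
    voxel_size: np.ndarray  # (3,) mm
    scheme: GradientScheme
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"DWI data must be 4D, got {self.data.ndim}D")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).ravel()
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be three positive lengths (mm)")
        if self.data.shape[3] != len(self.scheme):
            raise ValueError(
                f"image has {self.data.shape[3]} volumes but the gradient "
                f"table describes {len(self.scheme)} measurements"
            )
        if self.affine is None:
            self.affine = np.diag(np.append(self.voxel_size, 1.0))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class SubjectRecord:
    """Group label, birth weight and behavioral scores for one animal."""

    subject_id: str
    group: str
    birth_weight: float  # grams
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(
                f"unknown group label {self.group!r}; expected one of {GROUP_LABELS}"
            )
        unknown = set(self.scores) - set(SCORE_REGISTRY)
        if unknown:
            raise ValueError(f"unknown score names: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# volume I/O


def write_volume(array: np.ndarray, voxel_size, path, dtype=np.float32) -> None:
    """Write a 3D/4D array as NIfTI with a diagonal voxel-size affine."""
    voxel_size = np.asarray(voxel_size, dtype=float).ravel()
    affine = np.diag(np.append(voxel_size, 1.0))
    img = nib.Nifti1Image(np.asarray(array).astype(dtype), affine)
    img.header.set_zooms(tuple(voxel_size) + ((1.0,) if array.ndim == 4 else ()))
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns ``(array, voxel_size_mm)``."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return data, voxel_size


def write_dwi(dwi: DWIVolume, image_path, bval_path, bvec_path) -> None:
    write_volume(dwi.data, dwi.voxel_size, image_path, dtype=np.float64)
    write_bval_bvec(dwi.scheme, bval_path, bvec_path)


def read_dwi(image_path, bval_path, bvec_path) -> DWIVolume:
    """Read a 4D NIfTI plus FSL gradient tables into a validated DWIVolume.

    The measurement count is cross-checked between the image and the tables;
    non-unit b > 0 directions and all-zero b-values are errors.
    """
    for p in (image_path, bval_path, bvec_path):
        if not Path(p).exists():
            raise FileNotFoundError(str(p))
    img = nib.load(str(image_path))
    if img.ndim != 4:
        raise ValueError(f"expected a 4D image, got {img.ndim}D")
    scheme = read_bval_bvec(bval_path, bvec_path)
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.shape[3] != len(scheme):
        raise ValueError(
            f"image has {data.shape[3]} volumes but the gradient table "
            f"describes {len(scheme)} measurements"
        )
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return DWIVolume(data, voxel_size, scheme, affine=np.asarray(img.affine))


def check_same_grid(shape_a, shape_b, what: str = "volume") -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise ValueError(f"{what} grid {tuple(shape_b)} does not match {tuple(shape_a)}")


# ---------------------------------------------------------------------------
# manifest I/O

_MANIFEST_BASE_COLS = ["subject_id", "group", "birth_weight"]


def write_manifest(records: list[SubjectRecord], csv_path) -> None:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group, "birth_weight": r.birth_weight}
        for name in SCORE_REGISTRY:
            row[name] = r.scores.get(name, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(csv_path, index=False)


def read_manifest(csv_path) -> list[SubjectRecord]:
    """Read the subject manifest CSV.

    Empty score cells become NaN (missing), never zero; downstream statistics
    use pairwise deletion.  Duplicate subject ids and unknown group labels
    are errors.
    """
    df = pd.read_csv(csv_path)
    missing = [c for c in _MANIFEST_BASE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    ids = df["subject_id"].astype(str)
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate subject ids: {dups}")
    records = []
    score_cols = [c for c in df.columns if c in SCORE_REGISTRY]
    for _, row in df.iterrows():
        scores = {c: float(row[c]) for c in score_cols}
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                birth_weight=float(row["birth_weight"]),
                scores=scores,
            )
        )
    return records
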