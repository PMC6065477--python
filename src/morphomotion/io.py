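"""Readers and writers for the pipeline's file formats.

Three formats are handled: NIfTI-1 image volumes (via nibabel), the
six-column whitespace-delimited realignment-parameter text files produced
by rigid-body realignment (the SPM ``rp_*.txt`` dialect), and cohort
tables as CSV with a header row.

Conventions
-----------
Array indices are 0-based; voxel ``(i, j, k)`` spans the half-open cube
``[i, i+1) x [j, j+1) x [k, k+1)`` in voxel units.  Readers never reorder
rows or axes.  The rp-file angle unit is a *required* argument everywhere
rotations appear: rp files conventionally store radians, but preprocessed
releases sometimes re-export degrees, and a silent unit mistake scales
rotational displacement by a factor of ~57.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

PLANES = ("sagittal", "coronal", "axial")

#: NIfTI axis-code letter -> the anatomical plane sliced along that axis.
_AXCODE_TO_PLANE = {
    "R": "sagittal", "L": "sagittal",
    "A": "coronal", "P": "coronal",
    "S": "axial", "I": "axial",
}


class FormatError(ValueError):
    """Malformed file content (wrong shape, bad token, missing column)."""


@dataclass
class VoxelVolume:
    """A 3D scalar or binary image grid.

    Parameters
    ----------
    data
        3D array; intensities in arbitrary units, or {0, 1} occupancy.
    voxel_size_mm
        Physical edge lengths of one voxel, all positive.
    axis_labels
        Which anatomical plane each array axis slices through, e.g.
        ``("sagittal", "coronal", "axial")`` for a RAS-ordered array.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_labels: tuple[str, str, str] = PLANES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise FormatError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        if sorted(self.axis_labels) != sorted(PLANES):
            raise ValueError(
                f"axis_labels must be a permutation of {PLANES}, got {self.axis_labels}"
            )

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def require_binary(self) -> np.ndarray:
        """Return occupancy as bool, or raise TypeError for scalar data."""
        if not self.is_binary:
            raise TypeError("operation requires a binary {0,1} volume")
        return self.data.astype(bool)

    def plane_axis(self, plane: str) -> int:
        """Array axis along which slices of ``plane`` are stacked."""
        try:
            return self.axis_labels.index(plane)
        except ValueError:
            raise ValueError(
                f"unknown plane {plane!r}; expected one of {PLANES}"
            ) from None

    def with_data(self, data: np.ndarray) -> "VoxelVolume":
        return replace(self, data=data)


@dataclass
class RealignmentTrace:
    """Per-frame rigid-body realignment parameters.

    ``params`` is T x 6: columns 1-3 are translations in mm, columns 4-6
    rotations in ``angle_unit``.  ``tr_seconds`` is the repetition time.
    """

    params: np.ndarray
    angle_unit: str
    tr_seconds: float
    label: str = ""

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise FormatError(f"params must be Tx6, got shape {self.params.shape}")
        if self.params.shape[0] < 2:
            raise FormatError("trace needs at least 2 frames")
        if not np.isfinite(self.params).all():
            bad = np.argwhere(~np.isfinite(self.params))[0]
            raise ValueError(f"non-finite parameter at frame {bad[0]}, column {bad[1]}")
        if self.angle_unit not in ("radians", "degrees"):
            raise ValueError(f"angle_unit must be 'radians' or 'degrees', got {self.angle_unit!r}")
        if not self.tr_seconds > 0:
            raise ValueError(f"tr_seconds must be > 0, got {self.tr_seconds}")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


#: Cohort CSV column order; ``id`` and ``age_years`` are mandatory on read.
COHORT_COLUMNS = (
    "id", "age_years", "sex", "bmi_kg_m2",
    "motion_rest_mm_min", "motion_movie_mm_min",
    "thickness_mm", "fd_cortical", "gyrification",
    "aes_axial", "aes_coronal", "aes_sagittal",
)


@dataclass
class CohortRecord:
    """One subject's demographics, motion rates, AES triplet and morphology."""

    id: str
    age_years: float
    sex: str = ""
    bmi_kg_m2: float = math.nan  # NaN encodes "not measured", never 0
    motion_rest_mm_min: float = math.nan
    motion_movie_mm_min: float = math.nan
    thickness_mm: float = math.nan
    fd_cortical: float = math.nan
    gyrification: float = math.nan
    aes_axial: float = math.nan
    aes_coronal: float = math.nan
    aes_sagittal: float = math.nan

    @property
    def has_bmi(self) -> bool:
        return not math.isnan(self.bmi_kg_m2)


# ---------------------------------------------------------------------------
# NIfTI volumes


def _axis_labels_from_header(img: nib.Nifti1Image) -> tuple[str, str, str]:
    hdr = img.header
    sform, qform = int(hdr["sform_code"]), int(hdr["qform_code"])
    if sform == 0 and qform == 0:
        logger.warning(
            "NIfTI header carries no orientation codes; assuming axis order "
            "(sagittal, coronal, axial)"
        )
        return PLANES
    codes = nib.aff2axcodes(img.affine)
    labels = tuple(_AXCODE_TO_PLANE[c] for c in codes)
    if sorted(labels) != sorted(PLANES):
        raise FormatError(f"degenerate orientation codes {codes} in NIfTI header")
    return labels  # type: ignore[return-value]


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a 3D NIfTI-1 volume.

    Voxel sizes come from the header zooms and axis labels from the
    orientation codes; a header without codes falls back to
    (sagittal, coronal, axial) with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        shape = img.shape
        hdr_zooms = img.header.get_zooms()
    except Exception as exc:  # nibabel raises a zoo of header errors
        if isinstance(exc, nib.filebasedimages.ImageFileError) or "header" in str(exc).lower():
            raise FormatError(f"unreadable NIfTI header in {path}: {exc}") from exc
        raise
    if len(shape) == 4 and shape[3] == 1:
        img = nib.funcs.squeeze_image(img)
        shape = img.shape
    if len(shape) != 3:
        raise FormatError(f"{path} is {len(shape)}D; expected a 3D volume")
    data = np.asanyarray(img.dataobj)
    labels = _axis_labels_from_header(img)
    return VoxelVolume(data=data, voxel_size_mm=tuple(float(z) for z in hdr_zooms[:3]),
                       axis_labels=labels)


def write_volume(vol: VoxelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with a diagonal RAS affine from voxel sizes.

    The affine encodes the voxel sizes only; axis labels other than the
    default (sagittal, coronal, axial) are not representable without a
    rotation and raise.
    """
    if tuple(vol.axis_labels) != PLANES:
        raise ValueError("write_volume only supports (sagittal, coronal, axial) axis order")
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(Path(path)))


# ---------------------------------------------------------------------------
# Realignment traces


def read_realignment(path: str | Path, angle_unit: str, tr_seconds: float,
                     label: str = "") -> RealignmentTrace:
    """Read an SPM-style rp_*.txt file.

    Whitespace-delimited, exactly six numeric fields per non-empty row;
    rows are kept in file order, trailing blank lines ignored.
    ``angle_unit`` is required (see module docstring).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        if len(fields) != 6:
            raise FormatError(
                f"{path}: row {lineno} has {len(fields)} fields, expected 6"
            )
        try:
            rows.append([float(tok) for tok in fields])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric token on row {lineno}: {exc}") from exc
    return RealignmentTrace(params=np.array(rows, dtype=float),
                            angle_unit=angle_unit, tr_seconds=tr_seconds,
                            label=label or path.stem)


def write_realignment(trace: RealignmentTrace, path: str | Path) -> None:
    np.savetxt(str(Path(path)), trace.params, fmt="%.10e")


# ---------------------------------------------------------------------------
# Cohort tables


def read_cohort(path: str | Path) -> list[CohortRecord]:
    """Read a cohort CSV into records, preserving row order and missingness.

    ``id`` and ``age_years`` are mandatory columns; an empty BMI cell (or
    any other empty numeric cell) is kept as missing, never coerced to 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = {"id", "age_years"} - set(header)
        if missing:
            raise FormatError(f"{path}: missing mandatory columns {sorted(missing)}")
        records = []
        for row in reader:
            kwargs: dict[str, object] = {"id": row["id"], "sex": row.get("sex", "") or ""}
            for col in COHORT_COLUMNS:
                if col in ("id", "sex"):
                    continue
                cell = (row.get(col) or "").strip()
                kwargs[col] = float(cell) if cell else math.nan
            if math.isnan(kwargs["age_years"]):  # type: ignore[arg-type]
                raise FormatError(f"{path}: record {row['id']!r} has no age")
            records.append(CohortRecord(**kwargs))  # type: ignore[arg-type]
    return records


def write_cohort(records: Iterable[CohortRecord], path: str | Path) -> None:
    """Write records as CSV; missing values become empty cells."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for rec in records:
            row = []
            for col in COHORT_COLUMNS:
                val = getattr(rec, col)
                if isinstance(val, float) and math.isnan(val):
                    row.append("")
                elif isinstance(val, float):
                    row.append(repr(val))
                else:
                    row.append(str(val))
            writer.writerow(row)


def cohort_to_frame(records: Sequence[CohortRecord]):
    """Cohort records as a pandas DataFrame (one row per subject)."""
    import pandas as pd

    return pd.DataFrame([{col: getattr(r, col) for col in COHORT_COLUMNS} for r in records])
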