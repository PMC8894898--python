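"""Label-map and cohort-table input/output.

Reads whole-brain label volumes (NIfTI-1), extracts left/right hippocampus
binary masks under a configurable label dialect, and parses cohort tables
with per-scan demographics and paired left/right measurements.

All volumes are reoriented to a canonical RAS+ axis order on load
(right/anterior/superior ascending), so array axis 0 runs left-to-right,
axis 1 posterior-to-anterior, and axis 2 inferior-to-superior. Left and
right structures are identified by label ID only, never by image side.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LabelVolume",
    "BinaryMask",
    "ScanRecord",
    "LabelDialect",
    "GROUPS",
    "UNILATERAL_HS_GROUPS",
    "PATIENT_GROUPS",
    "register_dialect",
    "get_dialect",
    "read_label_volume",
    "write_label_volume",
    "extract_structure_masks",
    "read_cohort_table",
    "write_cohort_table",
]

#: Valid cohort group labels. ``HC`` are healthy controls; ``HS-*`` are
#: hippocampal-sclerosis patients by affected side; ``EPI-other`` are
#: epilepsy patients without reported HS ("all other epilepsies").
GROUPS = ("HC", "HS-left", "HS-right", "HS-bilateral", "EPI-other")
UNILATERAL_HS_GROUPS = ("HS-left", "HS-right")
PATIENT_GROUPS = ("HS-left", "HS-right", "HS-bilateral", "EPI-other")


@dataclass(frozen=True)
class LabelDialect:
    """Mapping from anatomical structure to integer label ID."""

    name: str
    left_hippocampus: int
    right_hippocampus: int


_DIALECTS: Dict[str, LabelDialect] = {}


def register_dialect(dialect: LabelDialect) -> None:
    """Register a label dialect under its name (overwrites silently)."""
    _DIALECTS[dialect.name] = dialect


def get_dialect(name: str) -> LabelDialect:
    try:
        return _DIALECTS[name]
    except KeyError:
        raise KeyError(
            f"unknown label dialect {name!r}; registered: {sorted(_DIALECTS)}"
        ) from None


# FreeSurfer aseg numbering: 17 = Left-Hippocampus, 53 = Right-Hippocampus.
register_dialect(LabelDialect("freesurfer-aseg", left_hippocampus=17,
                              right_hippocampus=53))

DEFAULT_DIALECT = "freesurfer-aseg"


@dataclass
class LabelVolume:
    """Canonicalized 3D integer label map with physical voxel spacing.

    Attributes
    ----------
    labels : (I, J, K) int ndarray
        Structure IDs, non-negative. Axes are RAS+ after canonicalization.
    spacing : (dx, dy, dz) in mm, strictly positive.
    affine : (4, 4) float ndarray
        Voxel-to-world affine of the canonicalized image (kept so volumes
        can be written back without losing placement).
    """

    labels: np.ndarray
    spacing: Tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")


@dataclass
class BinaryMask:
    """3D boolean mask of a single structure with voxel spacing in mm."""

    mask: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        """Total foreground volume = count x dx*dy*dz."""
        dx, dy, dz = self.spacing
        return self.n_foreground * dx * dy * dz


@dataclass
class ScanRecord:
    """One MRI scan's metadata plus paired left/right measurements.

    ``measures`` maps a metric name (e.g. ``"volume"``,
    ``"surface_to_volume_ratio"``) to its ``(lh, rh)`` value pair.
    """

    subject_id: str
    scan_id: str
    scan_date: _dt.date
    group: str
    age: float
    etiv: float
    measures: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not self.etiv > 0:
            raise ValueError(f"eTIV must be positive, got {self.etiv}")

    @property
    def is_patient(self) -> bool:
        return self.group != "HC"


def read_label_volume(path) -> LabelVolume:
    """Load a NIfTI label map and canonicalize it to RAS+ axis order.

    Raises on missing files, non-integer voxel data, and degenerate
    (non-positive) voxel spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label volume not found: {path}")
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        data = np.squeeze(data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.round(data)
        if not np.allclose(data, rounded, atol=1e-6, equal_nan=False):
            raise ValueError(f"{path} contains non-integer voxel values")
        data = rounded.astype(np.int32)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path} has degenerate voxel spacing {zooms}")
    return LabelVolume(labels=np.ascontiguousarray(data.astype(np.int32)),
                       spacing=zooms, affine=np.asarray(img.affine))


def write_label_volume(vol: LabelVolume, path) -> None:
    """Write a LabelVolume to NIfTI-1, preserving spacing and affine."""
    img = nib.Nifti1Image(vol.labels.astype(np.int16), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def extract_structure_masks(vol: LabelVolume,
                            dialect: str = DEFAULT_DIALECT
                            ) -> Tuple[BinaryMask, BinaryMask]:
    """Extract (left, right) hippocampus binary masks from a label map.

    Raises ``KeyError`` for an unregistered dialect and ``ValueError``
    naming the side when a structure label is absent from the volume.
    """
    d = get_dialect(dialect)
    left = vol.labels == d.left_hippocampus
    right = vol.labels == d.right_hippocampus
    if not left.any():
        raise ValueError(
            f"empty structure: no voxels with left-hippocampus label "
            f"{d.left_hippocampus} (dialect {d.name!r})")
    if not right.any():
        raise ValueError(
            f"empty structure: no voxels with right-hippocampus label "
            f"{d.right_hippocampus} (dialect {d.name!r})")
    return (BinaryMask(left, vol.spacing), BinaryMask(right, vol.spacing))


_REQUIRED_COLUMNS = ("subject_id", "scan_id", "scan_date", "group", "age", "etiv")


def read_cohort_table(path) -> List[ScanRecord]:
    """Parse a cohort CSV into ScanRecords.

    Required columns: ``subject_id, scan_id, scan_date, group, age, etiv``
    (dates ISO-8601). Any column pair ``<metric>_lh`` / ``<metric>_rh``
    becomes a paired measurement. Row numbers in error messages are
    1-based data rows (header excluded).
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "scan_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    metric_names = sorted(
        c[:-3] for c in df.columns
        if c.endswith("_lh") and (c[:-3] + "_rh") in df.columns
    )
    records: List[ScanRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        group = str(row["group"])
        if group not in GROUPS:
            raise ValueError(f"row {i}: unknown group label {group!r}")
        measures: Dict[str, Tuple[float, float]] = {}
        for m in metric_names:
            lh, rh = row[m + "_lh"], row[m + "_rh"]
            if pd.isna(lh) or pd.isna(rh):
                continue
            if m == "volume" and (lh <= 0 or rh <= 0):
                raise ValueError(f"row {i}: non-positive volume measure")
            measures[m] = (float(lh), float(rh))
        try:
            rec = ScanRecord(
                subject_id=str(row["subject_id"]),
                scan_id=str(row["scan_id"]),
                scan_date=_dt.date.fromisoformat(str(row["scan_date"])),
                group=group,
                age=float(row["age"]),
                etiv=float(row["etiv"]),
                measures=measures,
            )
        except ValueError as e:
            raise ValueError(f"row {i}: {e}") from None
        records.append(rec)
    return records


def write_cohort_table(records: List[ScanRecord], path) -> None:
    """Write ScanRecords to CSV (inverse of :func:`read_cohort_table`)."""
    metric_names = sorted({m for r in records for m in r.measures})
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "scan_id": r.scan_id,
            "scan_date": r.scan_date.isoformat(),
            "group": r.group,
            "age": r.age,
            "etiv": r.etiv,
        }
        for m in metric_names:
            if m in r.measures:
                row[m + "_lh"], row[m + "_rh"] = r.measures[m]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
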