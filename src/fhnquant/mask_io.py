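"""Label-volume I/O and validation.

Defines the coordinate and label conventions used throughout the package:

* labels: ``0`` background, ``1`` unaffected bone, ``2`` necrotic bone;
* world coordinates in millimetres, voxel-*center* convention;
* fixed anatomical axis order ``axis0 = left -> right``,
  ``axis1 = posterior -> anterior``, ``axis2 = inferior -> superior``
  (i.e. RAS); superior is ``+axis2``.

Files are NIfTI-1 (``.nii`` / ``.nii.gz``); volumes are kept at native
spacing — no resampling happens anywhere in this package.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VALID_LABELS",
    "AXIS_CONVENTION",
    "LabelVolume",
    "ArcoGrade",
    "Source",
    "CaseRecord",
    "Finding",
    "LabelValidationError",
    "read_label_volume",
    "write_label_volume",
    "validate_for_quantification",
    "read_case_record",
    "write_case_record",
    "read_manifest",
    "write_manifest",
]

VALID_LABELS = (0, 1, 2)

#: axis0 = L->R, axis1 = P->A, axis2 = I->S (superior is +axis2)
AXIS_CONVENTION = ("L->R", "P->A", "I->S")


class LabelValidationError(ValueError):
    """Raised when a volume violates the 0/1/2 label contract."""


class ArcoGrade(str, Enum):
    I = "I"
    II = "II"
    IIIA = "IIIA"
    IIIB = "IIIB"

    @property
    def is_advanced(self) -> bool:
        return self in (ArcoGrade.IIIA, ArcoGrade.IIIB)


class Source(str, Enum):
    MANUAL3D = "manual3d"
    MANUAL2D = "manual2d"
    AUTO2D = "auto2d"


@dataclass(frozen=True)
class CaseRecord:
    """Per-case metadata: identity, ARCO grade and segmentation source."""

    case_id: str
    arco_grade: ArcoGrade
    source: Source

    @property
    def group(self) -> str:
        """``"early"`` for ARCO I/II, ``"advanced"`` for IIIA/IIIB."""
        return "advanced" if self.arco_grade.is_advanced else "early"


@dataclass(frozen=True)
class Finding:
    """A validation finding; ``severity`` is ``error``/``warning``/``info``."""

    code: str
    message: str
    severity: str = "info"

    @property
    def blocking(self) -> bool:
        return self.severity == "error"


@dataclass
class LabelVolume:
    """A 3D segmentation label grid with world geometry.

    ``origin`` is the world position (mm) of the *center* of voxel
    ``(0, 0, 0)``; spacing components are strictly positive.
    """

    case_id: str
    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_convention: tuple[str, str, str] = AXIS_CONVENTION

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise LabelValidationError(
                f"labels must be 3D, got shape {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise LabelValidationError(
                f"labels must be integer-typed, got {self.labels.dtype}"
            )
        bad = np.setdiff1d(np.unique(self.labels), VALID_LABELS)
        if bad.size:
            raise LabelValidationError(
                f"invalid label values {sorted(int(b) for b in bad)}; "
                f"allowed: {set(VALID_LABELS)}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise LabelValidationError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (…, 3) voxel indices to world mm (voxel-center convention)."""
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map (…, 3) world mm to fractional voxel indices."""
        return (np.asarray(pts, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def label_count(self, label: int) -> int:
        return int(np.count_nonzero(self.labels == label))

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0


def _check_integer_data(data: np.ndarray) -> np.ndarray:
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6, rtol=0):
        bad = np.unique(data[~np.isclose(data, rounded, atol=1e-6, rtol=0)])
        raise LabelValidationError(
            f"non-integer voxel values present, e.g. {bad[:5].tolist()}"
        )
    return rounded.astype(np.int16)


def read_label_volume(path: str | Path, case_id: str | None = None) -> LabelVolume:
    """Read a NIfTI-1 label volume, reoriented to the fixed RAS convention.

    Voxel values outside ``{0, 1, 2}`` raise :class:`LabelValidationError`
    (never silently remapped); non-integer data likewise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise OSError(f"could not read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)  # reorient to RAS = our convention
    data = _check_integer_data(np.asanyarray(img.dataobj).astype(np.float64))
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise LabelValidationError(f"missing or invalid spacing in header: {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    vol = LabelVolume(
        case_id=case_id or path.name.split(".")[0],
        labels=data,
        spacing=tuple(float(z) for z in zooms),
        origin=origin,
    )
    return vol


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    """Write a NIfTI-1 file whose header spacing/origin equal ``vol``'s.

    ``read_label_volume(write_label_volume(v))`` is the identity on labels
    exactly and on spacing/origin to float32 header precision.
    """
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.labels.astype(np.uint8), affine)
    img.header.set_qform(affine, code=1)
    img.header.set_sform(affine, code=1)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise OSError(f"could not write NIfTI file {path}: {exc}") from exc


def validate_for_quantification(vol: LabelVolume) -> list[Finding]:
    """Check a volume for quantifiability; returns findings, never raises.

    An empty list means fully quantifiable with no caveats. ``error``
    findings block quantification; ``warning``/``info`` do not.
    """
    findings: list[Finding] = []
    n_fg = int(np.count_nonzero(vol.labels))
    if n_fg == 0:
        findings.append(Finding("no-foreground", "volume contains no foreground voxels", "error"))
        return findings
    if vol.label_count(2) == 0:
        findings.append(
            Finding("no-necrotic", "no necrotic voxels; necrosis metrics will report 0", "info")
        )
    fg = vol.foreground
    touching = sum(
        int(fg.take(0, axis=ax).any()) + int(fg.take(-1, axis=ax).any()) for ax in range(3)
    )
    if touching > 1:
        findings.append(
            Finding(
                "boundary-contact",
                f"foreground touches the grid boundary on {touching} faces; "
                "neck-cut detection may be ambiguous",
                "warning",
            )
        )
    return findings


def is_quantifiable(findings: Sequence[Finding]) -> bool:
    return not any(f.blocking for f in findings)


# -- per-case metadata sidecars and cohort manifests ----------------------

def write_case_record(record: CaseRecord, path: str | Path) -> None:
    payload = {
        "case_id": record.case_id,
        "arco_grade": record.arco_grade.value,
        "source": record.source.value,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_case_record(path: str | Path) -> CaseRecord:
    payload = json.loads(Path(path).read_text())
    return CaseRecord(
        case_id=payload["case_id"],
        arco_grade=ArcoGrade(payload["arco_grade"]),
        source=Source(payload["source"]),
    )


MANIFEST_COLUMNS = ("case_id", "arco_grade", "source", "path")


def write_manifest(rows: Sequence[tuple[CaseRecord, str | Path]], path: str | Path) -> None:
    """Write a cohort manifest CSV with columns case_id, arco_grade, source, path."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for record, vol_path in rows:
            writer.writerow(
                [record.case_id, record.arco_grade.value, record.source.value, str(vol_path)]
            )


def read_manifest(path: str | Path) -> list[tuple[CaseRecord, Path]]:
    out: list[tuple[CaseRecord, Path]] = []
    base = Path(path).parent
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            record = CaseRecord(
                case_id=row["case_id"],
                arco_grade=ArcoGrade(row["arco_grade"]),
                source=Source(row["source"]),
            )
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            out.append((record, p))
    return out
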