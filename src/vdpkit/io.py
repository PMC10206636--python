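"""Volume, mask, and cohort-table I/O.

All volumes are NIfTI-1; grids are indexed (x, y, z) with 0-based indices.
Physical orientation is carried through (the affine is kept as metadata) but
never used by any algorithm — every computation is mask-relative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tolerance (mm) when checking that two grids share a voxel spacing. Guards
#: against silent resampling mismatches without false alarms from float
#: serialization.
SPACING_TOL_MM = 1e-3

VALID_MODALITIES = ("SPECT", "MRI", "TRUTH")
VALID_GROUPS = ("none", "asthma", "COPD", "ILD")

#: Exact cohort CSV header, in order.
COHORT_COLUMNS = [
    "subject_id",
    "group",
    "vdp_t_spect",
    "vdp_k_spect",
    "vdp_t_mri",
    "vdp_k_mri",
    "age",
    "pack_years",
    "fev1_pct_pred",
    "fvc_pct_pred",
    "fev1_fvc_pct",
    "dlco_pct_pred",
]

_VDP_COLUMNS = ["vdp_t_spect", "vdp_k_spect", "vdp_t_mri", "vdp_k_mri"]


class GridMismatchError(ValueError):
    """Two grids that must match differ in shape or voxel spacing."""


@dataclass
class VolumeGrid:
    """A 3-D scalar intensity field with voxel spacing and a modality tag.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Signal intensities in arbitrary (signed) units; must be finite.
    voxel_spacing : tuple of 3 floats
        Voxel edge lengths in mm, all positive.
    modality : {"SPECT", "MRI", "TRUTH"}
    subject_id : str
    affine : ndarray (4, 4), optional
        NIfTI affine, carried through for round-trips only.
    """

    intensities: np.ndarray
    voxel_spacing: tuple[float, float, float]
    modality: str = "TRUTH"
    subject_id: str = ""
    affine: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"expected 3-D volume, got {self.intensities.ndim}-D array "
                f"of shape {self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume contains non-finite intensities")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be 3 positive reals, got {self.voxel_spacing}")
        if any(d < 1 for d in self.intensities.shape):
            raise ValueError(f"each dimension must be >= 1, got shape {self.intensities.shape}")
        if self.modality not in VALID_MODALITIES:
            raise ValueError(f"modality must be one of {VALID_MODALITIES}, got {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (spacing is in mm; 1 mL = 1000 mm^3)."""
        return float(np.prod(self.voxel_spacing)) / 1000.0


@dataclass
class CavityMask:
    """Binary thoracic-cavity mask aligned voxel-for-voxel to a VolumeGrid."""

    mask: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError(f"expected 3-D mask, got {self.mask.ndim}-D")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be 3 positive reals, got {self.voxel_spacing}")
        if not self.mask.any():
            raise ValueError("empty cavity mask: no voxel inside the thoracic cavity")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_spacing)) / 1000.0

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_volume_ml


@dataclass
class CohortRecord:
    """One study participant's group label, four VDPs, and clinical covariates."""

    subject_id: str
    group: str = "none"
    vdp_t_spect: Optional[float] = None
    vdp_k_spect: Optional[float] = None
    vdp_t_mri: Optional[float] = None
    vdp_k_mri: Optional[float] = None
    age: Optional[float] = None
    pack_years: Optional[float] = None
    fev1_pct_pred: Optional[float] = None
    fvc_pct_pred: Optional[float] = None
    fev1_fvc_pct: Optional[float] = None
    dlco_pct_pred: Optional[float] = None

    def __post_init__(self) -> None:
        self.group = normalize_group(self.group)
        for col in _VDP_COLUMNS:
            v = getattr(self, col)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                setattr(self, col, None)
                continue
            v = float(v)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{col} = {v} outside [0, 100] for subject {self.subject_id!r}")
            setattr(self, col, v)


def normalize_group(group: str) -> str:
    """Map a group label to its canonical casing; reject unknown labels."""
    g = str(group).strip()
    for valid in VALID_GROUPS:
        if g.lower() == valid.lower():
            if g != valid:
                logger.info("normalized group label %r -> %r", g, valid)
            return valid
    raise ValueError(f"unknown group label {group!r}; expected one of {VALID_GROUPS}")


def check_same_grid(volume: VolumeGrid, cavity: CavityMask) -> None:
    """Fail (before any computation) if a volume/mask pair disagree in grid."""
    if volume.shape != cavity.shape:
        raise GridMismatchError(
            f"grid shape mismatch: volume {volume.shape} vs mask {cavity.shape}"
        )
    dv = np.abs(np.array(volume.voxel_spacing) - np.array(cavity.voxel_spacing))
    if np.any(dv > SPACING_TOL_MM):
        raise GridMismatchError(
            f"voxel spacing mismatch beyond {SPACING_TOL_MM} mm: "
            f"volume {volume.voxel_spacing} vs mask {cavity.voxel_spacing}"
        )


def _nifti_spacing(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_volume(path, modality: str = "TRUTH", subject_id: str = "") -> VolumeGrid:
    """Read a 3-D NIfTI-1 volume into a :class:`VolumeGrid`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume in {path}, got {data.ndim}-D {data.shape}")
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume {path} contains non-finite voxels")
    return VolumeGrid(
        intensities=data,
        voxel_spacing=_nifti_spacing(img),
        modality=modality,
        subject_id=subject_id,
        affine=np.asarray(img.affine),
    )


def write_volume(volume: VolumeGrid, path) -> None:
    """Write a :class:`VolumeGrid` to NIfTI-1, preserving spacing and affine."""
    path = Path(path)
    affine = volume.affine
    if affine is None:
        affine = np.diag([*volume.voxel_spacing, 1.0])
    img = nib.Nifti1Image(volume.intensities.astype(np.float64), affine)
    img.header.set_zooms(volume.voxel_spacing)
    nib.save(img, str(path))


def read_mask(path, reference: VolumeGrid) -> CavityMask:
    """Read a NIfTI mask (nonzero = inside) and validate it against a reference grid."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3-D mask in {path}, got {data.ndim}-D {data.shape}")
    if data.shape != reference.shape:
        raise GridMismatchError(
            f"mask shape {data.shape} does not match reference volume shape {reference.shape}"
        )
    spacing = _nifti_spacing(img)
    dv = np.abs(np.array(spacing) - np.array(reference.voxel_spacing))
    if np.any(dv > SPACING_TOL_MM):
        raise GridMismatchError(
            f"mask spacing {spacing} differs from reference {reference.voxel_spacing} "
            f"beyond {SPACING_TOL_MM} mm"
        )
    mask = data != 0
    if not mask.any():
        raise ValueError(f"empty cavity mask in {path}")
    return CavityMask(mask=mask, voxel_spacing=reference.voxel_spacing)


def write_mask(mask: CavityMask, path, affine: Optional[np.ndarray] = None) -> None:
    path = Path(path)
    if affine is None:
        affine = np.diag([*mask.voxel_spacing, 1.0])
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), affine)
    img.header.set_zooms(mask.voxel_spacing)
    nib.save(img, str(path))


def write_cohort_table(records: Sequence[CohortRecord], path) -> None:
    """Write cohort records to CSV with the exact canonical header.

    Floats are serialized at >= 6 significant digits; missing values become
    empty cells. Validation (group labels, VDP range) happens in
    :class:`CohortRecord`, so every record written here is already valid.
    """
    rows = []
    for rec in records:
        if not isinstance(rec, CohortRecord):
            raise TypeError(f"expected CohortRecord, got {type(rec).__name__}")
        rows.append({col: getattr(rec, col) for col in COHORT_COLUMNS})
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.8g")


def load_cohort_table(path) -> list[CohortRecord]:
    """Load a cohort CSV back into records (inverse of :func:`write_cohort_table`)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort table not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table {path} missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in COHORT_COLUMNS:
            v = row[col]
            if col in ("subject_id", "group"):
                kwargs[col] = str(v)
            else:
                kwargs[col] = None if pd.isna(v) else float(v)
        records.append(CohortRecord(**kwargs))
    return records


def cohort_to_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Cohort records as a DataFrame with the canonical column order."""
    return pd.DataFrame(
        [{col: getattr(r, col) for col in COHORT_COLUMNS} for r in records],
        columns=COHORT_COLUMNS,
    )
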