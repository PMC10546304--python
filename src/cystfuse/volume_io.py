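"""Volume and cohort I/O.

Volumes are stored as NIfTI-1 (``.nii`` / ``.nii.gz``) with voxel spacing in
the header; a cohort is described by a CSV manifest with one row per
(patient, modality) and columns::

    patient_id,label,modality,path,center_x,center_y,center_z

Voxel arrays are indexed ``(x, y, z)``; axial slices are ``voxels[:, :, z]``.
Lesion-center coordinates are 0-based voxel indices in the reference modality
(T1post); the seven series of one patient are assumed co-registered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .constants import LABELS, MODALITIES, REFERENCE_MODALITY
from .errors import ValidationError

MANIFEST_COLUMNS = (
    "patient_id",
    "label",
    "modality",
    "path",
    "center_x",
    "center_y",
    "center_z",
)


@dataclass
class ModalityVolume:
    """One 3D scalar volume with spacing metadata and a modality tag."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(f"voxels must be 3D, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("volume contains non-finite voxel values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing_mm}")
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"unknown modality {self.modality!r}; expected one of {MODALITIES}"
            )

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclass
class PatientSeries:
    """One patient's seven co-registered modality volumes plus annotations.

    ``label`` is ``None`` in inference mode. ``lesion_center_vox`` is given in
    the reference modality's voxel grid.
    """

    patient_id: str
    volumes: Mapping[str, ModalityVolume]
    lesion_center_vox: tuple[int, int, int]
    label: Optional[str] = None

    def __post_init__(self) -> None:
        keys = tuple(self.volumes.keys())
        missing = [m for m in MODALITIES if m not in keys]
        if missing or len(keys) != len(MODALITIES):
            raise ValidationError(
                f"patient {self.patient_id!r}: expected exactly one volume per modality "
                f"{MODALITIES}; missing {missing}, got {sorted(keys)}"
            )
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS} or None, got {self.label!r}")
        c = tuple(int(v) for v in self.lesion_center_vox)
        ref = self.volumes[REFERENCE_MODALITY]
        if any(not (0 <= c[i] < ref.dims[i]) for i in range(3)):
            raise ValidationError(
                f"lesion center {c} outside reference volume of dims {ref.dims}"
            )
        self.lesion_center_vox = c

    @property
    def reference(self) -> ModalityVolume:
        return self.volumes[REFERENCE_MODALITY]


def write_volume(vol: ModalityVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with spacing on the affine diagonal."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, modality: str) -> ModalityVolume:
    """Read a NIfTI volume; spacing is taken from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    voxels = np.asarray(img.dataobj, dtype=np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ModalityVolume(voxels=voxels, spacing_mm=spacing, modality=modality)


def save_cohort(
    cohort: Sequence["PatientSeries"],
    out_dir: str | Path,
    truths: Optional[Sequence[object]] = None,
) -> Path:
    """Write a cohort to disk (one .nii.gz per modality) and return the manifest path.

    If ``truths`` (phantom ground-truth records with a ``to_json_dict``) is
    given, a ``<patient_id>.truth.json`` is written alongside each patient.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, series in enumerate(cohort):
        pdir = out_dir / series.patient_id
        for m in MODALITIES:
            p = write_volume(series.volumes[m], pdir / f"{m}.nii.gz")
            cx, cy, cz = series.lesion_center_vox
            rows.append(
                {
                    "patient_id": series.patient_id,
                    "label": series.label if series.label is not None else "",
                    "modality": m,
                    "path": str(p.relative_to(out_dir)),
                    "center_x": cx,
                    "center_y": cy,
                    "center_z": cz,
                }
            )
        if truths is not None:
            truth = truths[i]
            with open(pdir / f"{series.patient_id}.truth.json", "w") as fh:
                json.dump(truth.to_json_dict(), fh, indent=1)  # type: ignore[attr-defined]
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_csv: str | Path) -> list[PatientSeries]:
    """Load a cohort from a manifest CSV, validating the seven-modality invariant."""
    manifest_csv = Path(manifest_csv)
    if not manifest_csv.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_csv}")
    df = pd.read_csv(manifest_csv, dtype={"patient_id": str, "label": str, "modality": str})
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"manifest missing columns: {missing_cols}")
    root = manifest_csv.parent

    dup = df.duplicated(subset=["patient_id", "modality"])
    if dup.any():
        bad = sorted(df.loc[dup, "patient_id"].unique())
        raise ValidationError(f"duplicate (patient_id, modality) rows for patients: {bad}")

    cohort: list[PatientSeries] = []
    # Preserve first-appearance order of patients.
    for pid in df["patient_id"].drop_duplicates():
        sub = df[df["patient_id"] == pid]
        present = set(sub["modality"])
        absent = [m for m in MODALITIES if m not in present]
        if absent:
            raise ValidationError(f"patient {pid!r} is missing modalities: {absent}")
        extra = sorted(present - set(MODALITIES))
        if extra:
            raise ValidationError(f"patient {pid!r} has unknown modalities: {extra}")
        labels = set(sub["label"].fillna(""))
        if len(labels) != 1:
            raise ValidationError(f"patient {pid!r} has inconsistent labels: {sorted(labels)}")
        label = labels.pop()
        centers = sub[["center_x", "center_y", "center_z"]].drop_duplicates()
        if len(centers) != 1:
            raise ValidationError(f"patient {pid!r} has inconsistent lesion centers")
        volumes = {}
        for _, row in sub.iterrows():
            p = Path(row["path"])
            if not p.is_absolute():
                p = root / p
            volumes[row["modality"]] = read_volume(p, row["modality"])
        cohort.append(
            PatientSeries(
                patient_id=pid,
                volumes=volumes,
                lesion_center_vox=tuple(int(v) for v in centers.iloc[0]),
                label=label if label in LABELS else None,
            )
        )
    return cohort
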