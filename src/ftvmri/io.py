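"""Cohort directory layout and NIfTI + sidecar JSON round-tripping.

Layout, one directory per patient::

    cohort_dir/
      cohort.csv               # patient_id, label (pCR / non_pCR)
      P000/
        BL.nii.gz  BL_mask.nii.gz  BL.json
        C2.nii.gz  C2_mask.nii.gz  C2.json
        C4.nii.gz  C4_mask.nii.gz  C4.json

NIfTI has no standard field for DCE phase timing, so each study carries a
sidecar JSON with ``phase_times_s`` and ``spacing_mm``.  Image data are
stored (col, row, slice, phase) per NIfTI convention and transposed to the
in-memory (phase, slice, row, col) order on load.  Gzip members are
written with a zeroed mtime so identical cohorts serialize byte-identically.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DCEStudy, MaskSource, Timepoint, TumorMask
from .synthetic import SyntheticCohort

__all__ = [
    "save_study",
    "load_study",
    "save_mask",
    "load_mask",
    "write_cohort",
    "load_cohort_table",
    "iter_cohort",
]


def _write_nifti_deterministic(img: nib.Nifti1Image, path: Path) -> None:
    data = img.to_bytes()
    with open(path, "wb") as f:
        with gzip.GzipFile(fileobj=f, mode="wb", mtime=0) as gz:
            gz.write(data)


def _affine(spacing_mm) -> np.ndarray:
    r, c, s = spacing_mm
    return np.diag([c, r, s, 1.0])


def save_study(study: DCEStudy, directory, stem: str = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or study.timepoint.value
    # (phase, slice, row, col) -> (col, row, slice, phase)
    data = np.transpose(study.volumes, (3, 2, 1, 0)).astype(np.float32)
    img = nib.Nifti1Image(data, _affine(study.voxel_spacing_mm))
    _write_nifti_deterministic(img, directory / f"{stem}.nii.gz")
    sidecar = {
        "patient_id": study.patient_id,
        "timepoint": study.timepoint.value,
        "phase_times_s": list(study.phase_times_s),
        "spacing_mm": list(study.voxel_spacing_mm),
    }
    with open(directory / f"{stem}.json", "w") as f:
        json.dump(sidecar, f, indent=1, sort_keys=True)
        f.write("\n")


def load_study(directory, timepoint) -> DCEStudy:
    directory = Path(directory)
    tp = Timepoint(timepoint)
    with open(directory / f"{tp.value}.json") as f:
        sidecar = json.load(f)
    img = nib.load(directory / f"{tp.value}.nii.gz")
    data = np.transpose(np.asarray(img.dataobj, dtype=float), (3, 2, 1, 0))
    return DCEStudy(
        patient_id=sidecar["patient_id"],
        timepoint=tp,
        volumes=data,
        phase_times_s=tuple(sidecar["phase_times_s"]),
        voxel_spacing_mm=tuple(sidecar["spacing_mm"]),
    )


def save_mask(mask: TumorMask, spacing_mm, directory, stem: str) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = np.transpose(mask.mask, (2, 1, 0)).astype(np.uint8)
    img = nib.Nifti1Image(data, _affine(spacing_mm))
    _write_nifti_deterministic(img, directory / f"{stem}_mask.nii.gz")


def load_mask(directory, timepoint, source=MaskSource.MANUAL) -> TumorMask:
    directory = Path(directory)
    tp = Timepoint(timepoint)
    img = nib.load(directory / f"{tp.value}_mask.nii.gz")
    data = np.transpose(np.asarray(img.dataobj), (2, 1, 0)) > 0
    return TumorMask(mask=data, source=source)


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Serialize a synthetic cohort to the analysis directory layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for patient, label in zip(cohort.patients, cohort.labels):
        pdir = out_dir / patient.patient_id
        for tp, study in patient.studies.items():
            save_study(study, pdir)
            save_mask(patient.masks[tp], study.voxel_spacing_mm, pdir, tp.value)
        rows.append({
            "patient_id": patient.patient_id,
            "label": "pCR" if label == 1 else "non_pCR",
        })
    pd.DataFrame(rows).to_csv(out_dir / "cohort.csv", index=False)
    return out_dir


def load_cohort_table(cohort_dir) -> pd.DataFrame:
    table = pd.read_csv(Path(cohort_dir) / "cohort.csv")
    required = {"patient_id", "label"}
    if not required.issubset(table.columns):
        raise ValueError(f"cohort.csv must have columns {sorted(required)}")
    bad = set(table["label"]) - {"pCR", "non_pCR"}
    if bad:
        raise ValueError(f"unknown labels in cohort.csv: {sorted(bad)}")
    return table


def iter_cohort(cohort_dir, mask_source=MaskSource.MANUAL):
    """Yield (patient_id, label, {tp: study}, {tp: mask}) per patient.

    Patients missing any of the three timepoints are yielded with the
    available subset; the caller decides whether to exclude them.
    """
    cohort_dir = Path(cohort_dir)
    table = load_cohort_table(cohort_dir)
    for _, row in table.iterrows():
        pdir = cohort_dir / str(row["patient_id"])
        studies, masks = {}, {}
        for tp in Timepoint:
            if (pdir / f"{tp.value}.nii.gz").exists():
                studies[tp] = load_study(pdir, tp)
                masks[tp] = load_mask(pdir, tp, source=mask_source)
        yield str(row["patient_id"]), str(row["label"]), studies, masks
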