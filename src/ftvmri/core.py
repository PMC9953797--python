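"""Core DCE-MRI containers and voxel-wise enhancement mapping.

A dynamic contrast-enhanced (DCE) study is a stack of 3D volumes acquired
before and after contrast injection.  Downstream volumetrics need three
things from it: a subtraction image (post minus pre), a percentage
enhancement (PE) map quantifying wash-in, and a signal enhancement ratio
(SER) map quantifying wash-out:

    PE  = (S_early - S_pre) / S_pre * 100
    SER = (S_early - S_pre) / (S_late - S_pre)

Both are intensity-scale invariant, so no B1/T1 correction is attempted and
intensities are treated as arbitrary-unit magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Timepoint",
    "MaskSource",
    "DCEStudy",
    "TumorMask",
    "EnhancementMaps",
    "PhaseSelectionError",
    "SER_CAP",
    "select_phase",
    "subtraction_image",
    "compute_pe_map",
    "compute_ser_map",
    "compute_enhancement_maps",
]

#: SER assigned to voxels that enhance early but return exactly to baseline
#: by the late phase (denominator ~ 0).  Such complete wash-out is the
#: fastest kinetics SER is meant to flag, so the value sits far above the
#: threshold-grid maximum of 2.0 and the voxel passes every SER threshold.
SER_CAP = 10.0

#: Relative tolerance defining a "zero" late-enhancement denominator,
#: as a fraction of the study's intensity dynamic range.
SER_DENOM_REL_EPS = 1e-6


class Timepoint(str, Enum):
    """Imaging timepoint within the neoadjuvant course."""

    BL = "BL"
    C2 = "C2"
    C4 = "C4"


class MaskSource(str, Enum):
    MANUAL = "manual"
    REFINED = "refined"
    SYNTHETIC = "synthetic"


class PhaseSelectionError(ValueError):
    """No acquired phase lies close enough to the requested nominal time."""


@dataclass(frozen=True)
class DCEStudy:
    """One patient-timepoint 4D DCE series.

    Parameters
    ----------
    patient_id : str
        Opaque identifier.
    timepoint : Timepoint
        BL (baseline), C2 or C4 (after 2 / 4 cycles of therapy).
    volumes : ndarray, shape (n_phases, n_slices, n_rows, n_cols)
        Signal intensity, arbitrary units.
    phase_times_s : tuple of float
        Acquisition time of each phase in seconds relative to the start of
        contrast injection; pre-contrast phases have times <= 0.
    voxel_spacing_mm : tuple of float
        (row, column, slice-increment) spacing in mm.  The slice increment
        is the per-slice table advance, which for overlapping-slice
        protocols is smaller than the slice thickness.
    """

    patient_id: str
    timepoint: Timepoint
    volumes: np.ndarray
    phase_times_s: tuple
    voxel_spacing_mm: tuple

    def __post_init__(self):
        vols = np.asarray(self.volumes, dtype=float)
        if vols.ndim != 4:
            raise ValueError("volumes must be 4D (phase, slice, row, col)")
        times = np.asarray(self.phase_times_s, dtype=float)
        if times.shape != (vols.shape[0],):
            raise ValueError("one phase time per phase required")
        if not np.all(np.diff(times) > 0):
            raise ValueError("phase_times_s must be strictly increasing")
        if not np.any(times <= 0):
            raise ValueError("at least one pre-contrast phase (time <= 0) required")
        spacing = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("voxel_spacing_mm must be three positive values")
        object.__setattr__(self, "volumes", vols)
        object.__setattr__(self, "phase_times_s", tuple(float(t) for t in times))
        object.__setattr__(self, "voxel_spacing_mm", spacing)
        object.__setattr__(
            self, "timepoint", Timepoint(self.timepoint)
        )

    @property
    def n_phases(self) -> int:
        return self.volumes.shape[0]

    @property
    def spatial_shape(self) -> tuple:
        return self.volumes.shape[1:]

    @property
    def pre_contrast_index(self) -> int:
        """Index of the last phase acquired at or before injection."""
        times = np.asarray(self.phase_times_s)
        return int(np.nonzero(times <= 0)[0][-1])

    @property
    def dynamic_range(self) -> float:
        return float(self.volumes.max() - self.volumes.min())


@dataclass(frozen=True)
class TumorMask:
    """Binary tumor segmentation on the spatial grid of one study."""

    mask: np.ndarray
    source: MaskSource = MaskSource.MANUAL

    def __post_init__(self):
        m = np.asarray(self.mask)
        if m.ndim != 3:
            raise ValueError("mask must be 3D")
        object.__setattr__(self, "mask", m.astype(bool))
        object.__setattr__(self, "source", MaskSource(self.source))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class EnhancementMaps:
    """Voxel-wise PE (percent) and SER (dimensionless) with validity flags.

    ``valid`` is False wherever either map is undefined: non-positive
    pre-contrast signal (PE and SER undefined) or a voxel that does not
    enhance early (SER undefined).  Invalid voxels are never counted by any
    downstream volumetric.
    """

    pe: np.ndarray
    ser: np.ndarray
    valid: np.ndarray
    early_phase_label: float  # nominal minutes (1 or 2.5)

    def __post_init__(self):
        pe = np.asarray(self.pe, dtype=float)
        ser = np.asarray(self.ser, dtype=float)
        valid = np.asarray(self.valid, dtype=bool)
        if not (pe.shape == ser.shape == valid.shape) or pe.ndim != 3:
            raise ValueError("pe, ser, valid must share one 3D shape")
        object.__setattr__(self, "pe", pe)
        object.__setattr__(self, "ser", ser)
        object.__setattr__(self, "valid", valid)


def select_phase(study: DCEStudy, nominal_time_s: float) -> int:
    """Pick the acquired phase closest to a nominal post-injection time.

    Acquisition grids rarely land exactly on the protocol's nominal times
    (temporal resolution of a fast DCE series is on the order of 10 s), so
    the nearest acquired phase is used.  A request at or before injection
    (``nominal_time_s <= 0``) returns the last pre-contrast phase.

    Raises
    ------
    PhaseSelectionError
        If no phase lies within half the maximum inter-phase gap of the
        nominal time.
    """
    times = np.asarray(study.phase_times_s)
    if nominal_time_s <= 0:
        return study.pre_contrast_index
    diffs = np.abs(times - nominal_time_s)
    idx = int(np.argmin(diffs))
    tol = 0.5 * float(np.max(np.diff(times))) if len(times) > 1 else 0.0
    if diffs[idx] > tol:
        raise PhaseSelectionError(
            f"study {study.patient_id}/{study.timepoint.value}: no phase within "
            f"{tol:.1f} s of nominal time {nominal_time_s:.1f} s "
            f"(acquired at {tuple(times)})"
        )
    return idx


def subtraction_image(study: DCEStudy, phase: int) -> np.ndarray:
    """Post-contrast phase minus the pre-contrast phase, voxelwise."""
    if study.phase_times_s[phase] <= 0:
        raise ValueError(f"phase {phase} is pre-contrast; subtraction undefined")
    pre = study.volumes[study.pre_contrast_index]
    return study.volumes[phase] - pre


def compute_pe_map(study: DCEStudy, early_phase: int):
    """Percentage-enhancement map.

    PE = (S_early - S_pre) / S_pre * 100 where S_pre > 0.  Voxels with
    non-positive pre-contrast signal are flagged invalid rather than raised:
    they occur routinely in background air.

    Returns
    -------
    pe : ndarray
        Percent units; 0 where invalid.
    valid : ndarray of bool
    """
    if study.phase_times_s[early_phase] <= 0:
        raise ValueError("early phase must be post-contrast")
    pre = study.volumes[study.pre_contrast_index]
    early = study.volumes[early_phase]
    valid = pre > 0
    pe = np.zeros_like(pre)
    np.divide(early - pre, pre, out=pe, where=valid)
    pe *= 100.0
    return pe, valid


def compute_ser_map(study: DCEStudy, early_phase: int, late_phase: int):
    """Signal-enhancement-ratio map.

    SER = (S_early - S_pre) / (S_late - S_pre).  Three regimes per voxel:

    * normal: early enhancement and a non-degenerate late denominator;
    * complete wash-out: early enhancement but the late signal has returned
      to baseline within ``SER_DENOM_REL_EPS`` of the dynamic range -- SER
      is capped at :data:`SER_CAP` and remains valid;
    * non-enhancing (S_early <= S_pre): SER undefined, flagged invalid.
    """
    if study.phase_times_s[early_phase] <= 0 or study.phase_times_s[late_phase] <= 0:
        raise ValueError("early and late phases must be post-contrast")
    if study.phase_times_s[late_phase] <= study.phase_times_s[early_phase]:
        raise ValueError("late phase must be acquired after the early phase")
    pre = study.volumes[study.pre_contrast_index]
    early = study.volumes[early_phase]
    late = study.volumes[late_phase]

    eps = SER_DENOM_REL_EPS * study.dynamic_range
    num = early - pre
    den = late - pre
    enhancing = num > 0
    degenerate = enhancing & (den <= eps)
    valid = enhancing & (pre > 0)

    ser = np.zeros_like(pre)
    ok = enhancing & ~degenerate
    np.divide(num, den, out=ser, where=ok)
    ser[degenerate] = SER_CAP
    return ser, valid


def compute_enhancement_maps(
    study: DCEStudy,
    early_phase: int,
    late_phase: int,
    early_phase_label: float,
) -> EnhancementMaps:
    """PE and SER maps with the combined validity flag."""
    pe, pe_valid = compute_pe_map(study, early_phase)
    ser, ser_valid = compute_ser_map(study, early_phase, late_phase)
    return EnhancementMaps(
        pe=pe,
        ser=ser,
        valid=pe_valid & ser_valid,
        early_phase_label=early_phase_label,
    )
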