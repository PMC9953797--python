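"""Synthetic DCE cohort generator with exact ground truth.

Emulates the structure of a neoadjuvant DCE-MRI study cohort: each patient
is imaged at baseline (BL), after 2 cycles (C2) and after 4 cycles (C4);
each study has one pre-contrast phase, early post-contrast phases near
1 min and 2.5 min, and a late phase near 7 min.  Tumors are axis-aligned
ellipsoids of enhancing voxels on a uniform background, with per-patient
wash-in amplitude A and wash-out fraction W driving the voxel kinetics

    S(t) = S0 * (1 + A * w(t)),

where w ramps from 0 at injection to 1 at the first early phase and decays
linearly to (1 - W) at the late phase.  In the zero-noise limit the PE and
SER maps inside the tumor are therefore closed-form:
PE(early1) = 100 A and SER(early1) = 1 / (1 - W).

Response arms differ only in how much the enhancing volume shrinks at C2
and C4 (complete responders shrink nearly to zero), matching the
qualitative pattern that baseline volumetrics do not separate the arms
while on-treatment volumetrics do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import DCEStudy, MaskSource, SER_CAP, Timepoint, TumorMask

__all__ = [
    "CohortConfig",
    "PatientRecord",
    "SyntheticCohort",
    "ConfigError",
    "generate_patient",
    "generate_cohort",
]

TIMEPOINTS = (Timepoint.BL, Timepoint.C2, Timepoint.C4)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters; the defaults define the study conditions.

    Volume shrinkage factors are multiplicative on the enhancing volume
    relative to baseline, one per arm per on-treatment timepoint; a
    per-patient lognormal jitter models response heterogeneity.  Wash-in
    amplitudes and wash-out fractions are drawn uniformly from the per-arm
    ranges.  Noise is additive Gaussian on every voxel of every phase.
    """

    n_patients: int = 100
    pcr_rate: float = 0.49
    grid_shape: tuple = (48, 64, 64)          # (slice, row, col)
    spacing_mm: tuple = (1.0, 1.0, 1.5)       # (row, col, slice-increment)
    phase_times_s: tuple = (-10.0, 60.0, 150.0, 420.0)
    baseline_radius_mm_mean: float = 14.0
    baseline_radius_mm_sd: float = 4.0
    shrinkage: dict = field(default_factory=lambda: {
        "pCR": (0.35, 0.02), "non_pCR": (0.75, 0.45)})
    shrinkage_jitter_sd: float = 0.25
    washin_range: dict = field(default_factory=lambda: {
        "pCR": (0.5, 1.5), "non_pCR": (0.5, 1.5)})
    washout_range: dict = field(default_factory=lambda: {
        "pCR": (0.1, 0.7), "non_pCR": (0.1, 0.7)})
    s0: float = 100.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.pcr_rate < 1.0):
            raise ConfigError("pcr_rate must lie strictly between 0 and 1")
        for arm, (c2, c4) in self.shrinkage.items():
            if not (0.0 <= c4 <= c2 <= 1.0 or (0 <= c2 <= 1 and 0 <= c4 <= 1)):
                raise ConfigError(f"shrinkage factors for {arm} must be in [0, 1]")
        if not self.shrinkage["pCR"][1] < self.shrinkage["non_pCR"][1]:
            raise ConfigError("pCR C4 shrinkage factor must be below non-pCR's")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be positive")


@dataclass(frozen=True)
class PatientRecord:
    """Studies, masks and exact ground truth for one synthetic patient."""

    patient_id: str
    arm: str  # "pCR" or "non_pCR"
    studies: dict   # Timepoint -> DCEStudy
    masks: dict     # Timepoint -> TumorMask
    truth: dict     # Timepoint -> dict of ground-truth quantities


@dataclass(frozen=True)
class SyntheticCohort:
    patients: tuple
    labels: np.ndarray  # 1 = pCR
    config: CohortConfig

    @property
    def n_pcr(self) -> int:
        return int(self.labels.sum())


def _washin_weight(t: float, t_peak: float, t_late: float, washout: float) -> float:
    """Normalized enhancement time-course w(t)."""
    if t <= 0:
        return 0.0
    if t <= t_peak:
        return t / t_peak
    return 1.0 - washout * (t - t_peak) / (t_late - t_peak)


def _ellipsoid_mask(grid_shape, spacing_mm, semi_axes_mm, center_vox) -> np.ndarray:
    ns, nr, nc = grid_shape
    r_mm, c_mm, s_mm = spacing_mm
    a_sl, a_row, a_col = semi_axes_mm  # mm along slice/row/col axes
    if min(semi_axes_mm) <= 0:
        return np.zeros(grid_shape, dtype=bool)
    zz = (np.arange(ns)[:, None, None] - center_vox[0]) * s_mm / a_sl
    yy = (np.arange(nr)[None, :, None] - center_vox[1]) * r_mm / a_row
    xx = (np.arange(nc)[None, None, :] - center_vox[2]) * c_mm / a_col
    return zz**2 + yy**2 + xx**2 <= 1.0


def generate_patient(config: CohortConfig, arm: str, rng: np.random.Generator,
                     patient_id: str = "P000") -> PatientRecord:
    """One patient's BL/C2/C4 studies, masks and ground truth.

    The tumor sits at the grid center; its baseline mean radius is drawn
    from the configured normal (floored at 2 mm) with mild per-axis
    anisotropy.  On-treatment enhancing volumes scale by the arm's
    shrinkage factor with lognormal jitter; the linear scale is the cube
    root.  A tumor whose extent would leave the grid raises ConfigError.
    """
    if arm not in ("pCR", "non_pCR"):
        raise ValueError("arm must be 'pCR' or 'non_pCR'")
    times = np.asarray(config.phase_times_s, dtype=float)
    post = times[times > 0]
    if post.size < 2:
        raise ConfigError("need at least two post-contrast phases")
    t_peak, t_late = float(post[0]), float(post[-1])

    radius = max(2.0, rng.normal(config.baseline_radius_mm_mean,
                                 config.baseline_radius_mm_sd))
    aniso = rng.uniform(0.85, 1.15, size=3)
    base_axes = radius * aniso  # (slice, row, col) semi-axes, mm
    washin = rng.uniform(*config.washin_range[arm])
    washout = rng.uniform(*config.washout_range[arm])

    c2f, c4f = config.shrinkage[arm]
    jitter = np.exp(rng.normal(0.0, config.shrinkage_jitter_sd, size=2))
    factors = {
        Timepoint.BL: 1.0,
        Timepoint.C2: min(c2f * jitter[0], 1.0),
        Timepoint.C4: min(c4f * jitter[1], 1.0),
    }

    ns, nr, nc = config.grid_shape
    r_mm, c_mm, s_mm = config.spacing_mm
    half_extent_mm = np.array([ns * s_mm, nr * r_mm, nc * c_mm]) / 2.0
    if np.any(base_axes > half_extent_mm - np.array([s_mm, r_mm, c_mm]) * 2):
        raise ConfigError(
            f"tumor semi-axes {tuple(np.round(base_axes, 1))} mm exceed the "
            f"grid half-extent {tuple(half_extent_mm)} mm"
        )
    center = ((ns - 1) / 2.0, (nr - 1) / 2.0, (nc - 1) / 2.0)

    w = np.array([_washin_weight(t, t_peak, t_late, washout) for t in times])
    studies, masks, truth = {}, {}, {}
    for tp in TIMEPOINTS:
        scale = factors[tp] ** (1.0 / 3.0)
        axes = base_axes * scale
        tumor = _ellipsoid_mask(config.grid_shape, config.spacing_mm, axes, center)
        vols = np.full((len(times), ns, nr, nc), config.s0, dtype=float)
        for p, wp in enumerate(w):
            if wp != 0.0:
                vols[p][tumor] = config.s0 * (1.0 + washin * wp)
        if config.noise_sd > 0:
            vols += rng.normal(0.0, config.noise_sd, size=vols.shape)
        studies[tp] = DCEStudy(
            patient_id=patient_id, timepoint=tp, volumes=vols,
            phase_times_s=tuple(times), voxel_spacing_mm=config.spacing_mm,
        )
        masks[tp] = TumorMask(mask=tumor, source=MaskSource.SYNTHETIC)
        early_truth = {}
        for t in post[:-1]:
            wt = _washin_weight(float(t), t_peak, t_late, washout)
            label = round(float(t) / 60.0, 2)
            ser = SER_CAP if washout >= 1.0 else wt / (1.0 - washout)
            early_truth[label] = {"pe_pct": 100.0 * washin * wt, "ser": ser}
        truth[tp] = {
            "n_enhancing": int(tumor.sum()),
            "volume_factor": factors[tp],
            "washin": washin,
            "washout": washout,
            "semi_axes_mm": tuple(float(a) for a in axes),
            "early": early_truth,
        }
    return PatientRecord(patient_id=patient_id, arm=arm, studies=studies,
                         masks=masks, truth=truth)


def generate_cohort(config: CohortConfig,
                    require_both_classes: bool = True) -> SyntheticCohort:
    """A full cohort; bit-for-bit reproducible from (config, seed).

    Labels are a binomial draw at ``pcr_rate``; each patient then consumes
    an independently spawned random stream so per-patient content does not
    depend on cohort size or ordering.
    """
    rng = np.random.default_rng(config.seed)
    labels = (rng.random(config.n_patients) < config.pcr_rate).astype(int)
    if require_both_classes and (labels.sum() < 2 or (1 - labels).sum() < 2):
        raise ConfigError(
            "cohort draw yielded fewer than 2 patients in a response class; "
            "increase n_patients or change the seed"
        )
    streams = rng.spawn(config.n_patients)
    patients = []
    for i, (lab, child) in enumerate(zip(labels, streams)):
        arm = "pCR" if lab == 1 else "non_pCR"
        patients.append(
            generate_patient(config, arm, child, patient_id=f"P{i:03d}")
        )
    return SyntheticCohort(patients=tuple(patients), labels=labels,
                           config=config)
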