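"""Cohort-level orchestration: from a cohort of DCE studies and masks to
response-prediction report tables and AUC threshold surfaces.

For every patient-timepoint the pipeline measures LD and ellipsoidal TV
(from the 1 min and 7 min subtraction images), ETV at the 1 min and
2.5 min early phases, and the full FTV matrix over the PE x SER threshold
grid.  Cohort analyses are run separately for BL, C2, C4 and the relative
changes %C2/BL and %C4/BL: the simple volumetrics get a direct ROC
analysis; FTV first passes through the threshold grid search, then the
values at the selected optimal pair are analyzed the same way.  The
discrimination convention throughout is positive class = residual disease
(non-pCR), larger values / smaller shrinkage = more positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ftv_io
from .core import (
    DCEStudy,
    MaskSource,
    Timepoint,
    TumorMask,
    compute_enhancement_maps,
    select_phase,
    subtraction_image,
)
from .stats import LabeledScores, auc_ci_delong, mann_whitney
from .synthetic import SyntheticCohort
from .threshold_search import FTVThresholdSelector, ThresholdGrid, build_grid
from .volumetry import (
    ellipsoid_tv,
    etv,
    ftv_grid,
    longest_dimension,
    mask_to_diameters,
    refine_mask_histogram,
    relative_change,
)

__all__ = [
    "AnalysisConfig",
    "CohortReport",
    "AnalysisError",
    "analyze_cohort",
    "compare_timepoints",
]

TIMEPOINT_ROWS = ("BL", "C2", "C4", "%C2/BL", "%C4/BL")
VOLUMETRIC_KINDS = ("ld_1min", "ld_7min", "tv_1min", "tv_7min",
                    "etv_1min", "etv_2p5min")
FTV_KINDS = ("ftv_1min", "ftv_2p5min")


class AnalysisError(RuntimeError):
    pass


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-side knobs (nominal phase times in seconds)."""

    early_nominal_s: tuple = (60.0, 150.0)
    late_nominal_s: float = 420.0
    use_refined_mask: bool = True
    grid: ThresholdGrid = None
    alpha: float = 0.05


@dataclass
class CohortReport:
    """Cohort analysis results.

    ``volumetrics`` has one row per (measurement kind, timepoint row) for
    LD/TV/ETV; ``ftv`` likewise for FTV, with the selected optimal
    thresholds; ``measurements`` is the per-patient-timepoint table the
    reports are built from; ``surfaces`` maps (ftv kind, timepoint row) to
    the fitted AUC surface.
    """

    volumetrics: pd.DataFrame
    ftv: pd.DataFrame
    measurements: pd.DataFrame
    surfaces: dict
    ftv_values: dict             # (ftv kind, row) -> per-patient Series
    labels: pd.Series            # patient_id -> 1 (pCR) / 0 (non-pCR)
    excluded: list
    log: list
    alpha: float = 0.05

    @property
    def n_analyzed(self) -> int:
        return int(self.labels.size)


def _maybe_refine(mask: TumorMask, sub_img, use_refined: bool) -> TumorMask:
    if not use_refined or mask.n_voxels == 0:
        return mask
    return refine_mask_histogram(mask, sub_img)


def _measure_patient_timepoint(study: DCEStudy, mask: TumorMask,
                               config: AnalysisConfig, grid: ThresholdGrid,
                               log: list):
    """All per-study measurements: scalars plus the two FTV grid matrices."""
    e1 = select_phase(study, config.early_nominal_s[0])
    e2 = select_phase(study, config.early_nominal_s[1])
    late = select_phase(study, config.late_nominal_s)
    spacing = study.voxel_spacing_mm

    sub_e1 = subtraction_image(study, e1)
    sub_e2 = subtraction_image(study, e2)
    sub_late = subtraction_image(study, late)
    mask_e1 = _maybe_refine(mask, sub_e1, config.use_refined_mask)
    mask_e2 = _maybe_refine(mask, sub_e2, config.use_refined_mask)
    mask_late = _maybe_refine(mask, sub_late, config.use_refined_mask)

    d1 = mask_to_diameters(mask_e1, spacing, phase_label=1.0)
    d7 = mask_to_diameters(mask_late, spacing, phase_label=7.0)
    maps_e1 = compute_enhancement_maps(study, e1, late, 1.0)
    maps_e2 = compute_enhancement_maps(study, e2, late, 2.5)

    scalars = {
        "ld_1min": longest_dimension(d1),
        "ld_7min": longest_dimension(d7),
        "tv_1min": ellipsoid_tv(d1),
        "tv_7min": ellipsoid_tv(d7),
        "etv_1min": etv(mask_e1, spacing),
        "etv_2p5min": etv(mask_e2, spacing),
    }
    grids = {
        "ftv_1min": ftv_grid(mask_e1, maps_e1, grid, spacing),
        "ftv_2p5min": ftv_grid(mask_e2, maps_e2, grid, spacing),
    }
    return scalars, grids


def _iter_source(source):
    """Yield (patient_id, label_str, studies, masks) from either a
    directory layout or an in-memory synthetic cohort."""
    if isinstance(source, SyntheticCohort):
        for patient, lab in zip(source.patients, source.labels):
            yield (patient.patient_id, "pCR" if lab == 1 else "non_pCR",
                   patient.studies, patient.masks)
    else:
        yield from ftv_io.iter_cohort(source)


def _group_stats(scores, y_pos):
    """AUC/CI/p, Mann-Whitney p, group mean+-SD and Youden cutoff."""
    ls = LabeledScores(scores, y_pos)
    roc = auc_ci_delong(ls, positive_high=True)
    pos, neg = ls.split()  # pos = non-pCR
    mw = mann_whitney(pos, neg)
    return {
        "auc": roc.auc, "ci_low": roc.ci_low, "ci_high": roc.ci_high,
        "p_auc": roc.p_value, "p_mannwhitney": mw.p_value,
        "mean_nonpcr": pos.mean(), "sd_nonpcr": pos.std(ddof=1) if pos.size > 1 else 0.0,
        "mean_pcr": neg.mean(), "sd_pcr": neg.std(ddof=1) if neg.size > 1 else 0.0,
        "best_cutoff": roc.best_cutoff,
        "n_nonpcr": int(pos.size), "n_pcr": int(neg.size),
    }


def analyze_cohort(source, config: AnalysisConfig = None,
                   out_dir=None) -> CohortReport:
    """Run the full response analysis over a cohort.

    Parameters
    ----------
    source : SyntheticCohort or path-like
        In-memory cohort or a cohort directory (see :mod:`ftvmri.io`).
    config : AnalysisConfig
    out_dir : path-like, optional
        If given, report tables, per-patient measurements, AUC surfaces
        and the run log are written there.

    Raises
    ------
    AnalysisError
        If after exclusions the cohort has fewer than two patients in
        either response class.
    """
    config = config or AnalysisConfig()
    grid = config.grid if config.grid is not None else build_grid()
    log: list = []
    excluded: list = []

    ids, labels = [], []
    scalar_rows = []
    grid_store = {k: {} for k in FTV_KINDS}  # kind -> {(pid, tp): matrix}
    for pid, label, studies, masks in _iter_source(source):
        missing = [tp.value for tp in Timepoint if tp not in studies]
        if missing:
            excluded.append({"patient_id": pid, "reason": f"missing {missing}"})
            log.append({"event": "excluded", "patient_id": pid,
                        "missing_timepoints": missing})
            continue
        ids.append(pid)
        labels.append(1 if label == "pCR" else 0)
        for tp in Timepoint:
            scalars, grids = _measure_patient_timepoint(
                studies[tp], masks[tp], config, grid, log)
            scalar_rows.append({"patient_id": pid, "timepoint": tp.value,
                                **scalars})
            for kind in FTV_KINDS:
                grid_store[kind][(pid, tp.value)] = grids[kind]

    labels = pd.Series(labels, index=pd.Index(ids, name="patient_id"),
                       name="pcr")
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise AnalysisError(
            f"class imbalance: cohort has {(labels == 1).sum()} pCR and "
            f"{(labels == 0).sum()} non-pCR patients after exclusions; "
            "at least 2 per class are required"
        )
    y_pos = (1 - labels.values)  # positive class = non-pCR

    measurements = pd.DataFrame(scalar_rows)
    # relative-change rows per measurement kind
    wide = measurements.set_index(["patient_id", "timepoint"])
    for later_tp, row_name in (("C2", "%C2/BL"), ("C4", "%C4/BL")):
        rows = []
        for pid in ids:
            entry = {"patient_id": pid, "timepoint": row_name}
            for kind in VOLUMETRIC_KINDS:
                entry[kind] = relative_change(
                    wide.loc[(pid, "BL"), kind], wide.loc[(pid, later_tp), kind])
            rows.append(entry)
        measurements = pd.concat([measurements, pd.DataFrame(rows)],
                                 ignore_index=True)

    # ---- LD / TV / ETV report -------------------------------------------
    vol_rows = []
    meas_idx = measurements.set_index(["patient_id", "timepoint"])
    for kind in VOLUMETRIC_KINDS:
        for row_name in TIMEPOINT_ROWS:
            vals = np.array([meas_idx.loc[(pid, row_name), kind] for pid in ids],
                            dtype=float)
            ok = ~np.isnan(vals)
            dropped = int((~ok).sum())
            if dropped:
                log.append({"event": "dropped_undefined_change",
                            "kind": kind, "row": row_name, "n": dropped})
            stats = _group_stats(vals[ok], y_pos[ok])
            vol_rows.append({"kind": kind, "row": row_name,
                             "n_dropped": dropped, **stats})
    volumetrics = pd.DataFrame(vol_rows)

    # ---- FTV report via threshold grid search ---------------------------
    surfaces = {}
    ftv_values = {}
    ftv_rows = []
    for kind in FTV_KINDS:
        stacks = {
            tp: np.stack([grid_store[kind][(pid, tp)] for pid in ids])
            for tp in ("BL", "C2", "C4")
        }
        value_sets = dict(stacks)
        for later_tp, row_name in (("C2", "%C2/BL"), ("C4", "%C4/BL")):
            bl, later = stacks["BL"], stacks[later_tp]
            with np.errstate(divide="ignore", invalid="ignore"):
                change = np.where(bl > 0, (later - bl) / bl * 100.0, np.nan)
            value_sets[row_name] = change
        for row_name in TIMEPOINT_ROWS:
            values = value_sets[row_name]
            selector = FTVThresholdSelector(
                positive_high=True, grid=grid,
                measurement_kind=f"{kind}:{row_name}",
            ).fit(values, y_pos)
            surfaces[(kind, row_name)] = selector.surface_
            if len(selector.tie_set_) > 1:
                log.append({"event": "auc_tie_set", "kind": kind,
                            "row": row_name, "ties": selector.tie_set_})
            vals = selector.transform(values)
            ftv_values[(kind, row_name)] = pd.Series(vals, index=ids)
            ok = ~np.isnan(vals)
            dropped = int((~ok).sum())
            if dropped:
                log.append({"event": "dropped_undefined_change",
                            "kind": kind, "row": row_name, "n": dropped})
            stats = _group_stats(vals[ok], y_pos[ok])
            ftv_rows.append({
                "kind": kind, "row": row_name,
                "optimal_pe": selector.optimal_pe_,
                "optimal_ser": selector.optimal_ser_,
                "n_ties": len(selector.tie_set_), "n_dropped": dropped,
                **stats,
            })
    ftv_report = pd.DataFrame(ftv_rows)

    # per-patient FTV values (and the thresholds they used) onto the
    # measurements table, one column pair per FTV kind
    for kind in FTV_KINDS:
        for row_name in TIMEPOINT_ROWS:
            sel = measurements["timepoint"] == row_name
            surf = surfaces[(kind, row_name)]
            series = ftv_values[(kind, row_name)]
            measurements.loc[sel, kind] = (
                measurements.loc[sel, "patient_id"].map(series).to_numpy()
            )
            measurements.loc[sel, f"{kind}_pe_thr"] = surf.optimal_pe
            measurements.loc[sel, f"{kind}_ser_thr"] = surf.optimal_ser

    report = CohortReport(
        volumetrics=volumetrics, ftv=ftv_report, measurements=measurements,
        surfaces=surfaces, ftv_values=ftv_values, labels=labels,
        excluded=excluded, log=log, alpha=config.alpha,
    )
    if out_dir is not None:
        _write_report(report, out_dir)
    return report


def compare_timepoints(report: CohortReport) -> pd.DataFrame:
    """Mann-Whitney comparison of each measurement's C2 vs C4 values.

    Tests whether the value distributions after 2 and after 4 cycles
    differ, per measurement kind; FTV kinds use the values at each
    timepoint's own optimal threshold pair.
    """
    meas = report.measurements.set_index(["patient_id", "timepoint"])
    ids = list(report.labels.index)
    rows = []
    for kind in VOLUMETRIC_KINDS:
        c2 = np.array([meas.loc[(pid, "C2"), kind] for pid in ids], dtype=float)
        c4 = np.array([meas.loc[(pid, "C4"), kind] for pid in ids], dtype=float)
        mw = mann_whitney(c2, c4)
        rows.append({"kind": kind, "p_value": mw.p_value,
                     "significant": mw.p_value < report.alpha})
    for kind in FTV_KINDS:
        c2 = report.ftv_values[(kind, "C2")].loc[ids].to_numpy()
        c4 = report.ftv_values[(kind, "C4")].loc[ids].to_numpy()
        mw = mann_whitney(c2, c4)
        rows.append({"kind": kind, "p_value": mw.p_value,
                     "significant": mw.p_value < report.alpha})
    return pd.DataFrame(rows)


def _write_report(report: CohortReport, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.volumetrics.to_csv(out_dir / "report_volumetrics.csv", index=False)
    report.ftv.to_csv(out_dir / "report_ftv.csv", index=False)
    report.measurements.to_csv(out_dir / "measurements.csv", index=False,
                               na_rep="")
    surf_dir = out_dir / "surfaces"
    surf_dir.mkdir(exist_ok=True)
    summaries = []
    n_pcr = int((report.labels == 1).sum())
    n_nonpcr = int((report.labels == 0).sum())
    for (kind, row_name), surf in report.surfaces.items():
        slug = f"{kind}_{row_name}".replace("%", "pct").replace("/", "_")
        surf.to_long_frame().to_csv(surf_dir / f"{slug}.csv", index=False)
        summaries.append({
            "kind": surf.measurement_kind,
            "optimal_pe": surf.optimal_pe,
            "optimal_ser": surf.optimal_ser,
            "max_auc": surf.max_auc,
            "n_pcr": n_pcr,
            "n_nonpcr": n_nonpcr,
        })
    with open(out_dir / "surfaces_summary.json", "w") as f:
        json.dump(summaries, f, indent=1, sort_keys=True)
        f.write("\n")
    with open(out_dir / "run_log.jsonl", "w") as f:
        for entry in report.log:
            f.write(json.dumps(entry, sort_keys=True, default=str) + "\n")
    with open(out_dir / "excluded.json", "w") as f:
        json.dump(report.excluded, f, indent=1, sort_keys=True)
        f.write("\n")
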