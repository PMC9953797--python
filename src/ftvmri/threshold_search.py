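"""PE x SER threshold grid search for the AUC-maximal FTV definition.

FTV depends on a pair of enhancement thresholds.  Rather than fixing the
pair a priori, the discriminating power (ROC AUC for pathologic complete
response vs residual disease) is evaluated at every pair of a predefined
grid -- PE from 0% to 220% in 5% steps (45 values) and SER from 0 to 2 in
0.05 steps (41 values), 1845 pairs -- and the pair with the maximum AUC is
selected.  Ties at the maximum are broken toward the smallest thresholds,
PE first then SER.

The search is exposed as the scikit-learn style estimator
:class:`FTVThresholdSelector`; :func:`auc_surface` and
:func:`select_optimal` are the underlying functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .stats import LabeledScores, auc_from_scores

__all__ = [
    "ThresholdGrid",
    "AUCSurface",
    "build_grid",
    "auc_surface",
    "select_optimal",
    "FTVThresholdSelector",
]

#: Floating-point slack treated as an exact AUC tie.
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class ThresholdGrid:
    """Predefined PE (percent) and SER threshold values.

    SER values are stored as integer hundredths so every grid value is
    exactly representable; ``ser_values`` converts on access.
    """

    pe_values: tuple
    ser_hundredths: tuple

    def __post_init__(self):
        pe = tuple(int(v) for v in self.pe_values)
        sh = tuple(int(v) for v in self.ser_hundredths)
        if any(b <= a for a, b in zip(pe, pe[1:])):
            raise ValueError("pe_values must be strictly increasing")
        if any(b <= a for a, b in zip(sh, sh[1:])):
            raise ValueError("ser values must be strictly increasing")
        object.__setattr__(self, "pe_values", pe)
        object.__setattr__(self, "ser_hundredths", sh)

    @property
    def ser_values(self) -> tuple:
        return tuple(h / 100.0 for h in self.ser_hundredths)

    @property
    def shape(self) -> tuple:
        return (len(self.pe_values), len(self.ser_hundredths))

    @property
    def n_pairs(self) -> int:
        return len(self.pe_values) * len(self.ser_hundredths)


def build_grid() -> ThresholdGrid:
    """The predefined grid: PE 0..220 step 5, SER 0..2.00 step 0.05."""
    return ThresholdGrid(
        pe_values=tuple(range(0, 221, 5)),
        ser_hundredths=tuple(range(0, 201, 5)),
    )


@dataclass(frozen=True)
class AUCSurface:
    """AUC over the threshold grid with the selected optimal pair."""

    auc: np.ndarray
    grid: ThresholdGrid
    measurement_kind: str
    optimal_pe: float
    optimal_ser: float
    max_auc: float
    tie_set: tuple = ()          # all (pe, ser) pairs at the max AUC
    n_dropped: np.ndarray = None  # per-cell count of patients dropped (NaN)

    def __post_init__(self):
        a = np.asarray(self.auc, dtype=float)
        if a.shape != self.grid.shape:
            raise ValueError("auc matrix must match grid shape")
        if np.nanmin(a) < 0 or np.nanmax(a) > 1:
            raise ValueError("AUC entries must lie in [0, 1]")
        object.__setattr__(self, "auc", a)

    def to_long_frame(self):
        """Long-format (pe, ser, auc) table, for CSV export / contour plots."""
        import pandas as pd

        pe, ser = np.meshgrid(self.grid.pe_values, self.grid.ser_values,
                              indexing="ij")
        return pd.DataFrame({
            "pe": pe.ravel(), "ser": ser.ravel(), "auc": self.auc.ravel(),
        })


def plot_auc_surface(surface: AUCSurface, ax=None):
    """Filled contour plot of an AUC surface with the optimum marked.

    Thin optional layer over matplotlib; the exported long-format CSV holds
    the same data for external plotting.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pe = np.asarray(surface.grid.pe_values)
    ser = np.asarray(surface.grid.ser_values)
    cs = ax.contourf(pe, ser, surface.auc.T, levels=20, cmap="viridis")
    ax.plot(surface.optimal_pe, surface.optimal_ser, "ko", mfc="none", ms=10)
    ax.set_xlabel("PE threshold (%)")
    ax.set_ylabel("SER threshold")
    ax.set_title(f"{surface.measurement_kind} (max AUC {surface.max_auc:.2f})")
    ax.figure.colorbar(cs, ax=ax, label="AUC")
    return ax


def _auc_matrix(values: np.ndarray, labels: np.ndarray,
                positive_high: bool) -> tuple:
    """Vectorized per-cell AUC over (n_patients, n_pe, n_ser) values.

    NaN entries (undefined relative changes) drop that patient from the
    affected cell only.  Cells left with fewer than 2 patients in either
    class, or where every remaining score ties, fall back to 0.5 by the
    tie convention.  Returns (auc matrix, per-cell dropped counts).
    """
    n, n_pe, n_ser = values.shape
    flat = values.reshape(n, -1)
    if not positive_high:
        flat = -flat
    pos = labels == 1
    nan_mask = np.isnan(flat)
    n_dropped = nan_mask.sum(axis=0)
    auc = np.empty(flat.shape[1])

    clean = ~nan_mask.any(axis=0)
    if clean.any():
        ranks = sps.rankdata(flat[:, clean], axis=0)
        m = pos.sum()
        k = n - m
        u = ranks[pos].sum(axis=0) - m * (m + 1) / 2
        auc[clean] = u / (m * k)
    for j in np.nonzero(~clean)[0]:
        ok = ~nan_mask[:, j]
        y = pos[ok]
        # fewer than 2 retained patients per class: the cell carries no
        # usable discrimination signal, so it takes the tie value and can
        # never win the argmax over informative cells
        if y.sum() < 2 or (~y).sum() < 2:
            auc[j] = 0.5
            continue
        s = flat[ok, j]
        ranks = sps.rankdata(s)
        m = y.sum()
        u = ranks[y].sum() - m * (m + 1) / 2
        auc[j] = u / (m * (len(s) - m))
    return auc.reshape(n_pe, n_ser), n_dropped.reshape(n_pe, n_ser)


def auc_surface(value_grids, labels, positive_high: bool = True,
                grid: ThresholdGrid = None,
                measurement_kind: str = "FTV") -> AUCSurface:
    """Cohort AUC at every threshold pair, with the optimal pair selected.

    Parameters
    ----------
    value_grids : array-like, shape (n_patients, n_pe, n_ser)
        Per-patient FTV (or FTV relative-change) matrices over the grid.
        NaN marks an undefined value (zero-baseline change); such patients
        are dropped pairwise from the affected cell, with counts recorded
        on the returned surface.
    labels : array-like of {0, 1}
        Outcome per patient, positive class = 1.
    positive_high : bool
        Whether larger values indicate the positive class.
    """
    grid = grid if grid is not None else build_grid()
    values = np.asarray(value_grids, dtype=float)
    labels = np.asarray(labels).astype(int)
    if values.ndim != 3 or values.shape[1:] != grid.shape:
        raise ValueError(
            f"value_grids must have shape (n_patients, {grid.shape[0]}, "
            f"{grid.shape[1]})"
        )
    if values.shape[0] != labels.shape[0]:
        raise ValueError("one label per patient required")
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present in the cohort")
    auc, n_dropped = _auc_matrix(values, labels, positive_high)
    pe_star, ser_star, max_auc, ties = _argmax_with_ties(auc, grid)
    return AUCSurface(
        auc=auc, grid=grid, measurement_kind=measurement_kind,
        optimal_pe=pe_star, optimal_ser=ser_star, max_auc=max_auc,
        tie_set=ties, n_dropped=n_dropped,
    )


def _argmax_with_ties(auc: np.ndarray, grid: ThresholdGrid):
    max_auc = float(np.max(auc))
    ti, tj = np.nonzero(auc >= max_auc - _TIE_TOL)
    ties = tuple(
        (float(grid.pe_values[i]), float(grid.ser_values[j]))
        for i, j in sorted(zip(ti.tolist(), tj.tolist()))
    )
    pe_star, ser_star = ties[0]  # lexicographic: PE first, then SER
    return pe_star, ser_star, max_auc, ties


def select_optimal(surface: AUCSurface):
    """(PE*, SER*, max AUC) from a populated surface.

    The maximizing pair; among ties at the maximum, the pair minimal in
    lexicographic (PE, SER) order, which coincides with the componentwise
    minimum whenever one exists.
    """
    pe, ser, mx, _ = _argmax_with_ties(surface.auc, surface.grid)
    return pe, ser, mx


class FTVThresholdSelector(BaseEstimator, TransformerMixin):
    """Select the AUC-maximal (PE, SER) threshold pair over a cohort.

    A scikit-learn style estimator.  ``fit`` takes per-patient FTV (or
    FTV-change) matrices over the threshold grid, evaluates the ROC AUC of
    the values at every grid pair against the binary outcome, and stores
    the maximizing pair; ``transform`` returns each patient's value at the
    selected pair.

    Parameters
    ----------
    positive_high : bool, default True
        Orientation of the score/outcome association (see
        :func:`ftvmri.stats.auc_from_scores`).
    grid : ThresholdGrid or None
        Threshold grid; the predefined 45 x 41 grid when None.
    measurement_kind : str
        Free-text tag carried onto the fitted surface.

    Attributes
    ----------
    surface_ : AUCSurface
        Full AUC matrix over the grid.
    optimal_pe_ : float
        Selected PE threshold, percent.
    optimal_ser_ : float
        Selected SER threshold, dimensionless.
    max_auc_ : float
        AUC at the selected pair.
    tie_set_ : tuple of (pe, ser)
        Every pair achieving the maximum AUC (logged, first one selected).
    """

    def __init__(self, positive_high: bool = True, grid: ThresholdGrid = None,
                 measurement_kind: str = "FTV"):
        self.positive_high = positive_high
        self.grid = grid
        self.measurement_kind = measurement_kind

    def fit(self, X, y):
        grid = self.grid if self.grid is not None else build_grid()
        surface = auc_surface(
            X, y, positive_high=self.positive_high, grid=grid,
            measurement_kind=self.measurement_kind,
        )
        self.grid_ = grid
        self.surface_ = surface
        self.optimal_pe_ = surface.optimal_pe
        self.optimal_ser_ = surface.optimal_ser
        self.max_auc_ = surface.max_auc
        self.tie_set_ = surface.tie_set
        self._pe_index_ = grid.pe_values.index(int(surface.optimal_pe))
        self._ser_index_ = list(grid.ser_values).index(surface.optimal_ser)
        return self

    def transform(self, X):
        """Per-patient values at the fitted optimal threshold pair."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "surface_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1:] != self.grid_.shape:
            raise ValueError("X must have shape (n_patients, n_pe, n_ser)")
        return X[:, self._pe_index_, self._ser_index_]

    def score(self, X, y):
        """AUC of the values at the fitted pair on (possibly new) data."""
        vals = self.transform(X)
        ok = ~np.isnan(vals)
        return auc_from_scores(
            LabeledScores(vals[ok], np.asarray(y)[ok]),
            positive_high=self.positive_high,
        )
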