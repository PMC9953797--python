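"""Statistical layer: Mann-Whitney, AUC with DeLong CI, Youden cutoff,
and the Freeman-Halton (r x c) generalization of Fisher's exact test."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from math import lgamma

import numpy as np
from scipy import stats as sps

__all__ = [
    "LabeledScores",
    "ContingencyTable",
    "ROCResult",
    "MannWhitneyResult",
    "DegenerateAUCWarning",
    "mann_whitney",
    "auc_from_scores",
    "auc_ci_delong",
    "youden_cutoff",
    "fisher_exact_rxc",
    "FisherCapacityError",
]

#: Combined sample size at or below which the Mann-Whitney p-value is
#: computed by exact enumeration (ties permitting).
MANN_WHITNEY_EXACT_MAX_N = 20


class DegenerateAUCWarning(UserWarning):
    """DeLong variance is zero (e.g. perfect separation); CI collapses."""


@dataclass(frozen=True)
class LabeledScores:
    """Per-patient scores with an aligned binary outcome (positive = 1)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        y = np.asarray(self.labels)
        if s.shape != y.shape or s.ndim != 1:
            raise ValueError("scores and labels must be aligned 1D arrays")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", y.astype(int))

    def split(self):
        pos = self.scores[self.labels == 1]
        neg = self.scores[self.labels == 0]
        return pos, neg


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("table must be at least 2x2")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    best_cutoff: float
    degenerate: bool = False


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p_value: float
    method: str


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    ``u`` counts pairs with a > b plus half the tied pairs.  The p-value is
    by exact enumeration when the combined sample is small
    (<= :data:`MANN_WHITNEY_EXACT_MAX_N`) and tie-free; otherwise by the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    exact = (a.size + b.size) <= MANN_WHITNEY_EXACT_MAX_N and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return MannWhitneyResult(u=float(res.statistic), p_value=float(res.pvalue),
                             method=method)


def auc_from_scores(ls: LabeledScores, positive_high: bool = True) -> float:
    """AUC as the probability a random positive outscores a random negative.

    Ties count one half; equivalently U / (n1 n0).  ``positive_high=False``
    flips the orientation (lower scores indicate the positive class), which
    is how a fixed clinical convention (report discrimination of the
    residual-disease class) is kept without taking max(AUC, 1 - AUC).
    """
    pos, neg = ls.split()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    sign = 1.0 if positive_high else -1.0
    u = sps.mannwhitneyu(sign * pos, sign * neg, alternative="two-sided",
                         method="asymptotic").statistic
    return float(u) / (pos.size * neg.size)


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """AUC and its DeLong structural components (one per subject)."""
    m, n = pos.size, neg.size
    all_scores = np.concatenate([pos, neg])
    tz = sps.rankdata(all_scores)          # midranks over the pooled sample
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (tz[:m] - tx) / n                # per-positive placement values
    v10 = 1.0 - (tz[m:] - ty) / m          # per-negative placement values
    return auc, v01, v10


def auc_ci_delong(ls: LabeledScores, positive_high: bool = True,
                  alpha: float = 0.05) -> ROCResult:
    """AUC with DeLong 95% CI and a normal test against AUC = 0.5.

    With zero estimated variance (perfect separation or all-tied scores
    within each class pattern) the CI collapses to the point estimate and a
    :class:`DegenerateAUCWarning` is emitted; the p-value is then floored
    at the smallest positive float so it stays in (0, 1].
    """
    pos, neg = ls.split()
    if pos.size < 2 or neg.size < 2:
        raise ValueError("DeLong CI needs at least 2 subjects per class")
    sign = 1.0 if positive_high else -1.0
    auc, v01, v10 = _delong_components(sign * pos, sign * neg)
    var = v01.var(ddof=1) / pos.size + v10.var(ddof=1) / neg.size
    degenerate = var <= 0
    if degenerate:
        warnings.warn(
            "zero DeLong variance; AUC confidence interval collapses to a point",
            DegenerateAUCWarning,
        )
        se = 0.0
    else:
        se = math.sqrt(var)
    z = sps.norm.ppf(1 - alpha / 2)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    if degenerate:
        p = 1.0 if auc == 0.5 else np.finfo(float).tiny
    else:
        zstat = (auc - 0.5) / se
        p = max(2 * sps.norm.sf(abs(zstat)), np.finfo(float).tiny)
    cutoff = youden_cutoff(ls, positive_high=positive_high)
    return ROCResult(auc=float(auc), ci_low=float(lo), ci_high=float(hi),
                     p_value=float(p), best_cutoff=float(cutoff),
                     degenerate=bool(degenerate))


def youden_cutoff(ls: LabeledScores, positive_high: bool = True) -> float:
    """Observed score maximizing Youden's J = sensitivity + specificity - 1.

    The rule classifies positive at ``score >= c`` (``<= c`` when
    ``positive_high=False``); candidate cutoffs are the observed scores and
    ties in J are broken toward the smallest cutoff.
    """
    pos, neg = ls.split()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    candidates = np.unique(ls.scores)
    best_c, best_j = None, -np.inf
    for c in candidates:
        if positive_high:
            sens = (pos >= c).mean()
            spec = (neg < c).mean()
        else:
            sens = (pos <= c).mean()
            spec = (neg > c).mean()
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c)


class FisherCapacityError(RuntimeError):
    """Exact r x c enumeration exceeds the table budget."""


def _enumerate_cell_logfact_sums(row_margins, col_margins, budget):
    """Yield sum_ij log(n_ij!) over all tables with the given margins.

    Depth-first over rows; within a row, over compositions bounded by the
    remaining column totals.  Raises FisherCapacityError past ``budget``
    completed tables.
    """
    rows = list(row_margins)
    n_rows = len(rows)
    count = 0

    def rec(i, remaining_cols, acc):
        nonlocal count
        if i == n_rows - 1:
            # last row is forced
            yield acc + sum(lgamma(c + 1) for c in remaining_cols)
            count += 1
            if count > budget:
                raise FisherCapacityError(
                    f"more than {budget} tables with these margins; "
                    "use monte_carlo=True"
                )
            return
        yield from _row_rec(i, rows[i], 0, remaining_cols, acc)

    def _row_rec(i, left, j, remaining_cols, acc):
        n_cols = len(remaining_cols)
        if j == n_cols - 1:
            if left <= remaining_cols[j]:
                nc = list(remaining_cols)
                nc[j] -= left
                yield from rec(i + 1, nc, acc + lgamma(left + 1))
            return
        tail_capacity = sum(remaining_cols[j + 1:])
        lo = max(0, left - tail_capacity)
        hi = min(left, remaining_cols[j])
        for x in range(lo, hi + 1):
            nc = list(remaining_cols)
            nc[j] -= x
            yield from _row_rec(i, left - x, j + 1, nc, acc + lgamma(x + 1))

    yield from rec(0, list(col_margins), 0.0)


def _log_table_prob_const(row_margins, col_margins):
    n = sum(row_margins)
    return (
        sum(lgamma(r + 1) for r in row_margins)
        + sum(lgamma(c + 1) for c in col_margins)
        - lgamma(n + 1)
    )


def fisher_exact_rxc(
    table,
    max_tables: int = 2_000_000,
    monte_carlo: bool = False,
    n_resamples: int = 100_000,
    rng=None,
    rel_tol: float = 1e-7,
) -> float:
    """Two-sided Fisher's exact test for an r x c table (Freeman-Halton).

    Sums the conditional hypergeometric probabilities of every table with
    the observed margins whose probability does not exceed that of the
    observed table (within relative tolerance ``rel_tol``).  When the
    margins admit more than ``max_tables`` tables, pass
    ``monte_carlo=True`` to estimate the p-value by sampling tables with
    Patefield's algorithm instead.
    """
    if isinstance(table, ContingencyTable):
        counts = table.counts
    else:
        counts = ContingencyTable(np.asarray(table)).counts
    row_margins = counts.sum(axis=1).tolist()
    col_margins = counts.sum(axis=0).tolist()
    if min(sum(row_margins), 1) == 0:
        raise ValueError("table must contain at least one observation")
    const = _log_table_prob_const(row_margins, col_margins)
    logp_obs = const - float(sum(lgamma(int(x) + 1) for x in counts.ravel()))
    cut = logp_obs + math.log1p(rel_tol)

    if monte_carlo:
        rng = np.random.default_rng(rng)
        dist = sps.random_table(row_margins, col_margins)
        sims = dist.rvs(n_resamples, method="patefield", random_state=rng)
        logfact = np.vectorize(lambda x: lgamma(x + 1))
        logp = const - logfact(sims).sum(axis=(1, 2))
        hits = int((logp <= cut).sum())
        return (hits + 1) / (n_resamples + 1)

    p = 0.0
    for logfact_sum in _enumerate_cell_logfact_sums(row_margins, col_margins,
                                                    max_tables):
        logp = const - logfact_sum
        if logp <= cut:
            p += math.exp(logp)
    return min(p, 1.0)
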