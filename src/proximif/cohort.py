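"""Cohort dichotomization and the nonparametric two-group test.

Two small primitives used throughout the pipeline's group comparisons:
splitting subjects into high/low halves at the sample median of a score,
and the two-tailed Mann–Whitney U test for comparing a measurement between
two groups without a normality assumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator


@dataclass
class GroupComparison:
    """Result of a two-tailed Mann–Whitney U test.

    ``u_statistic`` is the smaller of the two one-sided U statistics, so it
    lies in [0, n_x * n_y] and matches the tabled convention.
    """

    u_statistic: float
    p_two_tailed: float
    n_x: int
    n_y: int
    median_x: float
    median_y: float


def mann_whitney_two_tailed(x, y) -> GroupComparison:
    """Two-tailed Mann–Whitney U test on two independent samples.

    U is computed from midranks (tie-corrected). The p value is exact by
    enumeration for small tie-free samples (n_x + n_y <= 12), otherwise a
    normal approximation with tie-corrected variance and continuity
    correction is used, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_x = float(res.statistic)
    u = min(u_x, x.size * y.size - u_x)
    return GroupComparison(
        u_statistic=u,
        p_two_tailed=min(float(res.pvalue), 1.0),
        n_x=int(x.size), n_y=int(y.size),
        median_x=float(np.median(x)), median_y=float(np.median(y)),
    )


@dataclass
class DichotomyResult:
    """High/low labels from a median split.

    ``label == "high"`` iff ``value > cutoff``; ties at the median fall in
    the low group (documented tie rule — cohorts with distinct values split
    into exact halves for even n).
    """

    labels: pd.Series  # "high"/"low", indexed like the input
    cutoff: float
    n_high: int
    n_low: int


def dichotomize_by_median(values) -> DichotomyResult:
    """Split subjects at the sample median of their measurements.

    The cutoff is the ordinary sample median (mean of the middle order
    statistics for even n); values strictly above it are "high".
    """
    s = pd.Series(values, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 subjects to dichotomize")
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("values must be finite")
    if s.nunique() == 1:
        raise ValueError("all values identical: median split is degenerate")
    cutoff = float(s.median())
    labels = pd.Series(np.where(s > cutoff, "high", "low"), index=s.index, name="label")
    return DichotomyResult(labels=labels, cutoff=cutoff,
                           n_high=int((labels == "high").sum()),
                           n_low=int((labels == "low").sum()))


class MedianDichotomizer(BaseEstimator):
    """Estimator view of the median split: fit learns ``cutoff_``, predict labels.

    New subjects are labelled against the fitted cutoff, so the split learnt
    on one cohort can be applied to another.
    """

    def fit(self, X, y=None) -> "MedianDichotomizer":
        res = dichotomize_by_median(np.ravel(np.asarray(X, dtype=float)))
        self.cutoff_ = res.cutoff
        self.n_high_ = res.n_high
        self.n_low_ = res.n_low
        return self

    def predict(self, X) -> np.ndarray:
        v = np.ravel(np.asarray(X, dtype=float))
        return np.where(v > self.cutoff_, "high", "low")
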