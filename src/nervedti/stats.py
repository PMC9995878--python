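"""Statistical procedures for nerve DTI studies.

Covers the variability, agreement and trend analyses typical of
fascicle-level diffusion studies: coefficients of variation within and
between fascicles, one-way intraclass correlation for repeated
segmentations, slice-wise linear trends of an index along the nerve, the
per-sample regression + one-sample t-test used to test fascicle-level
correlations across nerves, and paired per-slice percent contrasts
between compartments.

Omnibus comparisons (normality tests, ANOVA, post-hoc contrasts) are
deliberately not re-implemented: the tables produced by the rest of the
package feed directly into any general statistics tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RatingTable",
    "SliceSeries",
    "coefficient_of_variation",
    "cov_within_between",
    "icc_oneway",
    "slice_trend",
    "fascicle_correlation_test",
    "compartment_contrast",
]


@dataclass(frozen=True)
class RatingTable:
    """n subjects × k repeated ratings, no missing cells."""

    ratings: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.ratings, dtype=float)
        if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
            raise ValueError("rating table must be (n >= 2) x (k >= 2)")
        if not np.all(np.isfinite(r)):
            raise ValueError("rating table has missing or non-finite cells")
        object.__setattr__(self, "ratings", r)


@dataclass(frozen=True)
class SliceSeries:
    """Ordered slice positions with one index value per slice."""

    slices: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.slices, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if s.shape != v.shape or s.ndim != 1 or s.size < 3:
            raise ValueError("need >= 3 (slice, value) pairs")
        object.__setattr__(self, "slices", s)
        object.__setattr__(self, "values", v)


def coefficient_of_variation(values: np.ndarray) -> float:
    """Sample standard deviation divided by the mean."""
    v = np.asarray(values, dtype=float).ravel()
    m = v.mean()
    if m == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(v.std(ddof=1) / m)


def cov_within_between(
    fa_table: pd.DataFrame | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Within- and between-fascicle coefficients of variation.

    ``fa_table`` is fascicle × slice (rows: fascicles, columns: slices).
    Returns (within, between, n_skipped): ``within`` holds one CoV per
    fascicle computed over its slices; ``between`` one CoV per slice
    computed over its fascicles.  Missing (NaN) cells are skipped and
    counted.
    """
    arr = np.asarray(fa_table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 fascicles and >= 2 slices")
    n_skipped = int(np.count_nonzero(np.isnan(arr)))

    def _cov_1d(v: np.ndarray) -> float:
        v = v[np.isfinite(v)]
        if v.size < 2:
            return np.nan
        return coefficient_of_variation(v)

    within = np.array([_cov_1d(row) for row in arr])
    between = np.array([_cov_1d(col) for col in arr.T])
    return within, between, n_skipped


def icc_oneway(
    table: RatingTable | np.ndarray, *, average: bool = False, clip: bool = False
) -> float:
    """One-way random-effects intraclass correlation, ICC(1).

    From the one-way ANOVA decomposition with n subjects and k ratings:

        ICC(1)   = (MSB − MSW) / (MSB + (k − 1)·MSW)
        ICC(1,k) = (MSB − MSW) / MSB                     (``average=True``)

    The single-rater form can be negative; it is returned unclipped unless
    ``clip`` is set.
    """
    if not isinstance(table, RatingTable):
        table = RatingTable(np.asarray(table))
    r = table.ratings
    n, k = r.shape
    grand = r.mean()
    if np.allclose(r, grand):
        raise ValueError("zero total variance: ICC undefined")
    subj_means = r.mean(axis=1)
    msb = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((r - subj_means[:, None]) ** 2) / (n * (k - 1))
    if average:
        icc = (msb - msw) / msb
    else:
        icc = (msb - msw) / (msb + (k - 1) * msw)
    return float(np.clip(icc, 0.0, 1.0)) if clip else float(icc)


def slice_trend(series: SliceSeries) -> tuple[float, float, float]:
    """Linear trend of an index along the nerve: (slope, Pearson r, p).

    Ordinary least-squares regression of the index on slice position with
    the two-sided t-test p-value for a non-zero slope.  A constant series
    has slope 0 and r defined as 0.
    """
    x, y = series.slices, series.values
    if np.all(x == x[0]):
        raise ValueError("constant slice positions: trend undefined")
    if np.all(y == y[0]):
        return 0.0, 0.0, 1.0
    res = sps.linregress(x, y)
    return float(res.slope), float(res.rvalue), float(res.pvalue)


def fascicle_correlation_test(
    per_nerve_pairs: list[tuple[np.ndarray, np.ndarray]],
) -> dict:
    """Per-nerve regression slopes compared against zero.

    For each nerve sample, the slope of an ordinary least-squares
    regression of y on x is computed; the slopes are then tested against
    zero with a one-sample t-test.  A pooled Pearson correlation over all
    pairs is reported alongside.  Nerves with constant x are dropped with
    a warning.

    Returns a dict with keys ``slopes``, ``t``, ``p``, ``pooled_r``,
    ``pooled_p``, ``n_dropped``.
    """
    slopes = []
    xs, ys = [], []
    n_dropped = 0
    for x, y in per_nerve_pairs:
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size or x.size < 3:
            raise ValueError("each nerve needs >= 3 (x, y) pairs")
        if np.all(x == x[0]):
            n_dropped += 1
            warnings.warn("nerve with constant x dropped", RuntimeWarning, stacklevel=2)
            continue
        slopes.append(float(sps.linregress(x, y).slope))
        xs.append(x)
        ys.append(y)
    if len(slopes) < 2:
        raise ValueError("need >= 2 usable nerves")
    slopes = np.array(slopes)
    if np.allclose(slopes, slopes[0]):
        # zero variance: the t statistic is unbounded unless the common
        # slope is exactly the null value
        t = 0.0 if slopes[0] == 0 else float("inf") * np.sign(slopes[0])
        p = 1.0 if slopes[0] == 0 else 0.0
    else:
        t, p = sps.ttest_1samp(slopes, popmean=0.0)
        t, p = float(t), float(p)
    pooled_r, pooled_p = sps.pearsonr(np.concatenate(xs), np.concatenate(ys))
    return dict(
        slopes=slopes, t=t, p=p,
        pooled_r=float(pooled_r), pooled_p=float(pooled_p),
        n_dropped=n_dropped,
    )


def compartment_contrast(
    per_slice_a: np.ndarray, per_slice_b: np.ndarray
) -> tuple[float, float]:
    """Mean ± SD of the per-slice percent difference 100·(a − b)/b.

    Inputs are paired by slice (e.g. perineurium vs fascicle MD on each
    included slice).  Raises if any reference value b is zero.
    """
    a = np.asarray(per_slice_a, dtype=float).ravel()
    b = np.asarray(per_slice_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("inputs must be paired by slice")
    if np.any(b == 0):
        raise ValueError("zero reference value in contrast denominator")
    pct = 100.0 * (a - b) / b
    sd = float(pct.std(ddof=1)) if pct.size > 1 else 0.0
    return float(pct.mean()), sd
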