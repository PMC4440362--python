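"""Statistical layer: rank tests, fixed-width binning, two-regime regression.

The morphometric analysis rests on non-parametric statistics (spine/synapse
size distributions are heavily skewed): Spearman rank correlation and the
Mann-Whitney U test.  The volume-dependence analysis pools measurements into
fixed-width spine-volume bins (default width 5.0e6 nm^3), excludes bins with a
single data point, and then describes the binned series with a two-regime
model: the dependent variable rises linearly with spine volume up to a
threshold and stays flat above it.  The threshold is chosen by maximizing the
goodness of fit (R^2) of the ordinary least-squares regression over the bins
below the candidate threshold; candidates are interior bin boundaries leaving
at least ``min_bins`` bins on each side (see :func:`fit_two_regime` for the
tie rules).  95% confidence bands come from the t distribution of the lower
fit.  No multiple-testing adjustment is applied; p-values are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "BinnedSeries",
    "TwoRegimeFit",
    "spearman",
    "mann_whitney",
    "bin_average",
    "fit_two_regime",
    "cohort_compare",
]


# ---------------------------------------------------------------- correlation

@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def spearman(x, y) -> CorrelationResult:
    """Two-tailed Spearman rank correlation with midrank ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("spearman needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant vector")
    res = sps.spearmanr(x, y, alternative="two-sided")
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(x))


# ----------------------------------------------------------------- rank test

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample a by pair counting; ties count 1/2."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-tailed exact p by full enumeration of group assignments.

    Enumerates every way of labeling the pooled sample, so midrank ties are
    handled exactly.  p = min(1, 2 * min(P(U <= u), P(U >= u))).
    """
    pooled = np.concatenate([a, b])
    n, total = len(a), len(a) + len(b)
    n_le = n_ge = 0
    idx_all = frozenset(range(total))
    for pick in combinations(range(total), n):
        aa = pooled[list(pick)]
        bb = pooled[list(idx_all - set(pick))]
        u = _u_statistic(aa, bb)
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    m = comb(total, n)
    return min(1.0, 2.0 * min(n_le / m, n_ge / m))


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U (of sample ``a``) and two-tailed p.

    Small samples (both < 8) use exact enumeration; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(a, b)
    if len(a) < 8 and len(b) < 8:
        p = _exact_p(a, b, u)
    else:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    return u, p


# ------------------------------------------------------------------- binning

@dataclass
class BinnedSeries:
    """Fixed-width binned averages of (x, y) with single-point bins excluded."""

    bin_width: float
    bin_index: np.ndarray    # retained bins, k such that bin = [k*w, (k+1)*w)
    center: np.ndarray       # bin centers (k + 0.5) * w
    mean_x: np.ndarray
    mean_y: np.ndarray
    count: np.ndarray
    excluded: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.bin_index)

    @property
    def n_points_retained(self) -> int:
        return int(self.count.sum())


def bin_average(x, y, width: float = 5.0e6) -> BinnedSeries:
    """Pool (x, y) points into contiguous bins [k*w, (k+1)*w) and average.

    Bins containing exactly one data point are excluded and logged with the
    reason; retained + excluded point counts always equal the input size.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if width <= 0:
        raise ValueError("bin width must be positive")
    if len(x) == 0:
        raise ValueError("empty input")
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    k = np.floor(x / width).astype(int)
    df = pd.DataFrame({"k": k, "x": x, "y": y})
    g = df.groupby("k").agg(mean_x=("x", "mean"), mean_y=("y", "mean"), count=("x", "size"))
    keep = g[g["count"] >= 2]
    excluded = [(int(i), "single data point") for i in g[g["count"] == 1].index]
    return BinnedSeries(
        bin_width=float(width),
        bin_index=keep.index.to_numpy(dtype=int),
        center=(keep.index.to_numpy(dtype=float) + 0.5) * width,
        mean_x=keep["mean_x"].to_numpy(),
        mean_y=keep["mean_y"].to_numpy(),
        count=keep["count"].to_numpy(dtype=int),
        excluded=excluded,
    )


# ------------------------------------------------------------ two-regime fit

@dataclass
class RegimeFit:
    slope: float
    intercept: float
    r_squared: float
    slope_p: float       # slope-vs-zero, two-tailed
    n_bins: int
    mean_y: float


@dataclass
class TwoRegimeFit:
    threshold: float                 # nm^3, lies on a bin boundary
    lower: RegimeFit
    upper: RegimeFit | None
    n_bins: int
    n_lower: int
    band_x: np.ndarray               # lower-range bin mean x
    band_fit: np.ndarray             # fitted values
    band_lo: np.ndarray              # 95% confidence band
    band_hi: np.ndarray
    candidate_thresholds: np.ndarray
    candidate_r2: np.ndarray
    no_break: bool                   # all candidates fit equally well
    no_trend: bool                   # lower slope not distinguishable from 0


def _ols(x: np.ndarray, y: np.ndarray) -> RegimeFit:
    res = sps.linregress(x, y)
    return RegimeFit(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue) ** 2, slope_p=float(res.pvalue),
                     n_bins=len(x), mean_y=float(np.mean(y)))


def fit_two_regime(series: BinnedSeries, min_bins: int = 3,
                   plateau_rtol: float = 5e-4) -> TwoRegimeFit:
    """Threshold detection by R^2 optimization over the lower range.

    For every candidate threshold (an interior bin boundary leaving at least
    ``min_bins`` retained bins on each side) an OLS line is fit to the bins
    below; the threshold maximizing the lower-range R^2 wins.  Exact ties
    (a degenerate, break-free series) resolve to the smallest threshold and
    set the ``no_break`` flag; near-ties within ``plateau_rtol`` of the
    maximum resolve to the largest candidate, i.e. the longest lower range
    that fits as well as the best.  The upper regime is summarized by its
    own OLS fit and its mean.
    """
    if series.n_bins < 2 * min_bins:
        raise ValueError(f"need >= {2 * min_bins} retained bins, have {series.n_bins}")
    w = series.bin_width
    ks = series.bin_index
    # candidate boundaries: above candidate i, bins with k >= c go upper
    cands, r2s = [], []
    for i in range(min_bins, series.n_bins - min_bins + 1):
        c = ks[i]  # boundary at k*w separates bins [0..i) from [i..)
        lo = slice(0, i)
        fit = _ols(series.mean_x[lo], series.mean_y[lo])
        cands.append(c * w)
        r2s.append(fit.r_squared)
    cands = np.asarray(cands)
    r2s = np.asarray(r2s)
    no_break = bool(r2s.max() - r2s.min() < 1e-9)
    if no_break:
        best = 0  # exact tie: smallest threshold, flagged degenerate
    else:
        # R^2 saturates as the lower range grows toward the true break and
        # collapses once upper-regime bins are included, so near-ties at the
        # top (within plateau_rtol) resolve to the largest candidate: the
        # longest lower range that still fits as well as the best
        plateau = r2s >= r2s.max() - plateau_rtol
        best = int(np.max(np.where(plateau)[0]))
    threshold = float(cands[best])
    i = best + min_bins
    lower = _ols(series.mean_x[:i], series.mean_y[:i])
    upper = _ols(series.mean_x[i:], series.mean_y[i:]) if series.n_bins - i >= 2 else None

    # 95% confidence band of the lower fit at the lower-range bin positions
    xl, yl = series.mean_x[:i], series.mean_y[:i]
    yhat = lower.intercept + lower.slope * xl
    n = len(xl)
    dof = n - 2
    resid = yl - yhat
    s2 = float(resid @ resid) / dof if dof > 0 else np.nan
    sxx = float(np.sum((xl - xl.mean()) ** 2))
    se = np.sqrt(s2 * (1.0 / n + (xl - xl.mean()) ** 2 / sxx)) if dof > 0 else np.full(n, np.nan)
    tcrit = sps.t.ppf(0.975, dof) if dof > 0 else np.nan
    return TwoRegimeFit(
        threshold=threshold,
        lower=lower,
        upper=upper,
        n_bins=series.n_bins,
        n_lower=i,
        band_x=xl,
        band_fit=yhat,
        band_lo=yhat - tcrit * se,
        band_hi=yhat + tcrit * se,
        candidate_thresholds=cands,
        candidate_r2=r2s,
        no_break=no_break,
        no_trend=bool(lower.slope_p > 0.05),
    )


# ---------------------------------------------------------- cohort comparison

def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def cohort_compare(records_a: pd.DataFrame, records_b: pd.DataFrame,
                   variables: list[str],
                   labels: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Per-variable Mann-Whitney comparison with mean +/- SEM per cohort.

    Returns a table with one row per variable: mean, SEM and n for each
    cohort, the U statistic, the two-tailed p and significance stars at
    0.05 / 0.01 / 0.001.
    """
    if len(records_a) == 0 or len(records_b) == 0:
        raise ValueError("both cohorts must be non-empty")
    rows = []
    la, lb = labels
    for var in variables:
        if var not in records_a.columns or var not in records_b.columns:
            raise KeyError(f"unknown variable {var!r}")
        a = records_a[var].dropna().to_numpy(dtype=float)
        b = records_b[var].dropna().to_numpy(dtype=float)
        u, p = mann_whitney(a, b)
        rows.append({
            "variable": var,
            f"mean_{la}": a.mean(), f"sem_{la}": sps.sem(a) if len(a) > 1 else np.nan,
            f"n_{la}": len(a),
            f"mean_{lb}": b.mean(), f"sem_{lb}": sps.sem(b) if len(b) > 1 else np.nan,
            f"n_{lb}": len(b),
            "U": u, "p": p, "sig": _stars(p),
        })
    return pd.DataFrame(rows)
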