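import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spinemorph.stats import (bin_average, cohort_compare, fit_two_regime,
                              mann_whitney, spearman)


# --------------------------------------------------------------- spearman

def test_spearman_monotone_limits():
    x = np.arange(10.0)
    assert spearman(x, x ** 3).r == pytest.approx(1.0)
    assert spearman(x, -np.exp(x / 3)).r == pytest.approx(-1.0)


def test_spearman_with_ties_matches_rank_formula():
    x = np.array([1.0, 2.0, 2.0, 4.0, 5.0, 5.0, 7.0])
    y = np.array([3.0, 1.0, 4.0, 4.0, 6.0, 8.0, 8.0])
    # brute-force oracle: Pearson correlation of midranks
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    r_oracle = float(np.corrcoef(rx, ry)[0, 1])
    assert spearman(x, y).r == pytest.approx(r_oracle, abs=1e-12)


def test_spearman_invariant_under_monotone_transforms():
    rng = np.random.default_rng(0)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    base = spearman(x, y).r
    assert spearman(np.exp(x), y).r == pytest.approx(base)
    assert spearman(x, y ** 3).r == pytest.approx(base)


def test_spearman_errors():
    with pytest.raises(ValueError):
        spearman([1, 2], [1, 2])
    with pytest.raises(ValueError):
        spearman([1, 2, 3], [5, 5, 5])
    with pytest.raises(ValueError):
        spearman([1, 2, 3], [1, 2])


# ------------------------------------------------------------ mann-whitney

def _u_brute(a, b):
    return sum(1.0 if x > y else 0.5 if x == y else 0.0
               for x in a for y in b)


def test_u_statistic_examples():
    assert mann_whitney([1, 2], [3, 4])[0] == 0.0
    a = [1.0, 2.0, 3.0, 4.0]
    assert mann_whitney(a, a)[0] == len(a) ** 2 / 2


def test_u_matches_pair_counting_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        a = rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
        b = rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
        assert mann_whitney(a, b)[0] == pytest.approx(_u_brute(a, b))


def test_exact_p_identical_samples_is_one():
    _, p = mann_whitney([1, 2, 3], [1, 2, 3])
    assert p == pytest.approx(1.0)


def test_exact_p_matches_scipy_on_tie_free_samples():
    rng = np.random.default_rng(2)
    for _ in range(10):
        pool = rng.permutation(14)[:rng.integers(5, 12)].astype(float)
        k = len(pool) // 2
        a, b = pool[:k], pool[k:]
        if len(a) < 2 or len(a) >= 8 or len(b) >= 8:
            continue
        _, p = mann_whitney(a, b)
        p_sp = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(float(p_sp), abs=1e-12)


def test_mann_whitney_empty_rejected():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


# ---------------------------------------------------------------- binning

def test_bin_average_excludes_single_point_bins():
    series = bin_average([1e6, 2e6, 6e6], [1.0, 2.0, 3.0], width=5e6)
    assert series.n_bins == 1
    assert series.mean_x[0] == pytest.approx(1.5e6)
    assert series.mean_y[0] == pytest.approx(1.5)
    assert series.excluded == [(1, "single data point")]
    assert series.n_points_retained + len(series.excluded) == 3


def test_bin_average_single_bin_preserves_mean():
    y = [2.0, 4.0, 9.0]
    series = bin_average([1.0, 2.0, 3.0], y, width=10.0)
    assert series.n_bins == 1
    assert series.mean_y[0] == pytest.approx(np.mean(y))


def test_bin_average_all_singletons():
    series = bin_average([0.0, 10.0, 20.0], [1.0, 2.0, 3.0], width=5.0)
    assert series.n_bins == 0
    assert len(series.excluded) == 3


def test_bin_average_conserves_points():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 1e8, 300)
    series = bin_average(x, rng.normal(size=300), width=5e6)
    singles = sum(1 for _ in series.excluded)
    assert series.n_points_retained + singles == 300


def test_bin_average_errors():
    with pytest.raises(ValueError):
        bin_average([], [], width=5.0)
    with pytest.raises(ValueError):
        bin_average([1.0], [1.0], width=0)
    with pytest.raises(ValueError):
        bin_average([-1.0, 1.0], [0.0, 0.0], width=5.0)


# --------------------------------------------------------- two-regime fit

def _piecewise(seed, n=200, thr=5e7, slope=2e-8, noise=0.02):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1e8, n)
    y = slope * np.minimum(x, thr) + rng.normal(0, noise, n)
    return bin_average(x, y, width=5e6)


def test_breakpoint_recovered_within_one_bin():
    fit = fit_two_regime(_piecewise(seed=0))
    assert abs(fit.threshold - 5e7) <= 5e6
    assert fit.lower.r_squared > 0.9
    assert fit.lower.slope_p < 0.05
    assert not fit.no_trend


def test_breakpoint_median_error_over_seeds_below_bin_width():
    errs = [abs(fit_two_regime(_piecewise(seed=s)).threshold - 5e7)
            for s in range(30)]
    assert np.median(errs) <= 5e6


def test_perfectly_linear_data_flagged_no_break():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 1e8, 300)
    series = bin_average(x, 3e-8 * x, width=5e6)
    fit = fit_two_regime(series)
    assert fit.no_break
    assert fit.threshold == pytest.approx(series.bin_index[3] * series.bin_width)
    assert fit.upper.slope == pytest.approx(fit.lower.slope, rel=1e-6)


def test_flat_data_flagged_no_trend():
    rng = np.random.default_rng(2)
    x = rng.uniform(0, 1e8, 400)
    series = bin_average(x, rng.normal(0, 1, 400), width=5e6)
    assert fit_two_regime(series).no_trend


def test_threshold_invariant_to_y_affine_rescaling():
    series = _piecewise(seed=5)
    fit0 = fit_two_regime(series)
    import dataclasses
    scaled = dataclasses.replace(series, mean_y=series.mean_y * 37.0 - 4.2)
    fit1 = fit_two_regime(scaled)
    assert fit1.threshold == fit0.threshold
    np.testing.assert_allclose(fit1.candidate_r2, fit0.candidate_r2, atol=1e-9)


def test_two_regime_needs_enough_bins():
    series = bin_average([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], width=10.0)
    with pytest.raises(ValueError):
        fit_two_regime(series)


def test_confidence_band_brackets_fit():
    fit = fit_two_regime(_piecewise(seed=7))
    assert np.all(fit.band_lo <= fit.band_fit)
    assert np.all(fit.band_fit <= fit.band_hi)


# ---------------------------------------------------------------- cohorts

def test_identical_cohorts_compare_as_equal():
    df = pd.DataFrame({"volume": np.arange(10.0), "sphericity": np.linspace(0.3, 0.8, 10)})
    table = cohort_compare(df, df.copy(), ["volume", "sphericity"],
                           labels=("young", "mature"))
    assert (table["U"] == 50.0).all()
    assert (table["mean_young"] == table["mean_mature"]).all()
    assert (table["sig"] == "ns").all()


def test_shifted_cohorts_detected():
    rng = np.random.default_rng(4)
    a = pd.DataFrame({"v": rng.normal(0, 1, 50)})
    b = pd.DataFrame({"v": rng.normal(1.5, 1, 50)})
    table = cohort_compare(a, b, ["v"])
    assert table["p"].iloc[0] < 0.05


def test_unknown_variable_rejected():
    df = pd.DataFrame({"v": [1.0, 2.0]})
    with pytest.raises(KeyError):
        cohort_compare(df, df, ["nope"])
    with pytest.raises(ValueError):
        cohort_compare(df.iloc[:0], df, ["v"])
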