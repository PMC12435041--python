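"""Univariate tests, IRLS logistic regression, Wald odds ratios, and the screen."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from romtraj import (
    SimulationConfig,
    classify_cohort,
    compute_roi_records,
    fisher_exact_test,
    fit_logistic_irls,
    run_screen,
    simulate_cohort,
    two_sample_t_test,
    wald_odds_ratios,
)
from romtraj.risk_screen import (
    BASE_FACTORS,
    ClassSizeError,
    FactorSpec,
    InsufficientDataError,
    NotConvergedError,
)


# ---------------------------------------------------------------------------
# Independent oracles


def welch_t_reference(x, y):
    """Hand-coded Welch t-test, independent of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p


def fisher_reference(a, b, c, d):
    """Two-sided Fisher p by exact hypergeometric enumeration (rationals)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def hyper(k):
        return (Fraction(math.comb(r1, k) * math.comb(r2, c1 - k),
                         math.comb(n, c1)))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = hyper(a)
    total = sum(hyper(k) for k in range(lo, hi + 1) if hyper(k) <= p_obs)
    return float(total)


# ---------------------------------------------------------------------------
# t-test


def test_t_test_identical_samples():
    t, p = two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_t_test_matches_independent_welch_formula():
    x = [0.0, 0.0, 1.0, 1.0]
    y = [1.0, 1.0, 2.0, 2.0]
    t, p = two_sample_t_test(x, y)
    t_ref, p_ref = welch_t_reference(x, y)
    assert t == pytest.approx(t_ref, abs=1e-9)
    assert p == pytest.approx(p_ref, abs=1e-9)


def test_t_test_matches_welch_on_random_samples(rng):
    for _ in range(50):
        x = rng.normal(0, 1, size=int(rng.integers(3, 30)))
        y = rng.normal(0.3, 1.5, size=int(rng.integers(3, 30)))
        t, p = two_sample_t_test(x, y)
        t_ref, p_ref = welch_t_reference(x, y)
        assert t == pytest.approx(t_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-9)


def test_t_test_scale_invariance():
    x = [1.0, 2.0, 4.0, 9.0]
    y = [2.0, 5.0, 7.0, 8.0]
    t1, p1 = two_sample_t_test(x, y)
    t2, p2 = two_sample_t_test([10 * v for v in x], [10 * v for v in y])
    assert t1 == pytest.approx(t2, abs=1e-12)
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_t_test_requires_two_observations():
    with pytest.raises(InsufficientDataError):
        two_sample_t_test([1.0], [1.0, 2.0])


def test_t_test_degenerate_equal_constants_gives_p_one():
    assert two_sample_t_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)


def test_t_test_pooled_variance_switch():
    x = [0.0, 0.0, 1.0, 1.0, 2.0]
    y = [1.0, 3.0, 5.0, 7.0]
    _, p_welch = two_sample_t_test(x, y)
    _, p_pooled = two_sample_t_test(x, y, equal_var=True)
    assert p_welch != p_pooled


# ---------------------------------------------------------------------------
# Fisher's exact test


def test_fisher_small_table_exact_value():
    """p(2,0;0,2) = 1/3: tables a in {0,1,2} have probs 1/6, 2/3, 1/6."""
    assert fisher_exact_test(2, 0, 0, 2) == pytest.approx(1.0 / 3.0, abs=1e-12)


def test_fisher_no_association_is_one():
    assert fisher_exact_test(5, 5, 5, 5) == pytest.approx(1.0)


def test_fisher_zero_margin_is_one():
    assert fisher_exact_test(0, 5, 0, 7) == pytest.approx(1.0)


def test_fisher_rejects_negative_counts():
    with pytest.raises(ValueError):
        fisher_exact_test(-1, 2, 3, 4)


def test_fisher_matches_enumeration_on_random_tables(rng):
    for _ in range(150):
        a, b, c, d = (int(v) for v in rng.integers(0, 11, size=4))
        if a + b + c + d == 0:
            continue
        assert fisher_exact_test(a, b, c, d) == pytest.approx(
            fisher_reference(a, b, c, d), abs=1e-12)


def test_fisher_invariant_under_row_and_column_swaps(rng):
    for _ in range(100):
        a, b, c, d = (int(v) for v in rng.integers(0, 11, size=4))
        if a + b + c + d == 0:
            continue
        p = fisher_exact_test(a, b, c, d)
        assert fisher_exact_test(c, d, a, b) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_test(b, a, d, c) == pytest.approx(p, abs=1e-12)


# ---------------------------------------------------------------------------
# Logistic IRLS


def _contingency_design(n11, n10, n01, n00):
    """exposed-event, exposed-nonevent, unexposed-event, unexposed-nonevent."""
    x = [1] * (n11 + n10) + [0] * (n01 + n00)
    y = [1] * n11 + [0] * n10 + [1] * n01 + [0] * n00
    X = np.column_stack([np.ones(len(x)), x])
    return X, np.array(y, float)


def test_irls_reproduces_contingency_odds_ratio():
    X, y = _contingency_design(20, 10, 10, 20)
    fit = fit_logistic_irls(X, y, column_names=["intercept", "exposed"])
    assert fit.converged
    assert math.exp(fit.coefficients[1]) == pytest.approx(4.0, abs=1e-6)


def test_irls_zero_coefficient_when_independent():
    X, y = _contingency_design(15, 15, 15, 15)
    fit = fit_logistic_irls(X, y)
    assert abs(fit.coefficients[1]) < 1e-8


def test_irls_recovers_planted_coefficients(rng):
    n = 2000
    beta = np.array([-1.0, 0.8])
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    y = (rng.random(n) < p).astype(float)
    fit = fit_logistic_irls(X, y)
    se = np.sqrt(np.diag(fit.covariance))
    assert np.all(np.abs(fit.coefficients - beta) < 3 * se)


def test_irls_matches_statsmodels():
    import statsmodels.api as sm
    rng = np.random.default_rng(4)
    n = 400
    X = np.column_stack([np.ones(n), rng.normal(size=n),
                         (rng.random(n) < 0.4).astype(float)])
    p = 1.0 / (1.0 + np.exp(-(X @ np.array([-0.5, 0.7, -0.9]))))
    y = (rng.random(n) < p).astype(float)
    fit = fit_logistic_irls(X, y)
    ref = sm.Logit(y, X).fit(disp=0)
    assert np.allclose(fit.coefficients, ref.params, atol=1e-6)
    assert np.allclose(np.sqrt(np.diag(fit.covariance)), ref.bse, atol=1e-5)


def test_irls_detects_separation():
    x = np.array([0, 0, 0, 1, 1, 1], float)
    y = np.array([0, 0, 0, 1, 1, 1], float)
    X = np.column_stack([np.ones(6), x])
    with pytest.warns(RuntimeWarning, match="separation"):
        fit = fit_logistic_irls(X, y)
    assert fit.separation and not fit.converged


def test_irls_rejects_allzero_column():
    X = np.column_stack([np.ones(4), np.zeros(4)])
    with pytest.raises(ValueError, match="all-zero"):
        fit_logistic_irls(X, np.array([0, 1, 0, 1], float))


# ---------------------------------------------------------------------------
# Wald odds ratios


def test_wald_interval_from_known_beta_and_se():
    fit = fit_logistic_irls(*_contingency_design(20, 10, 10, 20),
                            column_names=["intercept", "exposed"])
    # Freeze beta = 0, se = 0.1 to check the CI arithmetic directly.
    fit.coefficients = np.array([0.0, 0.0])
    fit.covariance = np.diag([0.01, 0.01])
    out = wald_odds_ratios(fit)
    row = out.iloc[0]
    assert row["odds_ratio"] == pytest.approx(1.0)
    assert row["ci_low"] == pytest.approx(math.exp(-1.959964 * 0.1), abs=1e-4)
    assert row["ci_high"] == pytest.approx(math.exp(1.959964 * 0.1), abs=1e-4)
    assert (0.822, 1.217) == (round(row["ci_low"], 3), round(row["ci_high"], 3))


def test_wald_or_is_exp_beta_and_inside_ci():
    fit = fit_logistic_irls(*_contingency_design(22, 13, 9, 17),
                            column_names=["intercept", "exposed"])
    out = wald_odds_ratios(fit).iloc[0]
    assert out["odds_ratio"] == pytest.approx(math.exp(fit.coefficients[1]))
    assert out["ci_low"] <= out["odds_ratio"] <= out["ci_high"]


def test_wald_refuses_nonconverged_fit():
    x = np.array([0, 0, 0, 1, 1, 1], float)
    X = np.column_stack([np.ones(6), x])
    with pytest.warns(RuntimeWarning):
        fit = fit_logistic_irls(X, x.copy())
    with pytest.raises(NotConvergedError):
        wald_odds_ratios(fit)


# ---------------------------------------------------------------------------
# run_screen


@pytest.fixture(scope="module")
def screened_cohort():
    ds = simulate_cohort(SimulationConfig(n_atsa=120, n_rtsa=0, seed=33))
    roi = compute_roi_records(ds)
    labels = classify_cohort(ds, roi.records, "ROI")
    return ds, labels


def test_screen_reports_every_factor(screened_cohort):
    ds, labels = screened_cohort
    report = run_screen(ds, labels, "roi-slow", prosthesis="aTSA")
    frame = report.to_frame()
    assert set(f.name for f in BASE_FACTORS) <= set(frame["factor"])
    assert frame["p_univariate"].notna().sum() >= 10
    assert (frame["reference_group"] == "fast/average ROI").all()


def test_screen_constant_factor_p_one_and_excluded(screened_cohort):
    ds, labels = screened_cohort
    ds2 = ds
    ds2.patients["cm_renal_failure"] = 0  # identical across classes
    report = run_screen(ds2, labels, "roi-slow", prosthesis="aTSA")
    row = report.univariate.set_index("factor").loc["chronic_renal_failure"]
    assert row["p_univariate"] == pytest.approx(1.0)
    assert "chronic_renal_failure" not in set(report.multivariate["factor"])


def test_screen_is_deterministic(screened_cohort):
    ds, labels = screened_cohort
    a = run_screen(ds, labels, "roi-slow", prosthesis="aTSA").to_frame()
    b = run_screen(ds, labels, "roi-slow", prosthesis="aTSA").to_frame()
    pd.testing.assert_frame_equal(a, b)


def test_screen_aborts_on_tiny_class(screened_cohort):
    ds, labels = screened_cohort
    lab = labels.copy()
    lab["label"] = "FAST"  # nobody slow
    with pytest.raises(ClassSizeError):
        run_screen(ds, lab, "roi-slow", prosthesis="aTSA")


def test_screen_rejects_unknown_comparison(screened_cohort):
    ds, labels = screened_cohort
    with pytest.raises(ValueError):
        run_screen(ds, labels, "slow-vs-fast")


def test_screen_preop_rom_identifies_slow_cohort(screened_cohort):
    """Slow-ROI patients carry higher preoperative ROM, as planted."""
    ds, labels = screened_cohort
    report = run_screen(ds, labels, "roi-slow", prosthesis="aTSA")
    uni = report.univariate.set_index("factor")
    assert uni.loc["preop_abduction", "p_univariate"] < 0.001
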