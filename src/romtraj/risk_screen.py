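"""Univariate comparison and multivariate logistic risk-factor screening.

The screen contrasts two trajectory classes (slow ROI vs. fast/average ROI,
or fast ROD vs. slow/average ROD) on a set of candidate factors:

1. **Univariate**: a two-tailed unpaired t-test for continuous factors
   (Welch by default; a pooled-variance switch is provided) and Fisher's
   exact test for binary factors.
2. **Multivariate**: factors with univariate p below alpha enter one
   logistic regression, fitted by iteratively reweighted least squares
   (IRLS), reported as Wald odds ratios with 95% confidence intervals.

There is no multiple-testing adjustment; alpha is 0.05 throughout.
Complete-case handling per factor; patients labelled UNCLASSIFIED are
excluded before the screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_data import CohortDataset, ROM_MEASURES


class InsufficientDataError(ValueError):
    """A sample is too small (or a class too thin) for the requested test."""


class ClassSizeError(InsufficientDataError):
    """Fewer than two patients in one of the compared classes."""


class NotConvergedError(RuntimeError):
    """Odds ratios requested from a non-converged logistic fit."""


# ---------------------------------------------------------------------------
# Univariate tests


def two_sample_t_test(x, y, equal_var: bool = False) -> tuple[float, float]:
    """Two-tailed unpaired t-test; Welch degrees of freedom by default.

    Returns (t, p).  Samples where both groups are constant and equal give
    (0.0, 1.0) — no evidence of a difference is representable for a
    degenerate factor.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each sample needs n >= 2 for a t-test")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def fisher_exact_test(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The two-sided p is the total hypergeometric probability of all tables
    with the observed margins whose probability does not exceed that of the
    observed table.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("table total must be positive")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


# ---------------------------------------------------------------------------
# Logistic regression by IRLS


@dataclass
class LogisticFit:
    """A fitted (or halted) logistic regression.

    coefficients : including the intercept in column order of the design.
    covariance : inverse observed information at the final iterate.
    converged : max |score| fell below ``tol`` before ``max_iter``.
    separation : a coefficient ran away (|beta| > 15), the classic
        perfect-separation signature.
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    converged: bool
    separation: bool
    n_iterations: int
    column_names: tuple[str, ...]


def fit_logistic_irls(design: np.ndarray, outcome: np.ndarray,
                      tol: float = 1e-8, max_iter: int = 100,
                      column_names: Optional[Sequence[str]] = None) -> LogisticFit:
    """Maximum-likelihood logistic regression via iteratively reweighted least squares.

    ``design`` must include an intercept column; ``outcome`` is 0/1.
    Convergence is declared when the largest score (gradient) component is
    below ``tol``.  Diverging coefficients (|beta| > 15) trigger a
    separation warning and a non-converged fit.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("design must be 2-D with one row per outcome")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if (X == 0).all(axis=0).any():
        raise ValueError("design contains an all-zero column")

    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        score = X.T @ (y - p)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(beta)) > 15.0:
            separation = True
            warnings.warn("possible perfect separation: coefficients diverging",
                          RuntimeWarning, stacklevel=2)
            break

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(p * (1.0 - p), 1e-12, None)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    names = tuple(column_names) if column_names is not None else tuple(
        f"x{i}" for i in range(k))
    return LogisticFit(coefficients=beta, covariance=cov,
                       converged=converged and not separation,
                       separation=separation, n_iterations=it,
                       column_names=names)


def wald_odds_ratios(fit: LogisticFit, alpha: float = 0.05,
                     reference_group: str = "") -> pd.DataFrame:
    """Odds ratios with Wald (1 - alpha) confidence intervals per coefficient.

    OR = exp(beta); CI = exp(beta +/- z * se); two-sided Wald p.  The
    intercept row is excluded.  Refuses a non-converged fit.
    """
    if not fit.converged:
        raise NotConvergedError(
            "odds ratios requested from a non-converged logistic fit"
            + (" (separation detected)" if fit.separation else ""))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    se = np.sqrt(np.diag(fit.covariance))
    rows = []
    for i, name in enumerate(fit.column_names):
        if name == "intercept":
            continue
        beta = fit.coefficients[i]
        wald = beta / se[i] if se[i] > 0 else np.inf
        rows.append({
            "factor": name,
            "odds_ratio": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - z * se[i])),
            "ci_high": float(np.exp(beta + z * se[i])),
            "p_value": float(2.0 * stats.norm.sf(abs(wald))),
            "reference_group": reference_group,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Factor specification and screen


@dataclass(frozen=True)
class FactorSpec:
    """A candidate risk factor: a named column and whether it is continuous."""

    name: str
    kind: str  # "continuous" | "binary"
    column: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError("factor kind must be 'continuous' or 'binary'")
        if not self.column:
            object.__setattr__(self, "column", self.name)


#: Patient-table factors screened for every comparison.
BASE_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("age", "continuous", "age_years"),
    FactorSpec("female", "binary", "sex_female"),
    FactorSpec("bmi", "continuous", "bmi"),
    FactorSpec("previous_surgery", "binary"),
    FactorSpec("injections", "binary"),
    FactorSpec("osteoarthritis", "binary", "dx_osteoarthritis"),
    FactorSpec("osteonecrosis", "binary", "dx_osteonecrosis"),
    FactorSpec("rotator_cuff_tear", "binary", "dx_rotator_cuff_tear"),
    FactorSpec("cuff_tear_arthropathy", "binary", "dx_cuff_tear_arthropathy"),
    FactorSpec("rheumatoid_arthritis", "binary", "dx_rheumatoid_arthritis"),
    FactorSpec("no_comorbidity", "binary", "cm_none"),
    FactorSpec("hypertension", "binary", "cm_hypertension"),
    FactorSpec("heart_disease", "binary", "cm_heart_disease"),
    FactorSpec("diabetes", "binary", "cm_diabetes"),
    FactorSpec("tobacco_use", "binary", "cm_tobacco"),
    FactorSpec("chronic_renal_failure", "binary", "cm_renal_failure"),
)

#: Preoperative ROM factors (continuous), filled from the visit table.
PREOP_ROM_FACTORS: tuple[FactorSpec, ...] = tuple(
    FactorSpec(f"preop_{m}", "continuous") for m in ROM_MEASURES)

#: Radiographic/complication factors, screened for the decline comparison.
RADIOGRAPHIC_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("humeral_rll", "binary"),
    FactorSpec("glenoid_rll", "binary"),
    FactorSpec("glenoid_rll_grade", "continuous"),
    FactorSpec("scapular_notching", "binary"),
    FactorSpec("notching_grade", "continuous"),
    FactorSpec("complication", "binary"),
    FactorSpec("revision", "binary"),
)

COMPARISONS = {
    # comparison key: (event label, reference description)
    "roi-slow": ("SLOW", "fast/average ROI"),
    "rod-fast": ("FAST", "slow/average ROD"),
}


def default_factors(comparison: str) -> tuple[FactorSpec, ...]:
    base = BASE_FACTORS + PREOP_ROM_FACTORS
    return base + RADIOGRAPHIC_FACTORS if comparison == "rod-fast" else base


@dataclass
class ScreenReport:
    """Result of one univariate -> multivariate screen."""

    comparison: str
    prosthesis: Optional[str]
    reference_group: str
    n_event: int
    n_reference: int
    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    fit: Optional[LogisticFit]

    def to_frame(self) -> pd.DataFrame:
        """Combined table mirroring the published risk-factor table layout."""
        uni = self.univariate.copy()
        if len(self.multivariate):
            multi = self.multivariate.rename(columns={"p_value": "p_multivariate"})
            out = uni.merge(
                multi[["factor", "p_multivariate", "odds_ratio", "ci_low", "ci_high"]],
                on="factor", how="left")
        else:
            out = uni.assign(p_multivariate=np.nan, odds_ratio=np.nan,
                             ci_low=np.nan, ci_high=np.nan)
        out["reference_group"] = self.reference_group
        return out[["factor", "type", "group1_summary", "group2_summary",
                    "p_univariate", "p_multivariate", "odds_ratio",
                    "ci_low", "ci_high", "reference_group"]]


def build_factor_table(dataset: CohortDataset) -> pd.DataFrame:
    """Patient table augmented with derived factor columns.

    Adds ``sex_female`` (unknown sex -> missing) and ``preop_<measure>``
    columns pulled from preoperative visits.
    """
    tbl = dataset.patients.copy()
    tbl["sex_female"] = tbl["sex"].map({"F": 1.0, "M": 0.0})
    pre = dataset.preop_values()
    pre = pre[pre["measure"].isin(ROM_MEASURES)]
    wide = pre.pivot_table(index="patient_id", columns="measure", values="value",
                           aggfunc="first")
    wide = wide.rename(columns={m: f"preop_{m}" for m in ROM_MEASURES})
    return tbl.merge(wide, on="patient_id", how="left")


def _summaries(factor: FactorSpec, x_event: np.ndarray, x_ref: np.ndarray) -> tuple[str, str]:
    if factor.kind == "continuous":
        return (f"{np.mean(x_ref):.1f} ± {np.std(x_ref, ddof=1):.1f}",
                f"{np.mean(x_event):.1f} ± {np.std(x_event, ddof=1):.1f}")
    return (f"{100.0 * np.mean(x_ref):.1f}%", f"{100.0 * np.mean(x_event):.1f}%")


def run_screen(dataset: CohortDataset, labels: pd.DataFrame, comparison: str,
               factors: Optional[Sequence[FactorSpec]] = None,
               alpha: float = 0.05, prosthesis: Optional[str] = None,
               equal_var: bool = False) -> ScreenReport:
    """Screen candidate factors for association with a trajectory class.

    Parameters
    ----------
    labels : classification results (one row per patient) of the kind
        matching ``comparison`` (ROI for ``roi-slow``, ROD for ``rod-fast``).
    comparison : ``"roi-slow"`` (slow ROI vs. fast/average) or ``"rod-fast"``
        (fast ROD vs. slow/average).
    prosthesis : restrict to one prosthesis; models are normally fitted
        separately per prosthesis.

    Univariate p-values are computed for every factor; factors with p below
    ``alpha`` enter a single multivariate logistic fit (complete case,
    constant columns dropped).  Identical inputs produce identical output.
    """
    if comparison not in COMPARISONS:
        raise ValueError(f"comparison must be one of {sorted(COMPARISONS)}")
    event_label, reference_group = COMPARISONS[comparison]
    if factors is None:
        factors = default_factors(comparison)

    table = build_factor_table(dataset)
    if prosthesis is not None:
        table = table[table["prosthesis"] == prosthesis]
    lab = labels[labels["label"].isin(("FAST", "AVERAGE", "SLOW"))]
    merged = table.merge(lab[["patient_id", "label"]], on="patient_id", how="inner")
    y_all = (merged["label"] == event_label).astype(int)
    if y_all.sum() < 2 or (1 - y_all).sum() < 2:
        raise ClassSizeError(
            f"need >= 2 patients per class; got {int(y_all.sum())} event / "
            f"{int((1 - y_all).sum())} reference")

    uni_rows = []
    significant: list[FactorSpec] = []
    for factor in factors:
        col = merged[factor.column]
        ok = col.notna()
        x_event = col[ok & (y_all == 1)].to_numpy(dtype=float)
        x_ref = col[ok & (y_all == 0)].to_numpy(dtype=float)
        if len(x_event) < 2 or len(x_ref) < 2:
            p = np.nan
            g_ref = g_event = "n/a"
        else:
            g_ref, g_event = _summaries(factor, x_event, x_ref)
            if factor.kind == "continuous":
                _, p = two_sample_t_test(x_event, x_ref, equal_var=equal_var)
            else:
                a = int(x_event.sum())
                b = len(x_event) - a
                c = int(x_ref.sum())
                d = len(x_ref) - c
                p = fisher_exact_test(a, b, c, d)
        uni_rows.append({"factor": factor.name, "type": factor.kind,
                         "group1_summary": g_ref, "group2_summary": g_event,
                         "p_univariate": p})
        if np.isfinite(p) and p < alpha:
            significant.append(factor)
    univariate = pd.DataFrame(uni_rows)

    multivariate = pd.DataFrame(
        columns=["factor", "odds_ratio", "ci_low", "ci_high", "p_value",
                 "reference_group"])
    fit = None
    if significant:
        cols = [f.column for f in significant]
        names = [f.name for f in significant]
        sub = merged[cols + ["label"]].dropna()
        y = (sub["label"] == event_label).to_numpy(dtype=float)
        X = sub[cols].to_numpy(dtype=float)
        keep = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0]
        if keep and len(sub) >= 10:
            X = X[:, keep]
            names = [names[i] for i in keep]
            design = np.column_stack([np.ones(len(y)), X])
            fit = fit_logistic_irls(design, y,
                                    column_names=["intercept"] + names)
            if fit.converged:
                multivariate = wald_odds_ratios(fit, alpha=alpha,
                                                reference_group=reference_group)

    return ScreenReport(comparison=comparison, prosthesis=prosthesis,
                        reference_group=reference_group,
                        n_event=int(y_all.sum()),
                        n_reference=int((1 - y_all).sum()),
                        univariate=univariate, multivariate=multivariate,
                        fit=fit)
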