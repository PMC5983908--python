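"""Association testing between eigen-feature weights and clinical measures.

All models control for age as a covariate because the diagnostic groups
differ in age by design; significance is Bonferroni-corrected over the
declared family of tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class AssociationResult:
    feature: int
    measurement: str
    kind: str                  # "linear" | "anova"
    estimate: float            # regression slope, or F statistic for ANOVA
    se: float
    p_value: float
    r_squared: float
    significant: bool | None = None   # set by bonferroni flagging
    flagged: str = ""                 # non-empty on degenerate input

    def as_dict(self) -> dict:
        return dict(feature=self.feature, measurement=self.measurement,
                    kind=self.kind, estimate=self.estimate, se=self.se,
                    p_value=self.p_value, r_squared=self.r_squared,
                    significant=self.significant, flagged=self.flagged)


def _complete(*arrays: np.ndarray) -> list[np.ndarray]:
    cols = [np.asarray(a, dtype=float) for a in arrays]
    mask = np.logical_and.reduce([np.isfinite(c) for c in cols])
    return [c[mask] for c in cols]


def univariate_feature_test(weights_k: np.ndarray, y: np.ndarray,
                            age: np.ndarray, feature: int = 0,
                            measurement: str = "") -> AssociationResult:
    """OLS of ``y`` on (intercept, feature weight, age); slope t-test.

    A significant slope on the feature term indicates an association between
    the structural feature and the clinical measurement, net of age.
    """
    w, yy, aa = _complete(weights_k, y, age)
    if len(w) < 4:
        raise ValueError("need at least 4 complete cases")
    if np.ptp(w) == 0:
        return AssociationResult(feature, measurement, "linear",
                                 np.nan, np.nan, np.nan, np.nan,
                                 flagged="constant predictor")
    x = sm.add_constant(np.column_stack([w, aa]))
    if np.linalg.matrix_rank(x) < x.shape[1]:
        return AssociationResult(feature, measurement, "linear",
                                 np.nan, np.nan, np.nan, np.nan,
                                 flagged="collinear design")
    fit = sm.OLS(yy, x).fit()
    return AssociationResult(feature, measurement, "linear",
                             estimate=float(fit.params[1]),
                             se=float(fit.bse[1]),
                             p_value=float(fit.pvalues[1]),
                             r_squared=float(fit.rsquared))


def categorical_test(weights_k: np.ndarray, category: np.ndarray,
                     age: np.ndarray, feature: int = 0,
                     measurement: str = "") -> AssociationResult:
    """One-way ANOVA of age-adjusted feature weights across categories.

    Age is regressed out of the weights first; the F test then asks whether
    the residual feature expression differs between groups.
    """
    w = np.asarray(weights_k, dtype=float)
    age = np.asarray(age, dtype=float)
    cat = np.asarray(category)
    mask = np.isfinite(w) & np.isfinite(age) & (cat != None)  # noqa: E711
    w, age, cat = w[mask], age[mask], cat[mask]
    levels = pd.unique(cat)
    if len(levels) < 2:
        raise ValueError("need at least 2 categories")
    if min((cat == lv).sum() for lv in levels) < 2:
        raise ValueError("every category needs at least 2 members")
    resid = sm.OLS(w, sm.add_constant(age)).fit().resid
    groups = [resid[cat == lv] for lv in levels]
    f, p = stats.f_oneway(*groups)
    return AssociationResult(feature, measurement, "anova",
                             estimate=float(f), se=np.nan,
                             p_value=float(p), r_squared=np.nan)


def bonferroni(p_values: np.ndarray, alpha: float = 0.05,
               m: int | None = None) -> np.ndarray:
    """Boolean significance flags at the family-wise threshold ``alpha / m``."""
    p = np.asarray(p_values, dtype=float)
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    m = len(p) if m is None else m
    if m < len(p):
        raise ValueError("family size m must cover all tests")
    return p < alpha / m


def multivariate_r2(weights: np.ndarray, y: np.ndarray,
                    age: np.ndarray) -> tuple[float, np.ndarray]:
    """R^2 of ``y`` regressed on all K feature weights plus age.

    Returns (R^2, fitted values aligned to complete cases) for scatterplot
    export of predicted-versus-true clinical measurements.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2:
        raise ValueError("weights must be (n, K)")
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    mask = np.isfinite(y) & np.isfinite(age) & np.all(np.isfinite(w), axis=1)
    w, y, age = w[mask], y[mask], age[mask]
    k = w.shape[1]
    if len(y) <= k + 2:
        raise ValueError("need n > K + 2 complete cases")
    x = sm.add_constant(np.column_stack([w, age]))
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design")
    fit = sm.OLS(y, x).fit()
    return float(fit.rsquared), np.asarray(fit.fittedvalues)


def association_table(weights: np.ndarray, table: pd.DataFrame,
                      age_col: str = "age",
                      measurements: tuple[str, ...] = ("sap_md", "sap_psd",
                                                       "fdt_md", "fdt_psd",
                                                       "mean_cprnflt"),
                      categories: tuple[str, ...] = ("group", "sex"),
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature association screen with Bonferroni flags.

    The family size is (K features) x (quantitative + categorical
    measurements) and is recorded in the output so the correction is
    explicit.
    """
    w = np.asarray(weights, dtype=float)
    n, k = w.shape
    age = table[age_col].to_numpy(dtype=float)
    results: list[AssociationResult] = []
    for j in range(k):
        for meas in measurements:
            results.append(univariate_feature_test(
                w[:, j], table[meas].to_numpy(dtype=float), age,
                feature=j, measurement=meas))
        for cat in categories:
            results.append(categorical_test(
                w[:, j], table[cat].to_numpy(), age,
                feature=j, measurement=cat))
    m = k * (len(measurements) + len(categories))
    pvals = np.array([r.p_value for r in results])
    flags = bonferroni(np.nan_to_num(pvals, nan=1.0), alpha=alpha, m=m)
    for r, f in zip(results, flags):
        r.significant = bool(f) and np.isfinite(r.p_value)
    df = pd.DataFrame([r.as_dict() for r in results])
    df["family_size"] = m
    df["alpha"] = alpha
    return df
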