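"""Progression ground-truthing and baseline prediction.

Ground truth follows a normative-rate construction: a linear mixed-effects
model with participant and eye-within-participant random intercepts and
slopes is fitted to the healthy eyes' longitudinal measurements; the
distribution of per-eye predicted slopes defines the normal ageing rate.
A glaucoma eye whose own ordinary-least-squares rate is faster (in the
worsening direction) than the healthy 95th percentile *and* significantly
different from zero (P < 0.05) is labelled progressing; otherwise stable.

Prediction then asks how well baseline-only information (eigen-feature
weights or a clinical scalar) separates the progressing from the stable
eyes under the same participant-held-out protocol used for detection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .detection import BootstrapAUC, age_controlled_bootstrap_auc, loo_scores

log = logging.getLogger(__name__)

#: slope sign that means worsening, per measurement (all thin/decline)
WORSENING_DIRECTION = {"mean_cprnflt": -1, "sap_md": -1, "fdt_md": -1}


@dataclass
class RateEstimate:
    eye_id: str
    measurement: str
    slope: float          # units / year
    se: float
    p_value: float
    n_visits: int


@dataclass
class HealthyRateDistribution:
    measurement: str
    slopes: np.ndarray            # per healthy eye, units / year
    direction: int                # -1: more negative is worse
    percentile: float = 95.0
    method: str = "ols"           # how per-eye slopes were obtained
    used_ols_fallback: bool = False
    fixed_slope: float = np.nan
    fixed_slope_se: float = np.nan

    @property
    def threshold(self) -> float:
        """Worsening-direction 95th-percentile rate of the healthy eyes."""
        q = 100.0 - self.percentile if self.direction < 0 else self.percentile
        return float(np.percentile(self.slopes, q))


@dataclass
class ProgressionLabel:
    eye_id: str
    measurement: str
    progressing: bool


# ---------------------------------------------------------------------------
# per-eye rates


def eye_rate_ols(visits: pd.DataFrame, measurement: str,
                 eye_id: str = "", time_col: str = "visit_month") -> RateEstimate:
    """OLS slope of a measurement on time in years, with t-test vs zero.

    A perfectly constant series gets slope 0 with p = 1 (no evidence of
    change) rather than an undefined p from the zero residual.
    """
    y = visits[measurement].to_numpy(dtype=float)
    t = visits[time_col].to_numpy(dtype=float) / 12.0
    ok = np.isfinite(y) & np.isfinite(t)
    y, t = y[ok], t[ok]
    if len(y) < 3:
        raise ValueError("need at least 3 visits for a rate estimate")
    res = stats.linregress(t, y)
    slope, se = float(res.slope), float(res.stderr)
    if se == 0.0 or not np.isfinite(se):
        p = 1.0 if slope == 0.0 else 0.0
    else:
        p = float(res.pvalue)
    return RateEstimate(eye_id=eye_id or str(visits.get("eye_id", pd.Series([""])).iloc[0]),
                        measurement=measurement, slope=slope, se=se,
                        p_value=p, n_visits=len(y))


def eye_rates(table: pd.DataFrame, measurement: str,
              min_visits: int = 3) -> list[RateEstimate]:
    """Per-eye OLS rates; eyes with fewer than ``min_visits`` are skipped."""
    out = []
    for eye_id, sub in table.groupby("eye_id"):
        if sub[measurement].notna().sum() < min_visits:
            log.info("eye %s has <%d visits for %s; unclassifiable",
                     eye_id, min_visits, measurement)
            continue
        out.append(eye_rate_ols(sub, measurement, eye_id=str(eye_id)))
    return out


# ---------------------------------------------------------------------------
# healthy normative distribution


def fit_healthy_mixed_model(healthy_visits: pd.DataFrame, measurement: str,
                            percentile: float = 95.0,
                            dist_method: str = "ols") -> HealthyRateDistribution:
    """Normative rate distribution from healthy eyes' longitudinal data.

    Model: measurement ~ intercept + years, with random intercept + slope
    per participant and a variance component for eye nested in participant
    (REML); the fixed slope and its SE describe the population ageing rate.

    The per-eye slope distribution that defines the 95th-percentile
    progression threshold is, by default (``dist_method="ols"``), the set of
    per-eye OLS rate estimates — the same estimator later applied to the
    glaucoma eyes, so the percentile comparison is apples-to-apples and the
    held-out false-positive rate stays at the nominal ~5% (times the
    significance-arm attenuation). ``dist_method="blup"`` instead uses the
    mixed model's shrunken per-eye predicted slopes (fixed + participant +
    eye random slopes); shrinkage narrows that distribution and makes the
    threshold anticonservative against OLS-estimated rates.

    Singular or non-converging fits fall back to per-eye OLS slopes for the
    fixed-effect summary too, flagged on the result.
    """
    if dist_method not in ("ols", "blup"):
        raise ValueError("dist_method must be 'ols' or 'blup'")
    df = healthy_visits.copy()
    if df["eye_id"].nunique() < 10:
        raise ValueError("need at least 10 healthy eyes")
    if df.groupby("eye_id")["visit_month"].count().min() < 3:
        raise ValueError("every healthy eye needs at least 3 visits")
    direction = WORSENING_DIRECTION.get(measurement)
    if direction is None:
        raise ValueError(f"no worsening direction configured for {measurement!r}")
    df["years"] = df["visit_month"].astype(float) / 12.0
    df["value"] = df[measurement].astype(float)
    df = df.dropna(subset=["value"])
    # within-participant eye coding keeps the variance-component design
    # small (2 levels) instead of one column per eye in the study
    df["eye_local"] = df.groupby("participant_id")["eye_id"].transform(
        lambda s: s.astype("category").cat.codes.astype(str))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "value ~ years", df, groups=df["participant_id"],
                re_formula="~years",
                vc_formula={"eye": "0 + C(eye_local)",
                            "eye_slope": "0 + C(eye_local):years"})
            fit = None
            for method in (None, "lbfgs", "powell"):
                kw = {} if method is None else {"method": method}
                candidate = model.fit(reml=True, **kw)
                if candidate.converged:
                    fit = candidate
                    break
        if fit is None:
            raise RuntimeError("mixed model did not converge")
        fixed_slope = float(fit.fe_params["years"])
        fixed_se = float(fit.bse_fe["years"])
        if dist_method == "blup":
            slopes = _per_eye_slopes(fit, df, fixed_slope)
        else:
            slopes = np.array([r.slope for r in eye_rates(df, measurement)])
        return HealthyRateDistribution(
            measurement=measurement, slopes=slopes, direction=direction,
            percentile=percentile, method=dist_method,
            used_ols_fallback=False,
            fixed_slope=fixed_slope, fixed_slope_se=fixed_se)
    except Exception as exc:  # singular fit, convergence failure, ...
        log.warning("mixed model for %s fell back to per-eye OLS (%s)",
                    measurement, exc)
        rates = eye_rates(df.assign(**{measurement: df["value"]}), measurement)
        slopes = np.array([r.slope for r in rates])
        return HealthyRateDistribution(
            measurement=measurement, slopes=slopes, direction=direction,
            percentile=percentile, method="ols", used_ols_fallback=True,
            fixed_slope=float(slopes.mean()),
            fixed_slope_se=float(slopes.std(ddof=1) / np.sqrt(len(slopes))))


def _per_eye_slopes(fit, df: pd.DataFrame, fixed_slope: float) -> np.ndarray:
    """fixed slope + participant random slope + eye random slope, per eye."""
    slopes = []
    sub = df[["participant_id", "eye_id", "eye_local"]].drop_duplicates()
    for _, row in sub.iterrows():
        re = fit.random_effects[row["participant_id"]]
        s = fixed_slope + float(re.get("years", 0.0))
        key = f"eye_slope[C(eye_local)[{row['eye_local']}]:years]"
        if key in re.index:
            s += float(re[key])
        slopes.append(s)
    return np.asarray(slopes)


# ---------------------------------------------------------------------------
# classification


def classify_progression(rate: RateEstimate,
                         dist: HealthyRateDistribution,
                         alpha: float = 0.05) -> ProgressionLabel:
    """Progressing iff the rate is worse than the healthy 95th-percentile
    threshold (strictly, in the worsening direction) and P < alpha."""
    if rate.measurement != dist.measurement:
        raise ValueError("rate and distribution are for different measurements")
    worse = (rate.slope < dist.threshold if dist.direction < 0
             else rate.slope > dist.threshold)
    return ProgressionLabel(eye_id=rate.eye_id, measurement=rate.measurement,
                            progressing=bool(worse and rate.p_value < alpha))


def label_glaucoma_eyes(table: pd.DataFrame, measurement: str,
                        min_visits: int = 3,
                        percentile: float = 95.0) -> pd.DataFrame:
    """End-to-end ground-truthing for one measurement.

    Fits the healthy normative distribution, estimates per-glaucoma-eye OLS
    rates, and returns a per-eye label frame (columns: eye_id, measurement,
    slope, p_value, progressing) plus distribution metadata as attrs.
    """
    healthy = table[table["group"] == "healthy"]
    glaucoma = table[table["group"] == "glaucoma"]
    dist = fit_healthy_mixed_model(healthy, measurement, percentile=percentile)
    rates = eye_rates(glaucoma, measurement, min_visits=min_visits)
    labels = [classify_progression(r, dist) for r in rates]
    out = pd.DataFrame([dict(eye_id=r.eye_id, measurement=measurement,
                             slope=r.slope, p_value=r.p_value,
                             progressing=lab.progressing)
                        for r, lab in zip(rates, labels)])
    out.attrs["threshold"] = dist.threshold
    out.attrs["used_ols_fallback"] = dist.used_ols_fallback
    out.attrs["n_unclassifiable"] = glaucoma["eye_id"].nunique() - len(rates)
    return out


# ---------------------------------------------------------------------------
# baseline-only prediction


@dataclass
class ProgressionPredictionResult:
    measurement: str
    model_id: str
    auc: BootstrapAUC
    n_progressing: int
    n_stable: int
    scores: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


def predict_progression_from_baseline(
        table: pd.DataFrame, stack: np.ndarray, labels: pd.DataFrame,
        model_id: str = "pca10", k: int = 10, n_boot: int = 2000,
        seed: int = 0) -> ProgressionPredictionResult:
    """Participant-held-out prediction of progression from baseline data.

    Restricted to labelled glaucoma eyes. Per fold, the feature chain
    (standardization + PCA) and the logistic model are refit on the training
    participants' baseline scans against their progression labels, then
    score the held-out participant's baselines. Clinical comparators use
    the baseline scalar directly under the identical protocol.
    """
    n_prog = int(labels["progressing"].sum())
    n_stab = int((~labels["progressing"]).sum())
    if n_prog < 2 or n_stab < 2:
        raise ValueError("need at least 2 progressing and 2 stable eyes "
                         f"(got {n_prog} / {n_stab})")
    lab_map = labels.set_index("eye_id")["progressing"]
    m0 = table["visit_month"].min()
    base_mask = ((table["visit_month"] == m0)
                 & (table["group"] == "glaucoma")
                 & table["eye_id"].isin(lab_map.index)).to_numpy()
    sub = table[base_mask].copy()
    sub["group"] = np.where(sub["eye_id"].map(lab_map), "progressing", "stable")
    preds = loo_scores(sub, stack[base_mask] if stack is not None else None,
                       model_id=model_id, k=k, positive="progressing")
    boot = age_controlled_bootstrap_auc(
        preds["score"], preds["label"], preds["age"],
        n_boot=n_boot, seed=seed, groups=preds["participant_id"])
    return ProgressionPredictionResult(
        measurement=str(labels["measurement"].iloc[0]) if len(labels) else "",
        model_id=model_id, auc=boot, n_progressing=n_prog, n_stable=n_stab,
        scores=preds)
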