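"""Glaucoma detection: participant-held-out scoring and AUC comparison.

The leave-one-out protocol removes *all* scans of one participant, refits
the whole feature-learning chain (per-pixel standardization, PCA, logistic
model) on the remainder, then scores the held-out scans — so no participant
ever influences their own features or classifier. Because the diagnostic
groups differ in age, AUCs are estimated with a bootstrap that reweights
the control age distribution to match the cases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .features import fit_pca, project
from .registration import apply_standardization, fit_standardization

log = logging.getLogger(__name__)

CLINICAL_MODELS = ("cprnflt", "sap_md", "fdt_md")
MODEL_COLUMNS = {"cprnflt": "mean_cprnflt", "sap_md": "sap_md",
                 "fdt_md": "fdt_md"}


# ---------------------------------------------------------------------------
# AUC


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_case > score_control) + 1/2 P(tie).

    Equals the trapezoidal area under the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """FPR/TPR coordinates at every score threshold (for plotting export)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order])
    fps = np.cumsum(~labels[order])
    tpr = np.concatenate([[0.0], tps / max(labels.sum(), 1)])
    fpr = np.concatenate([[0.0], fps / max((~labels).sum(), 1)])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


# ---------------------------------------------------------------------------
# age-matched bootstrap


def _control_weights(labels: np.ndarray, ages: np.ndarray,
                     bin_years: float = 5.0) -> np.ndarray:
    """Per-observation resampling weights.

    Controls are weighted by (case age-bin frequency) / (control age-bin
    frequency) so resampled controls match the case age distribution; cases
    keep weight 1. Bins with cases but no controls are merged into the
    nearest control-occupied bin.
    """
    labels = np.asarray(labels).astype(bool)
    ages = np.asarray(ages, dtype=float)
    lo = np.floor(ages.min() / bin_years) * bin_years
    edges = np.arange(lo, ages.max() + bin_years, bin_years)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_years])
    idx = np.clip(np.digitize(ages, edges) - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1
    case_counts = np.bincount(idx[labels], minlength=n_bins).astype(float)
    ctrl_counts = np.bincount(idx[~labels], minlength=n_bins).astype(float)

    occupied = np.flatnonzero(ctrl_counts > 0)
    if occupied.size == 0:
        raise ValueError("no controls available")
    for b in np.flatnonzero((case_counts > 0) & (ctrl_counts == 0)):
        nearest = occupied[np.argmin(np.abs(occupied - b))]
        log.info("age bin %d has cases but no controls; merged into bin %d",
                 b, nearest)
        case_counts[nearest] += case_counts[b]
        case_counts[b] = 0.0

    case_freq = case_counts / case_counts.sum()
    ctrl_freq = ctrl_counts / ctrl_counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ctrl_freq > 0, case_freq / ctrl_freq, 0.0)
    weights = np.ones(len(ages))
    weights[~labels] = ratio[idx[~labels]]
    return weights


class _GroupSampler:
    """Participant-level resampler for the age-controlled bootstrap.

    Case groups are drawn uniformly; control groups with probability
    proportional to their (age-matching) weight. Groups are participants by
    default so the two eyes / repeated visits of one person move together.
    """

    def __init__(self, labels, weights, groups):
        labels = np.asarray(labels).astype(bool)
        groups = np.asarray(groups)
        self.case_members: list[np.ndarray] = []
        self.ctrl_members: list[np.ndarray] = []
        ctrl_w = []
        for g in pd.unique(groups):
            sel = groups == g
            case_sel = sel & labels
            ctrl_sel = sel & ~labels
            if case_sel.any():
                self.case_members.append(np.flatnonzero(case_sel))
            if ctrl_sel.any():
                self.ctrl_members.append(np.flatnonzero(ctrl_sel))
                ctrl_w.append(weights[ctrl_sel].mean())
        w = np.asarray(ctrl_w, dtype=float)
        self.ctrl_probs = w / w.sum() if w.sum() > 0 else None

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        nc, nh = len(self.case_members), len(self.ctrl_members)
        picks = [self.case_members[i]
                 for i in rng.integers(0, nc, size=nc)]
        picks += [self.ctrl_members[i]
                  for i in rng.choice(nh, size=nh, replace=True,
                                      p=self.ctrl_probs)]
        return np.concatenate(picks)


@dataclass
class BootstrapAUC:
    auc: float
    ci: tuple[float, float]
    replicates: np.ndarray
    n_boot: int
    seed: int


def age_controlled_bootstrap_auc(scores, labels, ages, n_boot: int = 2000,
                                 seed: int = 0, groups=None,
                                 bin_years: float = 5.0) -> BootstrapAUC:
    """Bootstrap AUC with control resampling reweighted to the case ages."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    ages = np.asarray(ages, dtype=float)
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    if groups is None:
        groups = np.arange(len(scores))
    rng = np.random.default_rng(seed)
    weights = _control_weights(labels, ages, bin_years)
    sampler = _GroupSampler(labels, weights, groups)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = sampler.sample(rng)
        if labels[idx].all() or not labels[idx].any():
            reps[b] = np.nan
            continue
        reps[b] = auc(scores[idx], labels[idx])
    reps = reps[np.isfinite(reps)]
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BootstrapAUC(auc=float(reps.mean()), ci=(float(lo), float(hi)),
                        replicates=reps, n_boot=n_boot, seed=seed)


@dataclass
class AUCComparison:
    auc_a: float
    auc_b: float
    delta: float
    p_value: float
    n_boot: int
    seed: int


def compare_auc(scores_a, scores_b, labels, ages, n_boot: int = 2000,
                seed: int = 0, groups=None,
                bin_years: float = 5.0) -> AUCComparison:
    """Paired age-controlled bootstrap test of AUC_a - AUC_b.

    Both score vectors must be aligned on the same scans; each replicate
    resamples once and evaluates both models on the identical resample, so
    the difference distribution reflects paired uncertainty.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    ages = np.asarray(ages, dtype=float)
    if not (len(a) == len(b) == len(labels) == len(ages)):
        raise ValueError("paired inputs must share length")
    if groups is None:
        groups = np.arange(len(a))
    rng = np.random.default_rng(seed)
    weights = _control_weights(labels, ages, bin_years)
    sampler = _GroupSampler(labels, weights, groups)
    deltas = np.empty(n_boot)
    auc_as = np.empty(n_boot)
    auc_bs = np.empty(n_boot)
    for i in range(n_boot):
        idx = sampler.sample(rng)
        if labels[idx].all() or not labels[idx].any():
            deltas[i] = auc_as[i] = auc_bs[i] = np.nan
            continue
        auc_as[i] = auc(a[idx], labels[idx])
        auc_bs[i] = auc(b[idx], labels[idx])
        deltas[i] = auc_as[i] - auc_bs[i]
    ok = np.isfinite(deltas)
    deltas = deltas[ok]
    n = len(deltas)
    p_lo = (np.sum(deltas <= 0) + 1) / (n + 1)
    p_hi = (np.sum(deltas >= 0) + 1) / (n + 1)
    p = min(1.0, 2.0 * min(p_lo, p_hi))
    return AUCComparison(auc_a=float(np.nanmean(auc_as)),
                         auc_b=float(np.nanmean(auc_bs)),
                         delta=float(deltas.mean()), p_value=float(p),
                         n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# leave-one-participant-out scoring


def _fit_logistic(x: np.ndarray, y: np.ndarray) -> tuple[LogisticRegression, bool]:
    """Unpenalized fit; ridge-stabilized refit (flagged) on non-convergence
    or separation-driven blow-up."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(C=np.inf, max_iter=1000)
            clf.fit(x, y)
            return clf, False
        except (ConvergenceWarning, Exception):
            pass
    clf = LogisticRegression(C=1.0, max_iter=1000)
    clf.fit(x, y)
    return clf, True


def loo_scores(table: pd.DataFrame, stack: np.ndarray | None = None,
               model_id: str = "pca10", k: int = 10,
               label_col: str = "group",
               positive: str = "glaucoma") -> pd.DataFrame:
    """Held-out glaucoma probabilities under participant-based LOO.

    ``model_id="pca10"`` refits standardization + PCA (``k`` components) +
    logistic regression per fold on the registered map ``stack`` (rows
    aligned with ``table``). The clinical comparators ("cprnflt", "sap_md",
    "fdt_md") are single-predictor logistic fits under the identical
    protocol; their held-out scores are monotone in the raw measurement, so
    AUCs match using the raw values directly.

    Returns a DataFrame with scan_id, participant_id, eye_id, visit_month,
    age, label, score, ridge_flag.
    """
    if model_id == "pca10" and stack is None:
        raise ValueError("pca10 scoring needs the registered map stack")
    if model_id != "pca10" and model_id not in MODEL_COLUMNS:
        raise ValueError(f"unknown model_id {model_id!r}")
    y_all = (table[label_col].to_numpy() == positive).astype(int)
    pids = table["participant_id"].to_numpy()
    classes_of = {p: y_all[pids == p].max() for p in pd.unique(pids)}
    if sum(classes_of.values()) < 2 or sum(1 - v for v in classes_of.values()) < 2:
        raise ValueError("need at least 2 participants per class")

    scores = np.full(len(table), np.nan)
    ridge_flags = np.zeros(len(table), dtype=bool)
    for pid in pd.unique(pids):
        test = pids == pid
        train = ~test
        y_tr = y_all[train]
        if model_id == "pca10":
            std = fit_standardization(stack[train])
            z_tr = apply_standardization(stack[train], std)
            model = fit_pca(z_tr, k=min(k, train.sum() - 1))
            x_tr = project(z_tr, model)
            z_te = apply_standardization(stack[test], std)
            x_te = project(z_te, model)
        else:
            col = table[MODEL_COLUMNS[model_id]].to_numpy(dtype=float)
            x_tr = col[train].reshape(-1, 1)
            x_te = col[test].reshape(-1, 1)
        clf, ridge = _fit_logistic(x_tr, y_tr)
        scores[test] = clf.predict_proba(np.atleast_2d(x_te))[:, 1]
        ridge_flags[test] = ridge
        if ridge:
            log.debug("fold %s used ridge-stabilized logistic fit", pid)

    out = table[["scan_id", "participant_id", "eye_id", "visit_month",
                 "age"]].copy()
    out["label"] = y_all
    out["score"] = scores
    out["model"] = model_id
    out["ridge_flag"] = ridge_flags
    return out.reset_index(drop=True)
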