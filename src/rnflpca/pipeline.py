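"""End-to-end orchestration: simulate -> register -> features ->
associations -> detection -> progression, with machine-readable outputs.

Every figure is a rendering of a table that is also written as CSV, and all
randomness descends from the config seed, so a run is reproducible and
auditable from its output directory alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import associations as assoc
from . import detection as det
from . import progression as prog
from .config import CohortConfig
from .features import feature_change_map, fit_pca, project
from .maps import ThicknessMap, load_npz
from .registration import apply_standardization, fit_standardization, register_scans
from .simulate import Cohort, generate_cohort, read_cohort_csv, write_cohort_csv

log = logging.getLogger(__name__)

STAGES = ("simulate", "register", "features", "associate", "detect", "progress")
PROGRESSION_MEASUREMENTS = ("mean_cprnflt", "sap_md", "fdt_md")


def load_cohort(csv_path: str | Path, maps_dir: str | Path,
                config: CohortConfig) -> Cohort:
    """Data mode: cohort metadata CSV plus NPZ thickness maps.

    Maps are looked up as ``<maps_dir>/<scan_id>.npz`` unless the table has
    a ``map_path`` column.
    """
    table = read_cohort_csv(csv_path)
    maps_dir = Path(maps_dir)
    maps: dict[str, ThicknessMap] = {}
    errors = []
    for _, row in table.iterrows():
        sid = row.get("scan_id") or f"{row['eye_id']}_m{row['visit_month']:g}"
        path = Path(row["map_path"]) if "map_path" in table.columns else \
            maps_dir / f"{sid}.npz"
        if not path.exists():
            errors.append(f"missing map file {path}")
            continue
        maps[str(sid)] = load_npz(path)
    if errors:
        raise FileNotFoundError("; ".join(errors[:10]))
    if "scan_id" not in table.columns:
        table["scan_id"] = [f"{e}_m{m:g}" for e, m in
                            zip(table["eye_id"], table["visit_month"])]
    return Cohort(table=table, maps=maps, config=config)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def run_pipeline(config: CohortConfig, out_dir: str | Path,
                 stages: tuple[str, ...] = STAGES,
                 cohort: Cohort | None = None,
                 save_figures: bool = True) -> dict:
    """Run the requested stages and write ``report.json`` plus artifacts.

    Returns the report dictionary. Stage failures that reflect data limits
    (e.g. too few visits for progression) are recorded in the report instead
    of aborting the run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    report: dict = {"config": _round_floats(vars(cfg).copy()),
                    "seed": cfg.seed, "stages": {}}

    # ---- simulate ---------------------------------------------------------
    if cohort is None:
        cohort, truth = generate_cohort(cfg)
        write_cohort_csv(cohort, out / "cohort.csv")
        truth.eyes.to_csv(out / "ground_truth_eyes.csv", index=False)
        report["stages"]["simulate"] = {
            "n_participants": int(cohort.table["participant_id"].nunique()),
            "n_eyes": int(cohort.table["eye_id"].nunique()),
            "n_scans": int(len(cohort.table)),
            "n_glaucoma_eyes": int(cohort.table.loc[
                cohort.table.group == "glaucoma", "eye_id"].nunique()),
            "n_healthy_eyes": int(cohort.table.loc[
                cohort.table.group == "healthy", "eye_id"].nunique()),
        }
    table = cohort.table
    scan_order = table["scan_id"].tolist()
    maps = [cohort.maps[s] for s in scan_order]

    stack = None
    if {"register", "features", "associate", "detect", "progress"} & set(stages):
        stack, records = register_scans(maps)
        n_fail = sum(0 if r.converged else 1 for r in records)
        report["stages"]["register"] = {
            "n_registered": len(records),
            "n_ecc_fallback": n_fail,
            # scans whose ECC refinement was rejected keep their landmark
            # alignment; none are dropped, but each fallback is listed
            "fallbacks": [{"scan_id": r.scan_id, "reason": "ecc_nonconverged"}
                          for r in records if not r.converged],
            "exclusions": [],
        }

    model = None
    if {"features", "associate", "detect", "progress"} & set(stages):
        std = fit_standardization(stack)
        zstack = apply_standardization(stack, std)
        k = min(cfg.n_components, len(maps) - 1)
        model = fit_pca(zstack, k=k)
        vf = pd.DataFrame({"component": np.arange(1, k + 1),
                           "variance_fraction": model.variance_fraction})
        vf.to_csv(out / "variance_explained.csv", index=False)
        report["stages"]["features"] = {
            "k": k,
            "variance_fraction": model.variance_fraction.tolist(),
            "cumulative_variance": float(model.variance_fraction.sum()),
        }
        if save_figures:
            _plot_variance(vf, out / "variance_explained.png")
            _plot_components(model, out / "components.png")
            _plot_change_masks(model, out / "change_masks.png")

    if "associate" in stages:
        base = cohort.baseline()
        base_idx = [scan_order.index(s) for s in base["scan_id"]]
        w_base = project(zstack[base_idx], model)
        tab = assoc.association_table(w_base, base)
        tab.to_csv(out / "associations.csv", index=False)
        r2 = {}
        for meas in PROGRESSION_MEASUREMENTS:
            r2[meas], fitted = assoc.multivariate_r2(
                w_base, base[meas].to_numpy(float), base["age"].to_numpy(float))
            if save_figures:
                _plot_scatter(base[meas].to_numpy(float), fitted, meas,
                              r2[meas], out / f"predicted_{meas}.png")
        report["stages"]["associate"] = {
            "n_baseline_rows": int(len(base)),
            "family_size": int(tab["family_size"].iloc[0]),
            "n_significant": int(tab["significant"].sum()),
            "multivariate_r2": r2,
        }

    if "detect" in stages:
        report["stages"]["detect"] = _detect_stage(
            cfg, table, stack, out, save_figures)

    if "progress" in stages:
        try:
            report["stages"]["progress"] = _progress_stage(
                cfg, table, stack, scan_order, out)
        except ValueError as exc:
            report["stages"]["progress"] = {"error": f"insufficient data: {exc}"}

    with open(out / "report.json", "w") as fh:
        json.dump(_round_floats(report), fh, indent=2, sort_keys=True)
    return report


def _detect_stage(cfg, table, stack, out: Path, save_figures: bool) -> dict:
    results = {}
    preds = {}
    for model_id in ("pca10",) + det.CLINICAL_MODELS:
        p = det.loo_scores(table, stack if model_id == "pca10" else None,
                           model_id=model_id, k=cfg.n_components)
        score = p["score"].to_numpy()
        boot = det.age_controlled_bootstrap_auc(
            score, p["label"], p["age"], n_boot=cfg.n_boot, seed=cfg.seed,
            groups=p["participant_id"])
        preds[model_id] = p
        results[model_id] = {"auc": boot.auc, "ci": list(boot.ci)}
        det.roc_curve_points(score, p["label"]).to_csv(
            out / f"roc_detection_{model_id}.csv", index=False)
    comparisons = {}
    base = preds["pca10"]
    for model_id in det.CLINICAL_MODELS:
        cmp_res = det.compare_auc(
            base["score"], preds[model_id]["score"], base["label"],
            base["age"], n_boot=cfg.n_boot, seed=cfg.seed,
            groups=base["participant_id"])
        comparisons[f"pca10_vs_{model_id}"] = {
            "delta": cmp_res.delta, "p_value": cmp_res.p_value}
    rows = [{"model": m, **v} for m, v in results.items()]
    pd.DataFrame(rows).to_csv(out / "detection_auc.csv", index=False)
    if save_figures:
        _plot_roc(preds, out / "roc_detection.png")
    return {"auc": results, "comparisons": comparisons}


def _progress_stage(cfg, table, stack, scan_order, out: Path) -> dict:
    if cfg.n_visits < 3:
        raise ValueError("progression ground truth needs >= 3 visits")
    stage: dict = {"labels": {}, "prediction": {}}
    label_rows = []
    for meas in PROGRESSION_MEASUREMENTS:
        labels = prog.label_glaucoma_eyes(table, meas)
        label_rows.append(labels)
        stage["labels"][meas] = {
            "n_progressing": int(labels["progressing"].sum()),
            "n_eyes": int(len(labels)),
            "threshold": labels.attrs["threshold"],
            "used_ols_fallback": bool(labels.attrs["used_ols_fallback"]),
            "n_unclassifiable": int(labels.attrs["n_unclassifiable"]),
        }
        per_model = {}
        for model_id in ("pca10",) + det.CLINICAL_MODELS:
            try:
                res = prog.predict_progression_from_baseline(
                    table, stack, labels, model_id=model_id,
                    k=cfg.n_components, n_boot=cfg.n_boot, seed=cfg.seed)
                per_model[model_id] = {"auc": res.auc.auc,
                                       "ci": list(res.auc.ci)}
            except ValueError as exc:
                per_model[model_id] = {"error": str(exc)}
        stage["prediction"][meas] = per_model
    pd.concat(label_rows).to_csv(out / "progression_labels.csv", index=False)
    return stage


# ---------------------------------------------------------------------------
# figures (all renderings of tables written above)


def _plot_variance(vf: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(vf["component"], 100 * vf["variance_fraction"])
    ax.set_xlabel("feature")
    ax.set_ylabel("% variance explained")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_components(model, path: Path) -> None:
    k = model.k
    cols = min(5, k)
    rows = int(np.ceil(k / cols))
    fig, axes = plt.subplots(rows, cols, figsize=(2.2 * cols, 1.8 * rows))
    for i, ax in enumerate(np.atleast_1d(axes).ravel()):
        ax.axis("off")
        if i < k:
            ax.imshow(model.components[i], cmap="RdBu_r")
            ax.set_title(f"feature {i + 1}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_change_masks(model, path: Path, quantile: float = 0.9) -> None:
    k = model.k
    cols = min(5, k)
    rows = int(np.ceil(k / cols))
    fig, axes = plt.subplots(rows, cols, figsize=(2.2 * cols, 1.8 * rows))
    for i, ax in enumerate(np.atleast_1d(axes).ravel()):
        ax.axis("off")
        if i < k:
            ax.imshow(feature_change_map(model, i, quantile), cmap="gray")
            ax.set_title(f"feature {i + 1} mask", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_scatter(y, fitted, meas: str, r2: float, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(y[: len(fitted)], fitted, s=8, alpha=0.6)
    ax.set_xlabel(f"measured {meas}")
    ax.set_ylabel("predicted from features + age")
    ax.set_title(f"R² = {r2:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _plot_roc(preds: dict, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for model_id, p in preds.items():
        pts = det.roc_curve_points(p["score"].to_numpy(), p["label"])
        a = det.auc(p["score"], p["label"])
        ax.plot(pts["fpr"], pts["tpr"], label=f"{model_id} (AUC {a:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
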