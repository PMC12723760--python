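"""End-to-end pipeline orchestration.

Wires the stages into the full analysis: simulate (optional) -> read ->
preprocess -> model-grid selection -> posterior classification ->
descriptive summary -> class trajectories -> cross-validated baseline-only
prediction -> class-specific trial power -> classification tree.  Every
artifact is written under one run directory together with a
machine-readable manifest (input hashes, seeds, package version) and a
human-readable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import pacctraj
from pacctraj.cohort import (
    CohortData,
    read_cohort,
    summarize_by_class,
    write_cohort,
)
from pacctraj.evaluate import classification_metrics, cross_validate, make_folds
from pacctraj.lcmm import (
    LcmmFit,
    LcmmSpec,
    build_model_data,
    class_trajectories,
    fit_lcmm,
    select_model,
)
from pacctraj.power import group_summaries_from_fit, power_table
from pacctraj.simulate import preset_a4learn_like, simulate_cohort

log = logging.getLogger("pacctraj")

TREE_FEATURES = [
    "active_treatment",
    "ptau217",
    "amyloid_centiloid",
    "apoe4_carrier",
    "sex_female",
    "age",
    "education",
    "hipp_atrophy_z",
    "baseline_pacc",
]


@dataclass
class PipelineConfig:
    """Everything one run needs; serializes to/from YAML unchanged."""

    out_dir: str = "run"
    # inputs: either CSV paths or a synthetic preset
    visits_path: str | None = None
    baseline_path: str | None = None
    simulate_preset: str | None = "a4learn"
    n_subjects: int = 400
    seed: int = 20260121
    # model
    G_grid: tuple = (1, 2, 3)
    df_grid: tuple = (1, 2, 3)
    n_starts: int = 5
    fit_seed: int = 1
    use_known_transform: bool = True  # synthetic runs: reuse generating Box-Cox
    # cross-validation
    cv_folds: int = 10
    cv_seed: int = 17
    cv_n_starts: int = 2
    # power
    n_per_arm: int = 500
    attrition: dict = field(default_factory=lambda: {2.0: 0.10, 4.0: 0.20})
    # tree
    tree_seed: int = 23
    resume: bool = False
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)

    def to_yaml(self, path):
        d = asdict(self)
        d["G_grid"] = list(self.G_grid)
        d["df_grid"] = list(self.df_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    With ``config.resume`` set, stages whose outputs already exist are
    reloaded instead of recomputed.  Any stage failure leaves earlier
    artifacts in place and records the failure point in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), 20))
    manifest = {
        "version": pacctraj.__version__,
        "seeds": {
            "simulate": config.seed,
            "fit": config.fit_seed,
            "cv": config.cv_seed,
            "tree": config.tree_seed,
        },
        "stages": {},
        "hashes": {},
    }
    config.to_yaml(out / "config.yaml")

    def stage(name):
        log.info("=== stage: %s ===", name)
        manifest["stages"][name] = {"status": "running", "t0": time.time()}

    def done(name, *artifacts):
        rec = manifest["stages"][name]
        rec["status"] = "done"
        rec["seconds"] = round(time.time() - rec.pop("t0"), 2)
        for a in artifacts:
            manifest["hashes"][a.name] = _sha256(a)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        # ------------------------------------------------------ inputs
        stage("data")
        truth = None
        vpath, bpath = out / "visits.csv", out / "baseline.csv"
        if config.visits_path:
            cohort = read_cohort(config.visits_path, config.baseline_path)
        elif config.resume and vpath.exists() and bpath.exists():
            cohort = read_cohort(vpath, bpath)
            truth = preset_a4learn_like(config.n_subjects, config.seed)
        else:
            truth = preset_a4learn_like(config.n_subjects, config.seed)
            cohort, true_class = simulate_cohort(truth)
            write_cohort(cohort, vpath, bpath)
            truth.to_json(out / "truth.json")
            pd.Series(true_class, name="true_class").rename_axis(
                "subject_id"
            ).to_csv(out / "true_classes.csv")
        done("data", vpath, bpath) if not config.visits_path else done("data")

        boxcox = (
            truth.boxcox
            if (truth is not None and config.use_known_transform)
            else "fit"
        )

        # ------------------------------------------------------ selection
        stage("select_model")
        fit_path = out / "fit.json"
        sel_path = out / "selection.csv"
        if config.resume and fit_path.exists() and sel_path.exists():
            best = LcmmFit.from_json(fit_path)
            md = build_model_data(
                cohort,
                best.spec,
                boxcox=best.boxcox,
                spline=best.spline,
                scalers=(best.w_scaler, best.xm_scaler),
                atrophy_fit=best.atrophy_fit,
            )
            from pacctraj.lcmm import posterior_matrix

            best.posterior = posterior_matrix(md, best.params)
            best.subject_ids = md.subject_ids
            selection = pd.read_csv(sel_path)
        else:
            best, selection = select_model(
                cohort,
                df_grid=config.df_grid,
                G_grid=config.G_grid,
                n_starts=config.n_starts,
                seed=config.fit_seed,
                boxcox=boxcox,
            )
            md = build_model_data(
                cohort,
                best.spec,
                boxcox=best.boxcox,
                spline=best.spline,
                scalers=(best.w_scaler, best.xm_scaler),
                atrophy_fit=best.atrophy_fit,
            )
            selection.to_csv(sel_path, index=False)
            best.to_json(fit_path)
            best.posterior_table().to_csv(out / "posterior.csv", index=False)
        log.info(
            "selected G=%d, spline df=%d (BIC %.1f)",
            best.spec.n_classes,
            best.spec.spline_df,
            best.bic,
        )
        done("select_model", sel_path, fit_path)

        labels = best.class_labels

        # ------------------------------------------------------ summary
        stage("summary")
        summary = summarize_by_class(cohort, labels)
        summary.continuous.to_csv(out / "table1_continuous.csv", index=False)
        summary.categorical.to_csv(out / "table1_categorical.csv", index=False)
        (out / "table1.txt").write_text(summary.to_text())
        done("summary", out / "table1_continuous.csv")

        # ------------------------------------------------------ trajectories
        stage("trajectories")
        grid = np.linspace(0.0, min(6.0, best.spline.boundary_knots[1]), 25)
        trajs = class_trajectories(best, grid, md=md)
        rows = []
        for tr in trajs:
            for i, t in enumerate(tr.times):
                rows.append(
                    {
                        "class": tr.class_name,
                        "time_years": t,
                        "mean_pacc": tr.mean[i],
                        "ci_low": None if tr.ci_low is None else tr.ci_low[i],
                        "ci_high": None if tr.ci_high is None else tr.ci_high[i],
                    }
                )
        traj_df = pd.DataFrame(rows)
        traj_df.to_csv(out / "trajectories.csv", index=False)
        _plot_trajectories(traj_df, out / "trajectories.png")
        done("trajectories", out / "trajectories.csv")

        # ------------------------------------------------------ cross-validation
        stage("cross_validation")
        ptau = dict(zip(cohort.baseline.subject_id, cohort.baseline.ptau217))
        folds = make_folds(labels, ptau, K=config.cv_folds, seed=config.cv_seed)
        preds, meta = cross_validate(
            cohort,
            best.spec,
            folds,
            best,
            n_starts=config.cv_n_starts,
            seed=config.cv_seed,
            boxcox=boxcox,
        )
        preds["truth"] = preds["subject_id"].map(labels)
        preds.to_csv(out / "cv_predictions.csv", index=False)
        pred_map = dict(zip(preds.subject_id, preds.predicted))
        metrics = classification_metrics(
            pred_map, {s: labels[s] for s in pred_map}, probabilities=preds
        )
        cv_json = {
            "accuracy": metrics["accuracy"],
            "accuracy_ci": metrics["accuracy_ci"],
            "balanced_accuracy": metrics["balanced_accuracy"],
            "auprc_per_class": {
                str(k): v for k, v in metrics.get("auprc_per_class", {}).items()
            },
            "auprc_any_decliner": metrics.get("auprc_any_decliner"),
            "n": metrics["n"],
        }
        (out / "cv_metrics.json").write_text(json.dumps(cv_json, indent=2))
        done("cross_validation", out / "cv_predictions.csv")

        # ------------------------------------------------------ power
        stage("power")
        present = np.isin(cohort.baseline["subject_id"], best.subject_ids)
        bl = cohort.baseline[present].reset_index(drop=True)
        hard = best.posterior.argmax(axis=1)
        apos = (bl["arm"] != "LEARN").to_numpy()
        masks = {
            "amyloid_negative_stable": (~apos) & (hard == 0),
            "amyloid_positive_stable": apos & (hard == 0),
            "amyloid_positive_decliner": apos & (hard > 0),
        }
        masks = {k: v for k, v in masks.items() if v.sum() >= 10}
        ptable = pd.DataFrame()
        if "amyloid_negative_stable" in masks and len(masks) > 1:
            summaries = group_summaries_from_fit(best, md, masks)
            ptable = power_table(
                summaries,
                reference_group="amyloid_negative_stable",
                n_per_arm=config.n_per_arm,
                attrition_by_horizon=config.attrition,
            )
        ptable.to_csv(out / "power.csv", index=False)
        done("power", out / "power.csv")

        # ------------------------------------------------------ tree
        stage("tree")
        from pacctraj.tree import tune_tree

        feats = _tree_features(cohort, best)
        y = np.array([labels[s] for s in feats.index])
        cp, tree_model, cp_table = tune_tree(
            feats.reset_index(drop=True), y, seed=config.tree_seed
        )
        cp_table.to_csv(out / "tree_cv.csv", index=False)
        tree_model.to_json(out / "tree.json")
        (out / "tree.txt").write_text(tree_model.to_text())
        tree_model.variable_importance().rename("importance_pct").rename_axis(
            "variable"
        ).to_csv(out / "tree_importance.csv")
        done("tree", out / "tree.json")

        # ------------------------------------------------------ report
        stage("report")
        render_report(out)
        done("report", out / "report.txt")
    except Exception as exc:  # pragma: no cover - failure bookkeeping
        name = next(
            (
                k
                for k, v in manifest["stages"].items()
                if v.get("status") == "running"
            ),
            "unknown",
        )
        manifest["stages"][name] = {"status": "failed", "error": repr(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    return out


def _tree_features(cohort: CohortData, fit: LcmmFit) -> pd.DataFrame:
    """Baseline predictor table for the classification tree (complete-case)."""
    bl = cohort.baseline.set_index("subject_id").loc[list(fit.subject_ids)].copy()
    if fit.atrophy_fit is not None:
        b0, b1, mean, sd = fit.atrophy_fit
        bl["hipp_atrophy_z"] = -(
            (bl["hippocampal_volume"] - b0 - b1 * bl["icv"]) - mean
        ) / sd
    first = cohort.visits.groupby("subject_id", sort=False).first()
    bl["baseline_pacc"] = first["pacc"]
    cols = [c for c in TREE_FEATURES if c in bl.columns]
    return bl[cols].dropna()


def _plot_trajectories(traj_df: pd.DataFrame, path: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, grp in traj_df.groupby("class"):
        (line,) = ax.plot(grp["time_years"], grp["mean_pacc"], label=name)
        if grp["ci_low"].notna().any():
            ax.fill_between(
                grp["time_years"],
                grp["ci_low"],
                grp["ci_high"],
                alpha=0.2,
                color=line.get_color(),
            )
    ax.set_xlabel("years since baseline")
    ax.set_ylabel("PACC")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_report(run_dir) -> str:
    """Human-readable summary assembled from the run artifacts."""
    run_dir = Path(run_dir)
    lines = ["pacctraj pipeline report", "=" * 30, ""]
    sel = pd.read_csv(run_dir / "selection.csv")
    best = sel[sel["selected"]].iloc[0]
    lines.append(
        f"Model selection: G={int(best['G'])}, spline df={int(best['spline_df'])}"
        f" (BIC {best['BIC']:.1f}, ICL {best['ICL']:.1f})"
    )
    post = pd.read_csv(run_dir / "posterior.csv") if (run_dir / "posterior.csv").exists() else None
    if post is not None:
        props = post["class"].value_counts(normalize=True).sort_index()
        lines.append(
            "Class proportions: "
            + ", ".join(f"class {c + 1}: {p:.1%}" for c, p in props.items())
        )
        tau_cols = [c for c in post.columns if c.startswith("tau_")]
        conf = post[tau_cols].max(axis=1).mean()
        lines.append(f"Mean posterior confidence: {conf:.2f}")
    if (run_dir / "cv_metrics.json").exists():
        cv = json.loads((run_dir / "cv_metrics.json").read_text())
        lines.append(
            f"Cross-validated accuracy: {cv['accuracy']:.3f} "
            f"(95% CI {cv['accuracy_ci'][0]:.3f}-{cv['accuracy_ci'][1]:.3f})"
        )
        if cv.get("auprc_per_class"):
            lines.append(
                "One-vs-rest AUPRC: "
                + ", ".join(f"{k}: {v:.2f}" for k, v in cv["auprc_per_class"].items())
            )
    if (run_dir / "power.csv").exists():
        ptab = pd.read_csv(run_dir / "power.csv")
        if len(ptab):
            lines.append("")
            lines.append("Trial power (by group, horizon, effect fraction):")
            for _, r in ptab.iterrows():
                lines.append(
                    f"  {r['group']:28s} {r['horizon_years']:.0f}y "
                    f"f={r['effect_fraction']:.1f}: power {r['power']:.2f}"
                )
    if (run_dir / "tree_importance.csv").exists():
        imp = pd.read_csv(run_dir / "tree_importance.csv")
        if len(imp):
            lines.append("")
            lines.append("Tree variable importance (%):")
            for _, r in imp.head(6).iterrows():
                lines.append(f"  {r['variable']:20s} {r['importance_pct']:.1f}")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
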