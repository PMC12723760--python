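"""Prospective discrimination of latent classes.

Stratified ten-fold cross-validation with per-fold refitting of the LCMM
(including per-fold refits of the Box-Cox transform, spline knots, atrophy
residualization and covariate scaling — no information flows from held-out
subjects into training), baseline-only class prediction, precision-recall
curves with average-precision AUPRC, accuracy metrics, and cross-model
classification agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import norm

from pacctraj.cohort import CohortData
from pacctraj.errors import SpecificationError, ValidationError
from pacctraj.lcmm import (
    LcmmFit,
    LcmmSpec,
    build_model_data,
    fit_lcmm,
    class_trajectories,
)
from pacctraj.mnl import mnl_probs


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    """Partition of subjects into K folds, stratified on class x biomarker."""

    fold: dict  # subject_id -> fold index (0..K-1)
    K: int
    strata: dict  # subject_id -> stratum label

    def subjects_in_fold(self, k):
        return [s for s, f in self.fold.items() if f == k]


def stratified_folds(labels: dict, K: int, seed: int, strata: dict | None = None):
    """Round-robin fold assignment after a seeded shuffle within strata.

    ``labels`` maps subject to any stratum-defining label; if ``strata`` is
    given it overrides.  Within each stratum, fold sizes differ by at most
    one; a stratum with fewer members than K simply occupies that many
    distinct folds.
    """
    if K < 2:
        raise SpecificationError("need K >= 2 folds")
    strata = strata if strata is not None else labels
    rng = np.random.default_rng(seed)
    by_stratum = {}
    for sid in sorted(strata):
        by_stratum.setdefault(strata[sid], []).append(sid)
    fold = {}
    offset = 0
    for key in sorted(by_stratum, key=str):
        members = by_stratum[key]
        order = rng.permutation(len(members))
        for j, idx in enumerate(order):
            fold[members[idx]] = (offset + j) % K
        offset += len(members)  # stagger strata so small strata spread out
    return FoldAssignment(fold=fold, K=K, strata=dict(strata))


def make_folds(labels: dict, ptau: dict, K: int = 10, seed: int = 0) -> FoldAssignment:
    """Folds stratified by latent class crossed with P-tau217 tertile.

    Tertiles are computed over the full sample (a stratification variable,
    not a fitted quantity).
    """
    sids = sorted(labels)
    vals = np.array([ptau[s] for s in sids], dtype=float)
    cuts = np.quantile(vals[np.isfinite(vals)], [1 / 3, 2 / 3])
    tert = np.searchsorted(cuts, vals)
    strata = {s: (labels[s], int(t)) for s, t in zip(sids, tert)}
    return stratified_folds(labels, K=K, seed=seed, strata=strata)


# ---------------------------------------------------------------------------
# baseline-only prediction
# ---------------------------------------------------------------------------

def predict_class_baseline(
    fit: LcmmFit, cohort: CohortData, use_baseline_outcome: bool = True
) -> pd.DataFrame:
    """Class probabilities for subjects using only their baseline data.

    Combines the membership prior pi_g(x) with the Gaussian density of the
    single baseline outcome under each class (one visit at t = 0, marginal
    variance sigma_b^2 + sigma_e^2).  With
    ``use_baseline_outcome=False`` only the membership prior is returned.
    All transforms (Box-Cox, spline knots, atrophy residualization,
    covariate scaling) are the ones stored in ``fit``.
    """
    md = build_model_data(
        cohort,
        fit.spec,
        boxcox=fit.boxcox,
        spline=fit.spline,
        scalers=(fit.w_scaler, fit.xm_scaler),
        atrophy_fit=fit.atrophy_fit,
    )
    G = fit.spec.n_classes
    pi = (
        np.ones((md.n_subjects, 1))
        if G == 1
        else mnl_probs(fit.zeta, md.Xm)
    )
    if use_baseline_outcome:
        first = md.starts  # index of each subject's first (t=0) observation
        y0 = md.y[first]
        S0 = md.S[first]
        W0 = md.W[first]
        mu0 = S0 @ fit.alpha.T + (W0 @ fit.gamma)[:, None]
        var0 = fit.sigma_b**2 + fit.sigma_e**2
        logphi = -0.5 * (np.log(2 * np.pi * var0) + (y0[:, None] - mu0) ** 2 / var0)
        a = np.log(np.clip(pi, 1e-300, None)) + logphi
        a -= a.max(axis=1, keepdims=True)
        post = np.exp(a)
        post /= post.sum(axis=1, keepdims=True)
    else:
        post = pi
    out = pd.DataFrame(post, columns=[f"p_class{g + 1}" for g in range(G)])
    out.insert(0, "subject_id", md.subject_ids)
    out["predicted"] = post.argmax(axis=1)
    return out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def align_classes(fit: LcmmFit, reference: LcmmFit, n_grid: int = 13) -> np.ndarray:
    """Permutation mapping ``fit`` classes onto ``reference`` classes.

    Matches class mean PACC trajectories on a common grid by minimal summed
    squared distance over all permutations (G <= 3 in practice); resolves
    label switching between fold refits deterministically.
    """
    G = fit.spec.n_classes
    t_max = min(fit.spline.boundary_knots[1], reference.spline.boundary_knots[1])
    grid = np.linspace(0.0, t_max, n_grid)
    cf = np.stack([t.mean for t in class_trajectories(fit, grid, ci=False)])
    cr = np.stack([t.mean for t in class_trajectories(reference, grid, ci=False)])
    best_perm, best_cost = None, np.inf
    for perm in permutations(range(G)):
        cost = float(((cf[list(perm)] - cr) ** 2).sum())
        if cost < best_cost:
            best_perm, best_cost = perm, cost
    return np.asarray(best_perm)


def cross_validate(
    cohort: CohortData,
    spec: LcmmSpec,
    folds: FoldAssignment,
    reference_fit: LcmmFit,
    n_starts: int = 3,
    seed: int = 0,
    use_baseline_outcome: bool = True,
    **fit_kwargs,
):
    """Per-subject held-out baseline-only class probabilities.

    For each fold the LCMM is refit on the training 90% (all transforms
    refit on training data only), its classes are aligned to the
    full-data reference fit by trajectory matching, and held-out subjects
    are scored with :func:`predict_class_baseline`.  Returns
    ``(predictions, fold_meta)``; non-convergent folds are flagged and
    their subjects excluded.
    """
    G = spec.n_classes
    preds = []
    meta = []
    for k in range(folds.K):
        test_ids = folds.subjects_in_fold(k)
        if not test_ids:
            continue
        train_ids = [s for s, f in folds.fold.items() if f != k]
        train = cohort.subset(train_ids)
        test = cohort.subset(test_ids)
        fit_k = fit_lcmm(train, spec, n_starts=n_starts, seed=seed + k, **fit_kwargs)
        meta.append(
            {
                "fold": k,
                "n_train": len(train_ids),
                "n_test": len(test_ids),
                "loglik": fit_k.loglik,
                "converged": fit_k.converged,
            }
        )
        if not fit_k.converged:
            warnings.warn(f"fold {k} did not converge; excluded from pooling")
            continue
        perm = align_classes(fit_k, reference_fit)
        p = predict_class_baseline(fit_k, test, use_baseline_outcome)
        prob_cols = [f"p_class{g + 1}" for g in range(G)]
        probs = p[prob_cols].to_numpy()
        aligned = probs[:, perm]  # reference class r <- fold class perm[r]
        p[prob_cols] = aligned
        p["predicted"] = aligned.argmax(axis=1)
        p["fold"] = k
        preds.append(p)
    predictions = pd.concat(preds, ignore_index=True) if preds else pd.DataFrame()
    return predictions, pd.DataFrame(meta)


# ---------------------------------------------------------------------------
# precision-recall
# ---------------------------------------------------------------------------

@dataclass
class PRCurve:
    thresholds: np.ndarray  # descending distinct scores
    precision: np.ndarray
    recall: np.ndarray
    auprc: float


def pr_curve(scores, positives) -> PRCurve:
    """Precision-recall curve and average-precision AUPRC.

    One point per distinct score threshold (ties grouped); AUPRC is average
    precision, ``sum(delta recall * precision)`` over the step curve —
    step interpolation avoids the optimism of linear PR interpolation.
    """
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives).astype(int)
    n_pos = int(positives.sum())
    if n_pos == 0:
        raise ValidationError("PR curve undefined without positives")
    if n_pos == len(positives):
        raise ValidationError("PR curve undefined without negatives")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = positives[order]
    distinct = np.r_[np.flatnonzero(s[1:] != s[:-1]), len(s) - 1]
    tp = np.cumsum(y)[distinct]
    n_pred = distinct + 1.0
    precision = tp / n_pred
    recall = tp / n_pos
    d_recall = np.diff(np.r_[0.0, recall])
    auprc = float((d_recall * precision).sum())
    return PRCurve(
        thresholds=s[distinct], precision=precision, recall=recall, auprc=auprc
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def wilson_interval(k: int, n: int, level: float = 0.95):
    """Wilson score interval for a binomial proportion."""
    z = norm.ppf(0.5 + level / 2)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def classification_metrics(
    predicted: dict, truth: dict, probabilities: pd.DataFrame | None = None
) -> dict:
    """Accuracy, balanced accuracy, confusion matrix, per-class AUPRC.

    ``probabilities`` (optional) must carry subject_id and p_class{g}
    columns; per-class one-vs-rest AUPRCs and the "any-decliner vs stable"
    AUPRC (positives = every non-first class) are then included.
    Accuracy CI is the Wilson 95% interval.
    """
    sids = sorted(truth)
    if set(predicted) != set(truth):
        raise ValidationError("predicted and truth must cover the same subjects")
    t = np.array([truth[s] for s in sids])
    p = np.array([predicted[s] for s in sids])
    classes = sorted(set(t) | set(p))
    cm = pd.DataFrame(0, index=classes, columns=classes)
    for ti, pi in zip(t, p):
        cm.loc[ti, pi] += 1
    acc = float((t == p).mean())
    lo, hi = wilson_interval(int((t == p).sum()), len(t))
    recalls = []
    for c in classes:
        n_c = int((t == c).sum())
        if n_c == 0:
            warnings.warn(f"class {c} absent from truth; recall undefined")
            continue
        recalls.append(float(((t == c) & (p == c)).sum() / n_c))
    out = {
        "accuracy": acc,
        "accuracy_ci": (float(lo), float(hi)),
        "balanced_accuracy": float(np.mean(recalls)),
        "confusion": cm,
        "n": len(t),
    }
    if probabilities is not None:
        probs = probabilities.set_index("subject_id").loc[sids]
        auprc = {}
        for g in classes:
            col = f"p_class{g + 1}"
            if col not in probs.columns:
                continue
            pos = (t == g).astype(int)
            if 0 < pos.sum() < len(pos):
                auprc[g] = pr_curve(probs[col].to_numpy(), pos).auprc
        out["auprc_per_class"] = auprc
        decl_cols = [f"p_class{g + 1}" for g in classes[1:] if f"p_class{g + 1}" in probs]
        if decl_cols:
            pos = (t != classes[0]).astype(int)
            if 0 < pos.sum() < len(pos):
                out["auprc_any_decliner"] = pr_curve(
                    probs[decl_cols].sum(axis=1).to_numpy(), pos
                ).auprc
    return out


def classification_agreement(labels_a: dict, labels_b: dict):
    """(count, fraction) of common subjects whose modal class differs."""
    common = sorted(set(labels_a) & set(labels_b))
    if not common:
        raise ValidationError("no overlapping subjects")
    n_re = sum(labels_a[s] != labels_b[s] for s in common)
    return n_re, n_re / len(common)
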