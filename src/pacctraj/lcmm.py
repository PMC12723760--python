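"""Latent class mixed-effects models estimated by multi-start EM.

The model for subject i with transformed outcome vector y_i:

* membership submodel: ``P(class = g | x_i) = pi_ig``, a multinomial logit
  in baseline covariates (reference class = class 1, the canonical
  "stable" class);
* longitudinal submodel: within class g,
  ``y_i = S_i alpha_g + W_i gamma + Z_i b_i + eps_i`` with class-specific
  natural-spline time effects ``alpha_g``, covariate effects ``gamma``
  shared across classes, subject random effects ``b_i ~ N(0, D)``
  (random intercept by default; intercept + slope for the biomarker
  models), and i.i.d. Gaussian residuals.

The observed-data likelihood is the mixture
``L_i = sum_g pi_ig * phi(y_i; S_i alpha_g + W_i gamma, Z_i D Z_i' + sigma_e^2 I)``,
maximized by an ECM algorithm: the E-step computes posterior class
probabilities tau; the M-step updates zeta by weighted multinomial-logit
Newton-Raphson, (alpha, gamma) by tau-weighted GLS, and the variance
components by quasi-Newton ascent of the expected complete-data
log-likelihood.  Each conditional step cannot decrease the observed
log-likelihood, which gives the EM monotonicity property asserted
throughout the test-suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from pacctraj.cohort import CohortData
from pacctraj.errors import (
    DegenerateInputError,
    MissingDataError,
    SpecificationError,
)
from pacctraj.mnl import fit_mnl, mnl_probs
from pacctraj.transforms import BoxCoxTransform, SplineBasis, build_spline_basis

LOG2PI = np.log(2.0 * np.pi)

DEFAULT_LONGITUDINAL_COVARIATES = [
    "active_treatment",
    "ptau217",
    "amyloid_suvr",
    "apoe4_carrier",
    "sex_female",
    "age",
    "education",
    "hipp_atrophy_z",
    "pacc_version",
]
#: Membership covariates: all of the above except the stimulus version.
DEFAULT_MEMBERSHIP_COVARIATES = [
    c for c in DEFAULT_LONGITUDINAL_COVARIATES if c != "pacc_version"
]

CLASS_NAME_SETS = {
    1: ["all"],
    2: ["stable", "decliner"],
    3: ["stable", "slow_decliner", "fast_decliner"],
}


@dataclass(frozen=True)
class LcmmSpec:
    """Model definition: classes, spline flexibility, covariates, effects."""

    n_classes: int = 3
    spline_df: int = 2
    longitudinal_covariates: tuple = tuple(DEFAULT_LONGITUDINAL_COVARIATES)
    membership_covariates: tuple = tuple(DEFAULT_MEMBERSHIP_COVARIATES)
    random_effects: str = "intercept"  # or "intercept+slope"
    standardize: bool = True

    def __post_init__(self):
        if self.n_classes < 1:
            raise SpecificationError("n_classes must be >= 1")
        if self.random_effects not in ("intercept", "intercept+slope"):
            raise SpecificationError(f"unknown random_effects {self.random_effects!r}")

    @property
    def n_variance_params(self) -> int:
        return 2 if self.random_effects == "intercept" else 4

    def n_params(self) -> int:
        G, df = self.n_classes, self.spline_df
        return (
            (G - 1) * (1 + len(self.membership_covariates))
            + G * (1 + df)
            + len(self.longitudinal_covariates)
            + self.n_variance_params
        )


@dataclass
class ColumnScaler:
    """Per-column affine scaling ``(x - center) / scale``, reusable on new data."""

    names: list
    center: np.ndarray
    scale: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center) / self.scale

    def to_dict(self):
        return {
            "names": list(self.names),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(list(d["names"]), np.asarray(d["center"]), np.asarray(d["scale"]))


@dataclass
class ModelData:
    """Cohort prepared for likelihood evaluation (transformed and designed)."""

    subject_ids: np.ndarray  # (n,)
    y: np.ndarray  # (M,) transformed outcome
    times: np.ndarray  # (M,)
    starts: np.ndarray  # (n,) reduceat start index per subject
    n_i: np.ndarray  # (n,)
    S: np.ndarray  # (M, 1+df) intercept + spline columns
    W: np.ndarray  # (M, p) scaled shared-covariate design
    Xm: np.ndarray  # (n, p_m) scaled membership design
    spec: LcmmSpec
    boxcox: BoxCoxTransform | None
    spline: SplineBasis
    w_scaler: ColumnScaler
    xm_scaler: ColumnScaler
    atrophy_fit: tuple | None  # (beta0, beta1, mean, sd) for held-out reuse

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def t_max(self) -> float:
        return float(self.spline.boundary_knots[1])

    def subject_slices(self):
        ends = np.append(self.starts[1:], len(self.y))
        return zip(self.starts, ends)

    def time_groups(self):
        """Subjects grouped by identical visit-time pattern.

        With a common visit schedule most subjects share a handful of time
        patterns, so V_i (which depends only on the times) can be factorized
        once per group.  Returns a list of
        ``(times (m,), subject_indices (s,), obs_indices (s*m,))``.
        """
        if not hasattr(self, "_time_groups"):
            groups = {}
            for i, (a, b) in enumerate(self.subject_slices()):
                key = tuple(np.round(self.times[a:b], 9))
                groups.setdefault(key, []).append((i, a, b))
            out = []
            for key, members in groups.items():
                subj = np.array([m[0] for m in members])
                obs = np.concatenate(
                    [np.arange(a, b) for _, a, b in members]
                )
                out.append((np.asarray(key), subj, obs))
            self._time_groups = out
        return self._time_groups

    def reduce_subject(self, v: np.ndarray) -> np.ndarray:
        """Per-subject sums of an observation-level vector/matrix."""
        return np.add.reduceat(v, self.starts, axis=0)


def _atrophy_from_baseline(baseline: pd.DataFrame, atrophy_fit=None):
    vol = baseline["hippocampal_volume"].to_numpy(dtype=float)
    icv = baseline["icv"].to_numpy(dtype=float)
    if atrophy_fit is None:
        X = np.column_stack([np.ones_like(icv), icv])
        beta, *_ = np.linalg.lstsq(X, vol, rcond=None)
        resid = vol - X @ beta
        mean, sd = resid.mean(), resid.std(ddof=0)
        if sd == 0:
            raise DegenerateInputError("hippocampal volume collinear with icv")
        atrophy_fit = (float(beta[0]), float(beta[1]), float(mean), float(sd))
    b0, b1, mean, sd = atrophy_fit
    z = -((vol - b0 - b1 * icv) - mean) / sd
    return z, atrophy_fit


def build_model_data(
    cohort: CohortData,
    spec: LcmmSpec,
    boxcox="fit",
    spline: SplineBasis | None = None,
    scalers=None,
    atrophy_fit=None,
) -> ModelData:
    """Assemble design matrices and transformed outcome for a cohort.

    ``boxcox`` may be "fit" (maximum-likelihood fit on the pooled outcome),
    ``None`` (identity; used for biomarker models), or a fitted
    :class:`BoxCoxTransform` to reuse (cross-validation).  ``scalers`` and
    ``atrophy_fit`` likewise allow exact reuse of training-fit transforms on
    held-out subjects.  Subjects missing any model covariate are dropped
    (complete-case), as are visits with a missing outcome.
    """
    from pacctraj.transforms import fit_boxcox

    baseline = cohort.baseline.copy()
    if "hipp_atrophy_z" in set(spec.longitudinal_covariates) | set(
        spec.membership_covariates
    ):
        z, atrophy_fit = _atrophy_from_baseline(baseline, atrophy_fit)
        baseline["hipp_atrophy_z"] = z

    subj_cols = sorted(
        (set(spec.longitudinal_covariates) | set(spec.membership_covariates))
        - {"pacc_version"}
    )
    complete = baseline[subj_cols].notna().all(axis=1)
    baseline = baseline[complete]
    keep = set(baseline["subject_id"])

    visits = cohort.visits
    visits = visits[visits["subject_id"].isin(keep) & visits["pacc"].notna()]
    visits = visits.sort_values(["subject_id", "time_years"], kind="mergesort")
    observed = set(visits["subject_id"])
    baseline = baseline[baseline["subject_id"].isin(observed)].reset_index(drop=True)
    baseline = baseline.set_index("subject_id", drop=False).loc[
        sorted(observed)
    ].reset_index(drop=True)
    visits = visits.reset_index(drop=True)
    if len(baseline) == 0:
        raise MissingDataError("no subjects with complete covariates and outcomes")

    sid_obs = visits["subject_id"].to_numpy()
    subject_ids = baseline["subject_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, sid_obs[1:] != sid_obs[:-1]])
    n_i = np.diff(np.append(starts, len(visits)))

    y_raw = visits["pacc"].to_numpy(dtype=float)
    reused_transform = boxcox is not None and boxcox != "fit"
    if boxcox == "fit":
        boxcox = fit_boxcox(y_raw)
    # a transform fitted elsewhere may not cover held-out extremes: clamp
    y = boxcox.apply(y_raw, clamp=reused_transform) if boxcox is not None else y_raw

    times = visits["time_years"].to_numpy(dtype=float)
    if spline is None:
        spline = build_spline_basis(times, spec.spline_df)
    S = np.column_stack([np.ones(len(times)), spline.evaluate(times)])

    def design(names, table, visit_level):
        cols = []
        for name in names:
            if name == "pacc_version":
                cols.append(visits["pacc_version"].to_numpy(dtype=float))
            elif visit_level:
                cols.append(
                    visits["subject_id"].map(
                        table.set_index("subject_id")[name]
                    ).to_numpy(dtype=float)
                )
            else:
                cols.append(table[name].to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.empty((len(table), 0))

    W_raw = design(spec.longitudinal_covariates, baseline, visit_level=True)
    Xm_raw = design(spec.membership_covariates, baseline, visit_level=False)

    def make_scaler(names, X, subject_level):
        center = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
        if spec.standardize:
            for j in range(X.shape[1]):
                vals = X[:, j]
                uniq = np.unique(vals)
                if len(uniq) <= 2:
                    center[j] = uniq.min()  # binary codes mapped to 0/1
                    scale[j] = (uniq.max() - uniq.min()) or 1.0
                else:
                    center[j] = vals.mean()
                    scale[j] = vals.std(ddof=0) or 1.0
        return ColumnScaler(list(names), center, scale)

    if scalers is None:
        w_scaler = make_scaler(spec.longitudinal_covariates, W_raw, True)
        xm_scaler = make_scaler(spec.membership_covariates, Xm_raw, False)
    else:
        w_scaler, xm_scaler = scalers

    return ModelData(
        subject_ids=subject_ids,
        y=y,
        times=times,
        starts=starts,
        n_i=n_i,
        S=S,
        W=w_scaler.apply(W_raw),
        Xm=xm_scaler.apply(Xm_raw),
        spec=spec,
        boxcox=boxcox if boxcox is not None else None,
        spline=spline,
        w_scaler=w_scaler,
        xm_scaler=xm_scaler,
        atrophy_fit=atrophy_fit,
    )


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

@dataclass
class LcmmParams:
    """One parameter slice: enough to evaluate the likelihood."""

    alpha: np.ndarray  # (G, 1+df)
    gamma: np.ndarray  # (p,)
    zeta: np.ndarray  # (G-1, 1+p_m)
    sigma_e: float
    sigma_b: float = 0.0  # random-intercept SD
    chol: np.ndarray | None = None  # (2,2) lower Cholesky of D for i+s models

    def copy(self):
        return LcmmParams(
            self.alpha.copy(),
            self.gamma.copy(),
            self.zeta.copy(),
            self.sigma_e,
            self.sigma_b,
            None if self.chol is None else self.chol.copy(),
        )


def _mu_matrix(md: ModelData, params: LcmmParams) -> np.ndarray:
    """Observation-level class means, shape (M, G)."""
    shared = md.W @ params.gamma if md.W.shape[1] else 0.0
    return md.S @ params.alpha.T + np.atleast_1d(shared)[:, None]


def _residual_summaries(md, params):
    """Per-subject, per-class residual sums used by the intercept model."""
    R = md.y[:, None] - _mu_matrix(md, params)  # (M, G)
    ssr = md.reduce_subject(R * R)  # (n, G)
    s1 = md.reduce_subject(R)  # (n, G)
    return ssr, s1


def _component_loglik_intercept(md, ssr, s1, sigma_b, sigma_e):
    n_i = md.n_i[:, None]
    se2, sb2 = sigma_e**2, sigma_b**2
    denom = se2 + n_i * sb2
    c = sb2 / denom
    quad = (ssr - c * s1**2) / se2
    logdet = (n_i - 1) * np.log(se2) + np.log(denom)
    return -0.5 * (n_i * LOG2PI + logdet + quad)


def _component_loglik_dense(md, params):
    """(n, G) component log-densities for intercept+slope random effects."""
    mu = _mu_matrix(md, params)
    G = mu.shape[1]
    D = params.chol @ params.chol.T
    se2 = params.sigma_e**2
    out = np.empty((md.n_subjects, G))
    for times, subj, obs in md.time_groups():
        m, s = len(times), len(subj)
        Z = np.column_stack([np.ones(m), times])
        V = Z @ D @ Z.T + se2 * np.eye(m)
        L = np.linalg.cholesky(V)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        R = (md.y[obs, None] - mu[obs]).reshape(s, m, G)
        u = np.linalg.solve(L, R.transpose(1, 0, 2).reshape(m, s * G))
        quad = (u * u).sum(axis=0).reshape(s, G)
        out[subj] = -0.5 * (m * LOG2PI + logdet + quad)
    return out


def component_logliks(md: ModelData, params: LcmmParams) -> np.ndarray:
    if md.spec.random_effects == "intercept":
        ssr, s1 = _residual_summaries(md, params)
        return _component_loglik_intercept(md, ssr, s1, params.sigma_b, params.sigma_e)
    return _component_loglik_dense(md, params)


def membership_probs(md: ModelData, params: LcmmParams) -> np.ndarray:
    if md.spec.n_classes == 1:
        return np.ones((md.n_subjects, 1))
    return mnl_probs(params.zeta, md.Xm)


def loglik(md: ModelData, params: LcmmParams) -> float:
    """Observed-data log-likelihood (log-sum-exp over classes per subject)."""
    if params.sigma_e <= 0 and (
        params.sigma_b <= 0 if md.spec.random_effects == "intercept" else False
    ):
        raise DegenerateInputError("sigma_e = sigma_b = 0 gives a singular V_i")
    ll = component_logliks(md, params)
    logpi = np.log(np.clip(membership_probs(md, params), 1e-300, None))
    return float(logsumexp(logpi + ll, axis=1).sum())


def posterior_matrix(md: ModelData, params: LcmmParams) -> np.ndarray:
    ll = component_logliks(md, params)
    logpi = np.log(np.clip(membership_probs(md, params), 1e-300, None))
    a = logpi + ll
    a -= a.max(axis=1, keepdims=True)
    tau = np.exp(a)
    tau /= tau.sum(axis=1, keepdims=True)
    return tau


# ---------------------------------------------------------------------------
# M-step pieces
# ---------------------------------------------------------------------------

def _gls_update_intercept(md, tau, sigma_b, sigma_e):
    """tau-weighted GLS for (alpha_1..alpha_G, gamma), Woodbury V-inverse."""
    G = md.spec.n_classes
    k = md.S.shape[1]
    p = md.W.shape[1]
    K = G * k + p
    se2, sb2 = sigma_e**2, sigma_b**2
    c = sb2 / (se2 + md.n_i * sb2)  # (n,)

    S_sum = md.reduce_subject(md.S)  # (n, k)
    W_sum = md.reduce_subject(md.W) if p else np.empty((md.n_subjects, 0))
    y_sum = md.reduce_subject(md.y)  # (n,)
    tau_obs = tau[np.repeat(np.arange(md.n_subjects), md.n_i)]  # (M, G)

    def cross(U, Usum, V, Vsum, w_subj, w_obs):
        t1 = (U * w_obs[:, None]).T @ V
        t2 = (Usum * (w_subj * c)[:, None]).T @ Vsum
        return (t1 - t2) / se2

    A = np.zeros((K, K))
    rhs = np.zeros(K)
    for g in range(G):
        wg, wo = tau[:, g], tau_obs[:, g]
        sl = slice(g * k, (g + 1) * k)
        A[sl, sl] = cross(md.S, S_sum, md.S, S_sum, wg, wo)
        ySg = cross(md.S, S_sum, md.y[:, None], y_sum[:, None], wg, wo).ravel()
        rhs[sl] = ySg
        if p:
            SW = cross(md.S, S_sum, md.W, W_sum, wg, wo)
            A[sl, G * k :] = SW
            A[G * k :, sl] = SW.T
            A[G * k :, G * k :] += cross(md.W, W_sum, md.W, W_sum, wg, wo)
            rhs[G * k :] += cross(
                md.W, W_sum, md.y[:, None], y_sum[:, None], wg, wo
            ).ravel()
    beta = np.linalg.solve(A, rhs)
    alpha = beta[: G * k].reshape(G, k)
    gamma = beta[G * k :]
    return alpha, gamma


def _gls_update_dense(md, tau, params):
    """Dense tau-weighted GLS for intercept+slope covariance.

    Factorizes V once per time-pattern group; the class design S depends
    only on time, so S' V^-1 S is shared within a group.
    """
    G = md.spec.n_classes
    k = md.S.shape[1]
    p = md.W.shape[1]
    K = G * k + p
    D = params.chol @ params.chol.T
    se2 = params.sigma_e**2
    A = np.zeros((K, K))
    rhs = np.zeros(K)
    for times, subj, obs in md.time_groups():
        m, s = len(times), len(subj)
        Z = np.column_stack([np.ones(m), times])
        Vi = np.linalg.inv(Z @ D @ Z.T + se2 * np.eye(m))
        Sg = md.S[obs[:m]]  # (m, k): same for all subjects in the group
        Y = md.y[obs].reshape(s, m)
        ViY = Y @ Vi  # (s, m), Vi symmetric
        SVS = Sg.T @ Vi @ Sg
        SVy = Sg.T @ ViY.T  # (k, s)
        tg = tau[subj]  # (s, G)
        for g in range(G):
            sl = slice(g * k, (g + 1) * k)
            A[sl, sl] += tg[:, g].sum() * SVS
            rhs[sl] += SVy @ tg[:, g]
        if p:
            Wb = md.W[obs].reshape(s, m, p)
            ViW = np.einsum("mn,snp->smp", Vi, Wb)
            SVW = np.einsum("mk,smp->skp", Sg, ViW)
            for g in range(G):
                sl = slice(g * k, (g + 1) * k)
                blk = np.einsum("s,skp->kp", tg[:, g], SVW)
                A[sl, G * k :] += blk
                A[G * k :, sl] += blk.T
            A[G * k :, G * k :] += np.einsum("smp,smq->pq", Wb, ViW)  # sum_g tau = 1
            rhs[G * k :] += np.einsum("smp,sm->p", Wb, ViY)
    beta = np.linalg.solve(A, rhs)
    return beta[: G * k].reshape(G, k), beta[G * k :]


def _variance_update_intercept(md, params, tau):
    """Maximize expected complete-data loglik over (sigma_b, sigma_e)."""
    ssr, s1 = _residual_summaries(md, params)
    ssr_i = (tau * ssr).sum(axis=1)
    s1sq_i = (tau * s1**2).sum(axis=1)
    n_i = md.n_i.astype(float)

    def negQ(x):
        sb2, se2 = np.exp(2 * x[0]), np.exp(2 * x[1])
        denom = se2 + n_i * sb2
        c = sb2 / denom
        quad = (ssr_i - c * s1sq_i) / se2
        logdet = (n_i - 1) * np.log(se2) + np.log(denom)
        return 0.5 * float((logdet + quad).sum())

    x0 = np.log([max(params.sigma_b, 1e-5), max(params.sigma_e, 1e-5)])
    res = optimize.minimize(
        negQ, x0, method="L-BFGS-B", bounds=[(-12.0, 7.0)] * 2
    )
    if res.fun <= negQ(x0):
        return float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    return params.sigma_b, params.sigma_e


def _variance_update_dense(md, params, tau):
    """Maximize expected complete loglik over (chol(D), sigma_e), i+s model."""

    def negQ(x):
        x = np.clip(x, -10.0, 10.0)
        L = np.array([[np.exp(x[0]), 0.0], [x[1], np.exp(x[2])]])
        se = max(np.exp(x[3]), 1e-6)
        trial = LcmmParams(
            params.alpha, params.gamma, params.zeta, se, 0.0, L
        )
        try:
            ll = _component_loglik_dense(md, trial)
        except np.linalg.LinAlgError:
            return 1e12
        return -float((tau * ll).sum())

    L0 = params.chol
    x0 = np.array(
        [
            np.log(max(L0[0, 0], 1e-4)),
            L0[1, 0],
            np.log(max(L0[1, 1], 1e-4)),
            np.log(max(params.sigma_e, 1e-4)),
        ]
    )
    res = optimize.minimize(negQ, x0, method="Nelder-Mead",
                            options={"maxiter": 200, "fatol": 1e-8})
    x = res.x if res.fun <= negQ(x0) else x0
    L = np.array([[np.exp(x[0]), 0.0], [x[1], np.exp(x[2])]])
    return L, float(np.exp(x[3]))


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

@dataclass
class LcmmFit:
    """A fitted latent class mixed model."""

    spec: LcmmSpec
    params: LcmmParams
    loglik: float
    n_params: int
    bic: float
    icl: float
    posterior: np.ndarray  # (n, G)
    subject_ids: np.ndarray
    converged: bool
    n_iter: int
    n_starts_used: int
    empty_class: bool
    loglik_trace: list = field(default_factory=list)
    boxcox: BoxCoxTransform | None = None
    spline: SplineBasis | None = None
    w_scaler: ColumnScaler | None = None
    xm_scaler: ColumnScaler | None = None
    atrophy_fit: tuple | None = None
    w_reference: np.ndarray | None = None  # design-scale covariate profile
    seed: int | None = None

    @property
    def zeta(self):
        return self.params.zeta

    @property
    def alpha(self):
        return self.params.alpha

    @property
    def gamma(self):
        return self.params.gamma

    @property
    def sigma_b(self):
        return self.params.sigma_b

    @property
    def sigma_e(self):
        return self.params.sigma_e

    @property
    def class_names(self):
        G = self.spec.n_classes
        return CLASS_NAME_SETS.get(G, [f"class_{g + 1}" for g in range(G)])

    @property
    def class_labels(self) -> dict:
        hard = self.posterior.argmax(axis=1)
        return dict(zip(self.subject_ids, hard))

    @property
    def class_proportions(self) -> np.ndarray:
        hard = self.posterior.argmax(axis=1)
        return np.bincount(hard, minlength=self.spec.n_classes) / len(hard)

    def mean_posterior_confidence(self) -> float:
        """Mean of each subject's maximum posterior probability."""
        return float(self.posterior.max(axis=1).mean())

    def posterior_table(self) -> pd.DataFrame:
        G = self.spec.n_classes
        df = pd.DataFrame(
            self.posterior, columns=[f"tau_{g + 1}" for g in range(G)]
        )
        df.insert(0, "subject_id", self.subject_ids)
        df["class"] = self.posterior.argmax(axis=1)
        return df

    def to_json(self, path):
        d = {
            "spec": {
                "n_classes": self.spec.n_classes,
                "spline_df": self.spec.spline_df,
                "longitudinal_covariates": list(self.spec.longitudinal_covariates),
                "membership_covariates": list(self.spec.membership_covariates),
                "random_effects": self.spec.random_effects,
                "standardize": self.spec.standardize,
            },
            "alpha": self.params.alpha.tolist(),
            "gamma": self.params.gamma.tolist(),
            "zeta": self.params.zeta.tolist(),
            "sigma_b": self.params.sigma_b,
            "sigma_e": self.params.sigma_e,
            "chol": None if self.params.chol is None else self.params.chol.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "icl": self.icl,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_starts_used": self.n_starts_used,
            "empty_class": self.empty_class,
            "seed": self.seed,
            "boxcox": None if self.boxcox is None else self.boxcox.to_dict(),
            "spline": None if self.spline is None else self.spline.to_dict(),
            "w_scaler": None if self.w_scaler is None else self.w_scaler.to_dict(),
            "xm_scaler": None if self.xm_scaler is None else self.xm_scaler.to_dict(),
            "atrophy_fit": self.atrophy_fit,
            "w_reference": None
            if self.w_reference is None
            else self.w_reference.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        spec = LcmmSpec(
            n_classes=d["spec"]["n_classes"],
            spline_df=d["spec"]["spline_df"],
            longitudinal_covariates=tuple(d["spec"]["longitudinal_covariates"]),
            membership_covariates=tuple(d["spec"]["membership_covariates"]),
            random_effects=d["spec"]["random_effects"],
            standardize=d["spec"]["standardize"],
        )
        params = LcmmParams(
            alpha=np.asarray(d["alpha"]),
            gamma=np.asarray(d["gamma"]),
            zeta=np.asarray(d["zeta"]),
            sigma_e=d["sigma_e"],
            sigma_b=d["sigma_b"],
            chol=None if d["chol"] is None else np.asarray(d["chol"]),
        )
        return cls(
            spec=spec,
            params=params,
            loglik=d["loglik"],
            n_params=d["n_params"],
            bic=d["bic"],
            icl=d["icl"],
            posterior=np.zeros((0, spec.n_classes)),
            subject_ids=np.asarray([]),
            converged=d["converged"],
            n_iter=d["n_iter"],
            n_starts_used=d["n_starts_used"],
            empty_class=d["empty_class"],
            boxcox=None if d["boxcox"] is None else BoxCoxTransform.from_dict(d["boxcox"]),
            spline=None if d["spline"] is None else SplineBasis.from_dict(d["spline"]),
            w_scaler=None
            if d["w_scaler"] is None
            else ColumnScaler.from_dict(d["w_scaler"]),
            xm_scaler=None
            if d["xm_scaler"] is None
            else ColumnScaler.from_dict(d["xm_scaler"]),
            atrophy_fit=None if d["atrophy_fit"] is None else tuple(d["atrophy_fit"]),
            w_reference=None
            if d["w_reference"] is None
            else np.asarray(d["w_reference"]),
            seed=d["seed"],
        )


def information_criteria(ll: float, n_params: int, n_subjects: int, tau: np.ndarray):
    """BIC and ICL.  ICL = BIC + 2 * total posterior entropy (>= BIC)."""
    bic = -2.0 * ll + n_params * np.log(n_subjects)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(tau * np.log(np.clip(tau, 1e-300, None)))
    return float(bic), float(bic + 2.0 * ent)


def _subject_ols_features(md: ModelData):
    """Per-subject OLS intercept and slope of y on t (slope 0 for 1 visit)."""
    feats = np.zeros((md.n_subjects, 2))
    for i, (a, b) in enumerate(md.subject_slices()):
        t, y = md.times[a:b], md.y[a:b]
        if b - a >= 2 and np.ptp(t) > 0:
            tc = t - t.mean()
            slope = float(tc @ (y - y.mean()) / (tc @ tc))
            feats[i] = [y.mean() - slope * t.mean(), slope]
        else:
            feats[i] = [y.mean(), 0.0]
    return feats


def _kmeans_once(X, G, rng, n_iter=30):
    centers = X[rng.choice(len(X), size=G, replace=False)]
    labels = np.zeros(len(X), dtype=int)
    for _ in range(n_iter):
        d = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
        new = d.argmin(axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
        for g in range(G):
            if np.any(labels == g):
                centers[g] = X[labels == g].mean(axis=0)
    d = ((X[:, None, :] - centers[None]) ** 2).sum(axis=2)
    return labels, float(d.min(axis=1).sum())


def _kmeans(X, G, rng, restarts=5):
    """Tiny seeded k-means (best of several restarts) for EM initialization."""
    best_labels, best_inertia = None, np.inf
    for _ in range(restarts):
        labels, inertia = _kmeans_once(X, G, rng)
        if inertia < best_inertia:
            best_labels, best_inertia = labels, inertia
    return best_labels


def _initial_params(md: ModelData, assign, spec: LcmmSpec):
    G = spec.n_classes
    tau0 = np.full((md.n_subjects, G), 0.05 / max(G - 1, 1))
    tau0[np.arange(md.n_subjects), assign] = 0.95 if G > 1 else 1.0
    tau0 /= tau0.sum(axis=1, keepdims=True)
    sd = md.y.std() or 1.0
    params = LcmmParams(
        alpha=np.zeros((G, md.S.shape[1])),
        gamma=np.zeros(md.W.shape[1]),
        zeta=np.zeros((G - 1, 1 + md.Xm.shape[1])),
        sigma_e=0.7 * sd,
        sigma_b=0.7 * sd,
        chol=None
        if spec.random_effects == "intercept"
        else np.diag([0.7 * sd, 0.1 * sd]),
    )
    if spec.random_effects == "intercept":
        params.alpha, params.gamma = _gls_update_intercept(
            md, tau0, params.sigma_b, params.sigma_e
        )
    else:
        params.alpha, params.gamma = _gls_update_dense(md, tau0, params)
    return params, tau0


def _em_run(md, params, tau, max_iter, tol=1e-6, param_tol=1e-4):
    """Run ECM from the given state; returns (params, ll_trace, converged)."""
    spec = md.spec
    trace = []
    ll_prev = -np.inf
    converged = False
    for it in range(max_iter):
        # M-step (uses tau from the previous E-step or initialization)
        if spec.n_classes > 1:
            params.zeta = fit_mnl(md.Xm, tau, zeta0=params.zeta, max_iter=25)
        if spec.random_effects == "intercept":
            params.alpha, params.gamma = _gls_update_intercept(
                md, tau, params.sigma_b, params.sigma_e
            )
            params.sigma_b, params.sigma_e = _variance_update_intercept(
                md, params, tau
            )
        else:
            params.alpha, params.gamma = _gls_update_dense(md, tau, params)
            params.chol, params.sigma_e = _variance_update_dense(md, params, tau)
        # E-step
        tau = posterior_matrix(md, params)
        ll = loglik(md, params)
        trace.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    return params, tau, trace, converged


def _canonicalize(md, params, tau):
    """Reorder classes by model-implied mean at t_max, descending.

    Class 1 becomes the flattest ("stable") trajectory and the last class
    the steepest decliner; the membership reference class follows class 1.
    """
    G = md.spec.n_classes
    if G == 1:
        return params, tau
    s_end = np.concatenate([[1.0], md.spline.evaluate([md.t_max])[0]])
    means = params.alpha @ s_end
    perm = np.argsort(-means, kind="stable")
    params.alpha = params.alpha[perm]
    zeta_full = np.vstack([np.zeros(params.zeta.shape[1]), params.zeta])[perm]
    zeta_full = zeta_full - zeta_full[0]
    params.zeta = zeta_full[1:]
    return params, tau[:, perm]


def fit_lcmm(
    cohort_or_md,
    spec: LcmmSpec,
    n_starts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    short_iter: int = 30,
    boxcox="fit",
) -> LcmmFit:
    """Fit the LCMM by multi-start ECM.

    Starts from a k-means partition of per-subject OLS (intercept, slope)
    features plus ``n_starts - 1`` seeded perturbations; each start runs a
    short ECM burn-in and the best is continued to convergence
    (|delta loglik| < 1e-6, at most ``max_iter`` iterations).  Classes are
    then canonically ordered (flattest trajectory first), and posterior,
    BIC and ICL populated.
    """
    md = (
        cohort_or_md
        if isinstance(cohort_or_md, ModelData)
        else build_model_data(cohort_or_md, spec, boxcox=boxcox)
    )
    G = spec.n_classes
    rng = np.random.default_rng(seed)
    feats = _subject_ols_features(md)
    fs = (feats - feats.mean(axis=0)) / (feats.std(axis=0) + 1e-12)

    states = []
    for s in range(max(n_starts, 1)):
        if G == 1:
            assign = np.zeros(md.n_subjects, dtype=int)
        elif s == 0:
            assign = _kmeans(fs, G, np.random.default_rng(seed))
        elif s == 1:
            # slope-quantile start: classes differ mainly in rate of change
            ranks = np.argsort(np.argsort(feats[:, 1]))
            assign = np.minimum((ranks * G) // md.n_subjects, G - 1)
        else:
            assign = _kmeans(fs, G, rng)
            flip = rng.random(md.n_subjects) < 0.25
            assign[flip] = rng.integers(0, G, size=int(flip.sum()))
        params, tau = _initial_params(md, assign, spec)
        params, tau, trace, _ = _em_run(md, params, tau, max_iter=short_iter)
        states.append((trace[-1], params, tau, trace))
        if G == 1:
            break

    states.sort(key=lambda st: -st[0])
    _, params, tau, trace0 = states[0]
    params, tau, trace1, converged = _em_run(md, params, tau, max_iter=max_iter)
    trace = trace0 + trace1

    params, tau = _canonicalize(md, params, tau)
    ll = loglik(md, params)
    n_par = spec.n_params()
    bic, icl = information_criteria(ll, n_par, md.n_subjects, tau)
    empty = bool(np.any(tau.max(axis=0) < 1e-6))
    if empty:
        warnings.warn("a latent class has (numerically) no members", stacklevel=2)

    return LcmmFit(
        spec=spec,
        params=params,
        loglik=ll,
        n_params=n_par,
        bic=bic,
        icl=icl,
        posterior=tau,
        subject_ids=md.subject_ids,
        converged=converged,
        n_iter=len(trace),
        n_starts_used=len(states),
        empty_class=empty,
        loglik_trace=trace,
        boxcox=md.boxcox,
        spline=md.spline,
        w_scaler=md.w_scaler,
        xm_scaler=md.xm_scaler,
        atrophy_fit=md.atrophy_fit,
        w_reference=md.W.mean(axis=0) if md.W.size else np.zeros(0),
        seed=seed,
    )


def posterior_probs(fit: LcmmFit, md: ModelData) -> np.ndarray:
    """Posterior class probabilities from a subject's full outcome vector."""
    return posterior_matrix(md, fit.params)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def select_model(
    cohort: CohortData,
    df_grid=(1, 2, 3),
    G_grid=(1, 2, 3),
    n_starts: int = 10,
    seed: int = 0,
    spec_template: LcmmSpec | None = None,
    **fit_kwargs,
):
    """Fit the (df x G) model grid and select by minimum BIC.

    Returns ``(best_fit, selection_table)``; ties (delta BIC < 2) break
    toward fewer parameters.  Non-convergent cells are flagged and excluded
    from the argmin.
    """
    if not df_grid or not G_grid:
        raise SpecificationError("model grids must be non-empty")
    template = spec_template or LcmmSpec()
    rows = []
    fits = {}
    for df in df_grid:
        for G in G_grid:
            spec = LcmmSpec(
                n_classes=G,
                spline_df=df,
                longitudinal_covariates=template.longitudinal_covariates,
                membership_covariates=template.membership_covariates,
                random_effects=template.random_effects,
                standardize=template.standardize,
            )
            fit = fit_lcmm(cohort, spec, n_starts=n_starts, seed=seed, **fit_kwargs)
            fits[(G, df)] = fit
            rows.append(
                {
                    "G": G,
                    "spline_df": df,
                    "loglik": fit.loglik,
                    "n_params": fit.n_params,
                    "BIC": fit.bic,
                    "ICL": fit.icl,
                    "converged": fit.converged,
                    "empty_class": fit.empty_class,
                }
            )
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        warnings.warn("no grid cell converged; selecting best achieved BIC")
        ok = table
    best_bic = ok["BIC"].min()
    near = ok[ok["BIC"] < best_bic + 2.0]
    best_row = near.sort_values(
        ["n_params", "G", "spline_df"], kind="mergesort"
    ).iloc[0]
    best = fits[(int(best_row["G"]), int(best_row["spline_df"]))]
    table["dBIC"] = table["BIC"] - table.loc[table.index, "BIC"].min()
    table["dICL"] = table["ICL"] - table["ICL"].min()
    table["selected"] = [
        (r["G"] == best.spec.n_classes) and (r["spline_df"] == best.spec.spline_df)
        for _, r in table.iterrows()
    ]
    return best, table


# ---------------------------------------------------------------------------
# trajectories and uncertainty
# ---------------------------------------------------------------------------

@dataclass
class ClassTrajectory:
    class_index: int
    class_name: str
    times: np.ndarray
    mean: np.ndarray  # PACC scale
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None


def _score_alpha_gamma(md, params):
    """Analytic score of the mixture loglik w.r.t. (vec alpha, gamma)."""
    tau = posterior_matrix(md, params)
    G = md.spec.n_classes
    k = md.S.shape[1]
    p = md.W.shape[1]
    se2, sb2 = params.sigma_e**2, params.sigma_b**2
    c = sb2 / (se2 + md.n_i * sb2)
    R = md.y[:, None] - _mu_matrix(md, params)  # (M, G)
    r_sum = md.reduce_subject(R)  # (n, G)
    S_sum = md.reduce_subject(md.S)
    W_sum = md.reduce_subject(md.W) if p else None
    tau_obs = tau[np.repeat(np.arange(md.n_subjects), md.n_i)]
    score = np.zeros(G * k + p)
    for g in range(G):
        wg, wo = tau[:, g], tau_obs[:, g]
        # D' Vinv r = (D'r - c (D'1)(1'r)) / se2
        t1 = md.S.T @ (wo * R[:, g])
        t2 = S_sum.T @ (wg * c * r_sum[:, g])
        score[g * k : (g + 1) * k] = (t1 - t2) / se2
        if p:
            t1w = md.W.T @ (wo * R[:, g])
            t2w = W_sum.T @ (wg * c * r_sum[:, g])
            score[G * k :] += (t1w - t2w) / se2
    return score


def _observed_information(md, params, step=1e-5):
    """Observed information for (vec alpha, gamma) by central differences
    of the analytic score."""
    G, k, p = md.spec.n_classes, md.S.shape[1], md.W.shape[1]
    K = G * k + p

    def pack(theta):
        q = params.copy()
        q.alpha = theta[: G * k].reshape(G, k)
        q.gamma = theta[G * k :]
        return q

    theta0 = np.concatenate([params.alpha.ravel(), params.gamma])
    H = np.zeros((K, K))
    scale = np.maximum(np.abs(theta0), 1.0)
    for j in range(K):
        h = step * scale[j]
        tp, tm = theta0.copy(), theta0.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (_score_alpha_gamma(md, pack(tp)) - _score_alpha_gamma(md, pack(tm))) / (
            2 * h
        )
    H = 0.5 * (H + H.T)
    return -H  # observed information


def class_trajectories(
    fit: LcmmFit,
    times,
    md: ModelData | None = None,
    covariate_profile: np.ndarray | None = None,
    ci: bool = True,
) -> list:
    """Per-class mean PACC trajectories with delta-method 95% bands.

    The transformed-scale mean at the covariate profile (default: the
    design-scale covariate means stored at fit time) is
    ``[1, B(t)] alpha_g + w' gamma``; its variance comes from the
    observed-information covariance of (alpha, gamma); mean and interval
    endpoints are mapped through the inverse Box-Cox (monotone), so the
    bands remain valid on the PACC scale.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    B = np.column_stack([np.ones(len(times)), fit.spline.evaluate(times)])
    w = covariate_profile if covariate_profile is not None else fit.w_reference
    G, k = fit.spec.n_classes, B.shape[1]
    p = len(fit.gamma)

    cov = None
    if ci and md is not None:
        info = _observed_information(md, fit.params)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            warnings.warn("singular information matrix; CI unavailable")
            cov = None
        if cov is not None and np.any(np.diag(cov) < 0):
            cov = np.linalg.pinv(info)

    out = []
    z975 = 1.959963984540054
    for g in range(G):
        mean_t = B @ fit.alpha[g] + float(w @ fit.gamma)
        lo = hi = None
        if cov is not None:
            a = np.zeros((len(times), G * k + p))
            a[:, g * k : (g + 1) * k] = B
            a[:, G * k :] = w
            var = np.einsum("ij,jk,ik->i", a, cov, a)
            var = np.clip(var, 0.0, None)
            lo = mean_t - z975 * np.sqrt(var)
            hi = mean_t + z975 * np.sqrt(var)
        inv = fit.boxcox.inverse if fit.boxcox is not None else (lambda v: v)
        out.append(
            ClassTrajectory(
                class_index=g,
                class_name=fit.class_names[g],
                times=times,
                mean=inv(mean_t),
                ci_low=None if lo is None else inv(lo),
                ci_high=None if hi is None else inv(hi),
            )
        )
    return out


# ---------------------------------------------------------------------------
# biomarker LMM (G = 1, random intercept + slope)
# ---------------------------------------------------------------------------

def fit_biomarker_lmm(
    series: pd.DataFrame,
    value_col: str = "value",
    spline_df: int = 2,
    n_starts: int = 1,
    seed: int = 0,
):
    """Linear mixed model with random intercept+slope and natural-spline
    fixed effects for a longitudinal biomarker, on its native scale.

    ``series`` is long-format with columns subject_id, time_years and
    ``value_col``.  This is the single-class case of the LCMM with a 2x2
    random-effects covariance.  Returns ``(fit, trajectory)`` where the
    trajectory is the fixed-effect mean curve over the observed time range.
    """
    df = series.dropna(subset=[value_col]).copy()
    counts = df.groupby("subject_id")["time_years"].count()
    if (counts >= 2).sum() < 10:
        raise MissingDataError("need >= 2 visits for >= 10 subjects")

    visits = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "time_years": df["time_years"],
            "pacc": df[value_col],
            "pacc_version": 1,
        }
    )
    baseline = pd.DataFrame({"subject_id": sorted(df["subject_id"].unique())})
    baseline["arm"] = "LEARN"
    for col in ["ptau217", "amyloid_suvr", "amyloid_centiloid", "apoe4_carrier",
                "sex_female", "age", "education", "hippocampal_volume", "icv"]:
        baseline[col] = 0.0
    from pacctraj.cohort import validate_cohort

    cohort = validate_cohort(visits, baseline)
    spec = LcmmSpec(
        n_classes=1,
        spline_df=spline_df,
        longitudinal_covariates=(),
        membership_covariates=(),
        random_effects="intercept+slope",
    )
    fit = fit_lcmm(cohort, spec, n_starts=n_starts, seed=seed, boxcox=None)
    grid = np.linspace(0.0, fit.spline.boundary_knots[1], 25)
    traj = class_trajectories(fit, grid, ci=False)[0]
    return fit, traj
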