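"""Weighted multinomial logistic regression by Newton-Raphson.

Used for the latent-class membership submodel M-step (targets are the
fractional posterior probabilities tau) and for deriving the generating
membership coefficients of the synthetic cohort preset (targets are one-hot
class indicators).  Class 0 is the reference; coefficients are a
(G-1) x (1+p) matrix over an intercept plus p covariates.
"""

from __future__ import annotations

import numpy as np


def mnl_probs(zeta: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Class probabilities; ``X`` is (n, p) WITHOUT the intercept column.

    ``zeta`` is (G-1, 1+p); the reference class 0 has linear predictor 0.
    """
    n = X.shape[0]
    eta = np.zeros((n, zeta.shape[0] + 1))
    eta[:, 1:] = zeta[:, 0] + X @ zeta[:, 1:].T
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _weighted_ll(zeta, X, T):
    p = np.clip(mnl_probs(zeta, X), 1e-300, None)
    return float(np.sum(T * np.log(p)))


def fit_mnl(
    X: np.ndarray,
    T: np.ndarray,
    zeta0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Maximize ``sum_i sum_g T_ig log pi_ig(zeta; x_i)`` over zeta.

    ``T`` (n, G) holds non-negative weights with rows summing to 1 (hard
    labels or posterior probabilities).  Newton-Raphson with step halving;
    a tiny ridge keeps the Hessian invertible under separation.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    n, p = X.shape
    G = T.shape[1]
    k = 1 + p
    Xd = np.column_stack([np.ones(n), X])
    zeta = np.zeros((G - 1, k)) if zeta0 is None else np.array(zeta0, dtype=float)

    ll = _weighted_ll(zeta, X, T)
    for _ in range(max_iter):
        P = mnl_probs(zeta, X)
        # gradient: for g>=1, sum_i (T_ig - P_ig) x_i
        grad = ((T[:, 1:] - P[:, 1:]).T @ Xd).ravel()  # (G-1)*k
        # Hessian blocks: -sum_i x_i x_i' * (P_ig (delta_gh - P_ih))
        H = np.zeros(((G - 1) * k, (G - 1) * k))
        for g in range(1, G):
            for h in range(1, G):
                w = P[:, g] * ((1.0 if g == h else 0.0) - P[:, h])
                block = (Xd * w[:, None]).T @ Xd
                H[(g - 1) * k : g * k, (h - 1) * k : h * k] = -block
        H -= ridge * np.eye(H.shape[0])
        step = np.linalg.solve(H, grad).reshape(G - 1, k)
        # step halving on the weighted log-likelihood
        scale = 1.0
        for _half in range(30):
            cand = zeta - scale * step
            ll_new = _weighted_ll(cand, X, T)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        if ll_new < ll:
            break  # no improving step found
        improved = ll_new - ll
        zeta, ll = cand, ll_new
        if improved < tol:
            break
    return zeta
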