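"""Deterministic feature construction.

Box-Cox transform of the outcome with maximum-likelihood lambda, natural
cubic spline time bases, hippocampal residualize-and-z atrophy scores, and
the 8-region tau PET cortical composite.  All transforms store their fitted
parameters so they can be serialized and re-applied identically to held-out
data (a requirement for leakage-free cross-validation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from pacctraj.errors import (
    DegenerateInputError,
    MissingDataError,
    RangeError,
    SpecificationError,
)

#: The eight cortical regions averaged into the tau PET composite.
TAU_COMPOSITE_REGIONS = (
    "entorhinal",
    "inferior_temporal",
    "inferior_parietal",
    "posterior_cingulate",
    "caudal_middle_frontal",
    "middle_temporal",
    "superior_parietal",
    "frontal_pole",
)


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxCoxTransform:
    """A fitted Box-Cox power transform ``z = ((y + shift)^lam - 1) / lam``.

    ``shift`` is added before transforming so that all fitting values are
    strictly positive; ``lam = 0`` means the log transform.
    """

    lam: float
    shift: float = 0.0

    def apply(self, y, clamp: bool = False):
        """Forward transform; ``clamp=True`` floors out-of-domain values at
        the domain edge (used when re-applying a training-data transform to
        held-out subjects more extreme than anything seen in training)."""
        y = np.asarray(y, dtype=float)
        v = y + self.shift
        if np.any(v[np.isfinite(v)] <= 0):
            if clamp:
                v = np.maximum(v, 1e-6)
            else:
                bad = np.asarray(y)[v <= 0]
                raise RangeError(
                    f"Box-Cox domain violation: y + shift must be > 0, offending "
                    f"values {bad[:5].tolist()}"
                )
        if self.lam == 0.0:
            return np.log(v)
        return (np.power(v, self.lam) - 1.0) / self.lam

    def inverse(self, z):
        z = np.asarray(z, dtype=float)
        if self.lam == 0.0:
            return np.exp(z) - self.shift
        v = self.lam * z + 1.0
        if np.any(v[np.isfinite(v)] <= 0):
            bad = z[v <= 0]
            raise RangeError(
                f"inverse Box-Cox domain violation: lam*z + 1 must be > 0, "
                f"offending values {bad[:5].tolist()}"
            )
        return np.power(v, 1.0 / self.lam) - self.shift

    def to_dict(self):
        return {"lam": self.lam, "shift": self.shift}

    @classmethod
    def from_dict(cls, d):
        return cls(lam=float(d["lam"]), shift=float(d["shift"]))


def fit_boxcox(y, lam_bounds=(-3.0, 3.0), tol=1e-5) -> BoxCoxTransform:
    """Fit a Box-Cox transform by profile maximum likelihood.

    The shift convention is ``shift = 1 - min(y)`` when ``min(y) <= 0``
    (PACC takes negative values), else 0.  Lambda maximizes the standard
    Box-Cox profile log-likelihood (normal likelihood of the transformed
    values plus the Jacobian term ``(lam - 1) * sum(log(y + shift))``) over
    ``lam_bounds`` by bounded scalar search to ``tol``.
    """
    y = np.asarray(y, dtype=float)
    y = y[np.isfinite(y)]
    if y.size < 10:
        raise DegenerateInputError(
            f"need >= 10 finite values to fit Box-Cox, got {y.size}"
        )
    if np.ptp(y) == 0:
        raise DegenerateInputError("cannot fit Box-Cox to a constant vector")
    shift = 1.0 - y.min() if y.min() <= 0 else 0.0
    v = y + shift

    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, v),
        bounds=lam_bounds,
        method="bounded",
        options={"xatol": tol},
    )
    return BoxCoxTransform(lam=float(res.x), shift=float(shift))


def apply_boxcox(transform: BoxCoxTransform, y):
    """Forward Box-Cox; thin functional alias for :meth:`BoxCoxTransform.apply`."""
    return transform.apply(y)


def inverse_boxcox(transform: BoxCoxTransform, z):
    """Inverse Box-Cox; thin functional alias for :meth:`BoxCoxTransform.inverse`."""
    return transform.inverse(z)


# ---------------------------------------------------------------------------
# Natural cubic splines
# ---------------------------------------------------------------------------

def _natural_basis(t, knots):
    """Natural cubic spline basis (without intercept) on the given knots.

    Uses the closed-form basis built from truncated cubics
    ``d_k(t) = ((t-k_j)_+^3 - (t-k_K)_+^3) / (k_K - k_j)``; the columns are
    ``t`` and ``d_j - d_{K-1}`` for interior/left knots j.  This form is
    defined for all real t and is automatically linear outside the boundary
    knots (the natural constraint).
    """
    t = np.asarray(t, dtype=float)
    knots = np.asarray(knots, dtype=float)
    K = len(knots)

    def d(j):
        num = np.maximum(t - knots[j], 0.0) ** 3 - np.maximum(t - knots[-1], 0.0) ** 3
        return num / (knots[-1] - knots[j])

    cols = [t]
    if K >= 3:
        dlast = d(K - 2)
        for j in range(K - 2):
            cols.append(d(j) - dlast)
    return np.column_stack(cols)


@dataclass(frozen=True)
class SplineBasis:
    """Natural cubic spline basis with df in {1, 2, 3}.

    Boundary knots sit at the min and max observation time; interior knots
    at the median (df=2) or tertiles (df=3) of the pooled observation times,
    matching the knot rule used for the trajectory models.  The basis is
    linear beyond the boundary knots, so modest extrapolation is safe.
    """

    df: int
    boundary_knots: tuple
    interior_knots: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.df not in (1, 2, 3):
            raise SpecificationError(f"spline df must be in {{1,2,3}}, got {self.df}")
        if len(self.interior_knots) != self.df - 1:
            raise SpecificationError(
                f"df={self.df} requires {self.df - 1} interior knots, "
                f"got {len(self.interior_knots)}"
            )

    @property
    def all_knots(self):
        return np.asarray(
            sorted((self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1]))
        )

    def evaluate(self, times):
        """Basis matrix with one row per time and ``df`` columns (no intercept)."""
        B = _natural_basis(np.atleast_1d(times), self.all_knots)
        assert B.shape[1] == self.df
        return B

    def to_dict(self):
        return {
            "df": self.df,
            "boundary_knots": list(self.boundary_knots),
            "interior_knots": list(self.interior_knots),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            df=int(d["df"]),
            boundary_knots=tuple(d["boundary_knots"]),
            interior_knots=tuple(d["interior_knots"]),
        )


def build_spline_basis(times, df: int) -> SplineBasis:
    """Construct the natural spline basis from observed times.

    Interior knot rule: df=1 none, df=2 median, df=3 tertiles of the pooled
    observation times.
    """
    times = np.asarray(times, dtype=float)
    times = times[np.isfinite(times)]
    lo, hi = float(times.min()), float(times.max())
    if hi - lo <= 0:
        raise DegenerateInputError("observation times have zero span")
    if df == 1:
        interior = ()
    elif df == 2:
        interior = (float(np.quantile(times, 0.5)),)
    elif df == 3:
        interior = tuple(float(q) for q in np.quantile(times, [1 / 3, 2 / 3]))
    else:
        raise SpecificationError(f"spline df must be in {{1,2,3}}, got {df}")
    return SplineBasis(df=df, boundary_knots=(lo, hi), interior_knots=interior)


# ---------------------------------------------------------------------------
# Hippocampal atrophy and tau composite
# ---------------------------------------------------------------------------

def residualize_and_z(volume, icv):
    """Hippocampal atrophy z-score.

    OLS residuals of volume on (intercept, intracranial volume), z-scored,
    then sign-flipped so that larger values mean more atrophy (smaller
    residual volume).
    """
    volume = np.asarray(volume, dtype=float)
    icv = np.asarray(icv, dtype=float)
    if volume.shape != icv.shape:
        raise ValueError("volume and icv must have equal lengths")
    if volume.size < 3:
        raise DegenerateInputError("need n >= 3 to residualize")
    if np.ptp(icv) == 0:
        raise DegenerateInputError("intracranial volume has zero variance")
    X = np.column_stack([np.ones_like(icv), icv])
    beta, *_ = np.linalg.lstsq(X, volume, rcond=None)
    resid = volume - X @ beta
    sd = resid.std(ddof=0)
    if sd < 1e-12 * max(1.0, np.abs(volume).max()):
        raise DegenerateInputError(
            "residuals are (numerically) zero; volume is collinear with icv"
        )
    return -(resid - resid.mean()) / sd


def tau_composite(regional_suvr: dict) -> float:
    """Mean SUVr over the eight cortical composite regions.

    Raises :class:`MissingDataError` when any region is absent or
    non-finite, signalling that the subject is excluded from the tau model.
    """
    vals = []
    for region in TAU_COMPOSITE_REGIONS:
        if region not in regional_suvr or regional_suvr[region] is None:
            raise MissingDataError(f"tau composite missing region '{region}'")
        v = float(regional_suvr[region])
        if not np.isfinite(v):
            raise MissingDataError(f"tau composite region '{region}' is not finite")
        vals.append(v)
    return float(np.mean(vals))


def save_transforms(path, boxcox: BoxCoxTransform, spline: SplineBasis):
    """Serialize fitted transforms to JSON for exact reuse on held-out data."""
    with open(path, "w") as fh:
        json.dump({"boxcox": boxcox.to_dict(), "spline": spline.to_dict()}, fh, indent=2)


def load_transforms(path):
    with open(path) as fh:
        d = json.load(fh)
    return BoxCoxTransform.from_dict(d["boxcox"]), SplineBasis.from_dict(d["spline"])
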