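"""Class-specific clinical-trial power under attrition.

Power for a two-arm trial read out at a fixed horizon with a two-sample
t-test on PACC change, where the treatment effect is a fraction of the
"maximum possible benefit" — the gap between the amyloid-negative stable
group's mean and the target group's mean at that horizon.  Attrition is
handled as a completers-only analysis: ``n_eff = round(n * (1 - attrition))``
per arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pacctraj.errors import SpecificationError


def max_benefit(mean_reference_max: float, mean_control: float) -> float:
    """Maximum possible treatment benefit: reference minus control mean."""
    delta = mean_reference_max - mean_control
    if delta < 0:
        warnings.warn("reference group mean is below the control mean")
    return delta


@dataclass
class PowerScenario:
    """Inputs for one power calculation.

    Means and SDs are PACC points at the trial horizon; ``effect_fraction``
    scales the maximum benefit into the assumed treatment effect.
    """

    mean_control: float
    sd_control: float
    mean_reference_max: float
    sd_reference: float
    n_per_arm: int
    effect_fraction: float = 1.0
    attrition: float = 0.0
    alpha: float = 0.05
    horizon_years: float = 2.0

    @property
    def n_eff(self) -> int:
        return int(round(self.n_per_arm * (1.0 - self.attrition)))

    @property
    def delta(self) -> float:
        return self.effect_fraction * max_benefit(
            self.mean_reference_max, self.mean_control
        )

    def validate(self):
        if not 0 < self.alpha < 1:
            raise SpecificationError("alpha must be in (0, 1)")
        if not 0 <= self.attrition < 1:
            raise SpecificationError("attrition must be in [0, 1)")
        if self.n_eff < 2:
            raise SpecificationError("fewer than 2 completers per arm")
        if self.sd_control <= 0 or self.sd_reference <= 0:
            raise SpecificationError("SDs must be positive")


def power_two_sample(
    scenario: PowerScenario,
    pooled_sd: bool = True,
    exact: bool = False,
) -> float:
    """Two-sided two-sample t-test power.

    Default is the normal approximation
    ``Phi(-z + |delta|/se) + Phi(-z - |delta|/se)`` with
    ``se = sd * sqrt(2 / n_eff)``; ``exact=True`` uses the noncentral-t
    distribution with ``df = 2 n_eff - 2``.  ``pooled_sd`` pools the two
    groups' SDs (equal-variance convention); otherwise the control-arm SD
    alone is used.
    """
    scenario.validate()
    n = scenario.n_eff
    sd = (
        np.sqrt((scenario.sd_control**2 + scenario.sd_reference**2) / 2.0)
        if pooled_sd
        else scenario.sd_control
    )
    se = sd * np.sqrt(2.0 / n)
    nc = abs(scenario.delta) / se
    if exact:
        df = 2 * n - 2
        tcrit = stats.t.ppf(1 - scenario.alpha / 2, df)
        return float(
            1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        )
    z = stats.norm.ppf(1 - scenario.alpha / 2)
    return float(stats.norm.cdf(-z + nc) + stats.norm.cdf(-z - nc))


def power_table(
    group_summaries: dict,
    reference_group: str,
    horizons=(2.0, 4.0),
    fractions=(0.2, 1.0),
    n_per_arm: int = 500,
    attrition_by_horizon: dict | None = None,
    alpha: float = 0.05,
    pooled_sd: bool = True,
) -> pd.DataFrame:
    """Power per (group, horizon, effect fraction).

    ``group_summaries`` maps group name to {horizon: (mean, sd)}; the
    reference group defines the maximum benefit at each horizon.  Default
    attrition is 10% at 2 years and 20% at 4 years.
    """
    attrition_by_horizon = attrition_by_horizon or {2.0: 0.10, 4.0: 0.20}
    rows = []
    ref = group_summaries[reference_group]
    for group, summaries in group_summaries.items():
        if group == reference_group:
            continue
        for h in horizons:
            if h not in summaries or h not in ref:
                warnings.warn(f"no summary for group {group!r} at horizon {h}; skipped")
                continue
            mean_c, sd_c = summaries[h]
            mean_r, sd_r = ref[h]
            for frac in fractions:
                scen = PowerScenario(
                    mean_control=mean_c,
                    sd_control=sd_c,
                    mean_reference_max=mean_r,
                    sd_reference=sd_r,
                    n_per_arm=n_per_arm,
                    effect_fraction=frac,
                    attrition=attrition_by_horizon.get(h, 0.0),
                    alpha=alpha,
                    horizon_years=h,
                )
                rows.append(
                    {
                        "group": group,
                        "horizon_years": h,
                        "effect_fraction": frac,
                        "delta": scen.delta,
                        "sd_pooled": np.sqrt((sd_c**2 + sd_r**2) / 2.0),
                        "n_eff": scen.n_eff,
                        "power": power_two_sample(scen, pooled_sd=pooled_sd),
                    }
                )
    return pd.DataFrame(rows)


def group_summaries_from_fit(fit, md, group_masks: dict, horizons=(2.0, 4.0)) -> dict:
    """Model-based (mean, SD) per group and horizon for power scenarios.

    The mean is the back-transformed model mean at the group's covariate
    profile; the SD combines the fitted-mean variance with the subject and
    residual variance, back-propagated through the inverse Box-Cox by the
    delta method (slope of the inverse transform at the mean).
    """
    out = {}
    var_subj = fit.sigma_b**2 + fit.sigma_e**2
    for name, mask in group_masks.items():
        w = md.W[np.repeat(mask, md.n_i)].mean(axis=0)
        tau_g = fit.posterior[mask].mean(axis=0)
        summaries = {}
        for h in horizons:
            B = np.column_stack([[1.0], fit.spline.evaluate([h])])
            mean_T = float(tau_g @ (fit.alpha @ B.ravel()) + w @ fit.gamma)
            # delta-method slope of the inverse Box-Cox at the mean
            if fit.boxcox is not None and fit.boxcox.lam != 0:
                lam = fit.boxcox.lam
                slope = (lam * mean_T + 1.0) ** (1.0 / lam - 1.0)
                mean_raw = float(fit.boxcox.inverse(mean_T))
            else:
                slope, mean_raw = 1.0, mean_T
            summaries[h] = (mean_raw, float(np.sqrt(var_subj) * slope))
        out[name] = summaries
    return out
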