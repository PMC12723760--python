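"""Shared fixtures: small synthetic cohorts with known generating truth."""

import numpy as np
import pandas as pd
import pytest

from pacctraj.cohort import validate_cohort
from pacctraj.simulate import preset_a4learn_like, simulate_cohort


@pytest.fixture(scope="session")
def preset_truth():
    return preset_a4learn_like(n_subjects=400, seed=7)


@pytest.fixture(scope="session")
def small_cohort(preset_truth):
    """400-subject three-class cohort with known truth (session-wide)."""
    cohort, true_class = simulate_cohort(preset_truth)
    return cohort, true_class


@pytest.fixture(scope="session")
def fitted_model(small_cohort, preset_truth):
    """A converged 3-class fit on the session cohort (generating transform)."""
    from pacctraj.lcmm import LcmmSpec, build_model_data, fit_lcmm

    cohort, _ = small_cohort
    spec = LcmmSpec()
    md = build_model_data(cohort, spec, boxcox=preset_truth.boxcox)
    fit = fit_lcmm(md, spec, n_starts=3, seed=1)
    return fit, md


def make_tiny_cohort(n_subjects=2, n_visits=3, seed=0):
    """Hand-sized cohort for I/O and likelihood oracle tests."""
    rng = np.random.default_rng(seed)
    visits = []
    baseline = []
    for i in range(n_subjects):
        sid = f"T{i + 1}"
        times = np.arange(n_visits) * 1.0
        for k, t in enumerate(times):
            visits.append(
                {
                    "subject_id": sid,
                    "time_years": t,
                    "pacc": rng.normal(0, 2),
                    "pacc_version": (k % 2) + 1,
                    "cdr_global": 0.0,
                    "cdr_memory": 0.0,
                }
            )
        baseline.append(
            {
                "subject_id": sid,
                "arm": ["LEARN", "placebo", "solanezumab"][i % 3],
                "ptau217": float(rng.uniform(0.1, 0.5)),
                "amyloid_suvr": float(rng.uniform(1.0, 1.5)),
                "amyloid_centiloid": float(rng.uniform(-10, 100)),
                "apoe4_carrier": int(rng.random() < 0.5),
                "sex_female": int(rng.random() < 0.5),
                "age": float(rng.uniform(65, 85)),
                "education": float(rng.uniform(12, 20)),
                "hippocampal_volume": float(rng.uniform(6000, 8000)),
                "icv": float(rng.uniform(1.3e6, 1.6e6)),
                "tau_pet_composite": np.nan,
            }
        )
    return validate_cohort(pd.DataFrame(visits), pd.DataFrame(baseline))
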