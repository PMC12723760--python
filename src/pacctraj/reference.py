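"""Published A4/LEARN class-count structure as a programmatic fixture.

The reported baseline table gives, per latent class, the study-arm counts,
APOE e4 carrier counts and CDR-progressor counts.  :func:`count_cohort`
realizes those counts as a concrete cohort (one subject per counted unit,
with a two-visit CDR sequence encoding progression status), so summary
percentages can be recomputed from counts rather than copied.
"""

import numpy as np
import pandas as pd

from pacctraj.cohort import CohortData, validate_cohort

#: class -> (LEARN, placebo, solanezumab) counts
ARM_COUNTS = {
    "1_stable": (481, 386, 390),
    "2_slow": (35, 128, 90),
    "3_fast": (3, 49, 67),
}
#: class -> APOE e4 carrier count
APOE_CARRIER_COUNTS = {"1_stable": 525, "2_slow": 160, "3_fast": 88}
#: class -> CDR progressor count
CDR_PROGRESSOR_COUNTS = {"1_stable": 287, "2_slow": 182, "3_fast": 105}


def count_cohort():
    """Cohort realizing the published marginal counts.

    Returns ``(CohortData, labels)`` with one subject per counted unit.
    Covariate values other than the counted attributes are nominal
    placeholders; only counts and the derived percentages are meaningful.
    """
    visits, baseline, labels = [], [], {}
    i = 0
    for cls, arms in ARM_COUNTS.items():
        arm_list = (
            ["LEARN"] * arms[0] + ["placebo"] * arms[1] + ["solanezumab"] * arms[2]
        )
        carriers = APOE_CARRIER_COUNTS[cls]
        progressors = CDR_PROGRESSOR_COUNTS[cls]
        for j, arm in enumerate(arm_list):
            i += 1
            sid = f"P{i:04d}"
            labels[sid] = cls
            prog = j < progressors
            baseline.append(
                {
                    "subject_id": sid,
                    "arm": arm,
                    "ptau217": 0.2,
                    "amyloid_suvr": 1.1,
                    "amyloid_centiloid": 40.0,
                    "apoe4_carrier": int(j < carriers),
                    "sex_female": j % 2,
                    "age": 71.0,
                    "education": 16.0,
                    "hippocampal_volume": 7000.0 + (j * 37) % 101,
                    "icv": 1.5e6 + 10 * j,
                    "tau_pet_composite": np.nan,
                }
            )
            for t, cdr in [(0.0, 0.0), (1.0, 0.5 if prog else 0.0)]:
                visits.append(
                    {
                        "subject_id": sid,
                        "time_years": t,
                        "pacc": 0.0,
                        "pacc_version": 1,
                        "cdr_global": cdr,
                        "cdr_memory": cdr,
                    }
                )
    cohort = validate_cohort(pd.DataFrame(visits), pd.DataFrame(baseline))
    return cohort, labels
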