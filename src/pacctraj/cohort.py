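"""Cohort data model, CSV I/O, validation, and descriptive summaries.

The universal pipeline input is a :class:`CohortData`: a long-format visits
table (one row per subject-visit, with the PACC outcome, CDR scores, and
optional longitudinal biomarkers) joined to a one-row-per-subject baseline
covariate table.  CSVs are comma-separated UTF-8 with a header row and empty
cells for missing values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pacctraj.errors import ReferentialError, SchemaError, ValidationError

VISIT_COLUMNS = [
    "subject_id",
    "time_years",
    "pacc",
    "pacc_version",
    "cdr_global",
    "cdr_memory",
    "amyloid_centiloid",
    "ptau217",
    "tau_mtl_suvr",
    "tau_neo_suvr",
    "hippocampal_volume",
]
#: Columns that must be present in the visits CSV (the rest are optional).
VISIT_REQUIRED = ["subject_id", "time_years", "pacc", "pacc_version"]

BASELINE_COLUMNS = [
    "subject_id",
    "arm",
    "ptau217",
    "amyloid_suvr",
    "amyloid_centiloid",
    "apoe4_carrier",
    "sex_female",
    "age",
    "education",
    "hippocampal_volume",
    "icv",
    "tau_pet_composite",
]
BASELINE_REQUIRED = [c for c in BASELINE_COLUMNS if c != "tau_pet_composite"]

ARMS = ("LEARN", "placebo", "solanezumab")


@dataclass
class CohortData:
    """Long-format visits joined to one-row-per-subject baseline covariates.

    Invariants (enforced by :func:`validate_cohort`): every visit subject
    appears in baseline, every subject has at least one visit, visits are
    sorted by (subject, time), and each subject's first visit is at time 0.
    """

    visits: pd.DataFrame
    baseline: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.baseline)

    @property
    def subject_ids(self):
        return self.baseline["subject_id"].to_numpy()

    def subset(self, subject_ids) -> "CohortData":
        """Cohort restricted to the given subjects (order of baseline kept)."""
        keep = set(subject_ids)
        return CohortData(
            visits=self.visits[self.visits["subject_id"].isin(keep)].reset_index(drop=True),
            baseline=self.baseline[self.baseline["subject_id"].isin(keep)].reset_index(
                drop=True
            ),
        )


def validate_cohort(visits: pd.DataFrame, baseline: pd.DataFrame) -> CohortData:
    """Validate and canonicalize raw tables into a :class:`CohortData`.

    Re-anchors each subject's times so the earliest visit is 0 (time is
    years since the subject's first visit) and sorts visits by
    (subject, time).
    """
    for col in VISIT_REQUIRED:
        if col not in visits.columns:
            raise SchemaError(f"visits table missing required column '{col}'")
    for col in BASELINE_REQUIRED:
        if col not in baseline.columns:
            raise SchemaError(f"baseline table missing required column '{col}'")

    dup = baseline["subject_id"][baseline["subject_id"].duplicated()]
    if len(dup):
        raise ValidationError(
            f"duplicate baseline rows for subjects {sorted(set(dup))[:5]}"
        )

    known = set(baseline["subject_id"])
    unknown = sorted(set(visits["subject_id"]) - known)
    if unknown:
        raise ReferentialError(
            f"visit subjects not present in baseline: {unknown[:5]}"
        )
    no_visits = sorted(known - set(visits["subject_id"]))
    if no_visits:
        raise ReferentialError(
            f"baseline subjects with no visits: {no_visits[:5]}"
        )

    bad_arm = set(baseline["arm"]) - set(ARMS)
    if bad_arm:
        raise ValidationError(f"unknown arm values {sorted(bad_arm)}; expected {ARMS}")

    visits = visits.copy()
    visits["time_years"] = pd.to_numeric(visits["time_years"])
    if (visits["time_years"] < 0).any():
        raise ValidationError("negative visit times")
    visits = visits.sort_values(["subject_id", "time_years"], kind="mergesort")
    visits["time_years"] -= visits.groupby("subject_id")["time_years"].transform("min")
    for col in VISIT_COLUMNS:
        if col not in visits.columns:
            visits[col] = np.nan
    visits = visits[VISIT_COLUMNS].reset_index(drop=True)

    baseline = baseline.copy()
    if "tau_pet_composite" not in baseline.columns:
        baseline["tau_pet_composite"] = np.nan
    baseline["active_treatment"] = (baseline["arm"] == "solanezumab").astype(int)
    baseline = baseline.reset_index(drop=True)
    return CohortData(visits=visits, baseline=baseline)


def read_cohort(visits_path, baseline_path) -> CohortData:
    """Read and validate a cohort from two CSV files."""
    visits = pd.read_csv(visits_path, float_precision="round_trip")
    baseline = pd.read_csv(baseline_path, float_precision="round_trip")
    return validate_cohort(visits, baseline)


def write_cohort(cohort: CohortData, visits_path, baseline_path):
    """Write a cohort back to CSV (canonical column order, empty = missing)."""
    cohort.visits[VISIT_COLUMNS].to_csv(visits_path, index=False)
    cols = [c for c in BASELINE_COLUMNS if c in cohort.baseline.columns]
    cohort.baseline[cols].to_csv(baseline_path, index=False)


# ---------------------------------------------------------------------------
# CDR progression
# ---------------------------------------------------------------------------

def derive_cdr_progression(cdr_global_sequence):
    """CDR progression flag for one subject's time-ordered CDR Global scores.

    A subject progresses (returns 1) when some pair of consecutive
    non-missing CDR assessments are both > 0, or when the last non-missing
    assessment is > 0.  Missing assessments are skipped: "consecutive" means
    consecutive among observed CDR visits, so inserting missing visits
    cannot break an observed run.  Returns ``None`` when every assessment is
    missing (the subject is excluded from progression summaries).
    """
    vals = np.asarray(
        [v for v in np.asarray(cdr_global_sequence, dtype=float) if np.isfinite(v)]
    )
    if vals.size == 0:
        return None
    if vals[-1] > 0:
        return 1
    pos = vals > 0
    if np.any(pos[1:] & pos[:-1]):
        return 1
    return 0


def cdr_progression_by_subject(cohort: CohortData) -> pd.Series:
    """Per-subject progression flags (None where CDR is entirely missing)."""
    out = {}
    for sid, grp in cohort.visits.groupby("subject_id", sort=False):
        out[sid] = derive_cdr_progression(grp["cdr_global"].to_numpy())
    return pd.Series(out, name="cdr_progressor")


# ---------------------------------------------------------------------------
# Table-1-style summaries
# ---------------------------------------------------------------------------

CONTINUOUS_SUMMARY_VARS = [
    ("age", "Age, y"),
    ("education", "Education, y"),
    ("ptau217", "P-tau217, U/mL"),
    ("amyloid_centiloid", "Amyloid PET, CL"),
    ("hipp_atrophy_z", "Hipp. atrophy, z"),
    ("tau_pet_composite", "Tau PET, SUVr"),
    ("baseline_pacc", "PACC"),
]

CATEGORICAL_SUMMARY_VARS = [
    ("arm", "Group"),
    ("sex_female", "Female"),
    ("apoe4_carrier", "APOE e4 carrier"),
]


@dataclass
class ClassSummary:
    """Descriptive summary by latent class.

    ``continuous``: rows (variable, class) with n/mean/sd.
    ``categorical``: rows (variable, level, class) with count/pct.
    ``arm_by_class``: arm x class count crosstab (includes margins).
    Percentages are always count/denominator of the same table.
    """

    continuous: pd.DataFrame
    categorical: pd.DataFrame
    arm_by_class: pd.DataFrame
    class_counts: pd.Series

    def to_text(self) -> str:
        lines = ["Baseline characteristics by latent class", ""]
        counts = " | ".join(f"{c}: n={n}" for c, n in self.class_counts.items())
        lines.append(counts)
        lines.append("")
        for var, grp in self.continuous.groupby("variable", sort=False):
            cells = [
                f"{row['class']}: {row['mean']:.2f} ({row['sd']:.2f})"
                if row["n"] > 0
                else f"{row['class']}: --"
                for _, row in grp.iterrows()
            ]
            lines.append(f"{var:24s} " + " | ".join(cells))
        for (var, level), grp in self.categorical.groupby(["variable", "level"], sort=False):
            cells = [
                f"{row['class']}: {int(row['count'])} ({row['pct']:.1f}%)"
                for _, row in grp.iterrows()
            ]
            lines.append(f"{var} = {level!s:12s} " + " | ".join(cells))
        return "\n".join(lines)


def summarize_by_class(cohort: CohortData, class_labels: dict) -> ClassSummary:
    """Table-1-style descriptive statistics per latent class and overall.

    ``class_labels`` maps subject_id to a class label (any hashable; the
    summary orders classes by sorted label and appends an "Overall" column).
    Continuous covariates: mean (SD).  Categorical: count (%).  Also counts
    CDR progressors via :func:`derive_cdr_progression`; subjects with no CDR
    data are excluded from that denominator.
    """
    missing = set(cohort.baseline["subject_id"]) - set(class_labels)
    if missing:
        raise ValidationError(f"unlabelled subjects: {sorted(missing)[:5]}")

    df = cohort.baseline.copy()
    df["class"] = df["subject_id"].map(class_labels)

    # derived columns used in the summary
    first = cohort.visits.groupby("subject_id", sort=False).first()
    df["baseline_pacc"] = df["subject_id"].map(first["pacc"])
    if "hipp_atrophy_z" not in df.columns:
        from pacctraj.transforms import residualize_and_z

        ok = df["hippocampal_volume"].notna() & df["icv"].notna()
        df["hipp_atrophy_z"] = np.nan
        if ok.sum() >= 3:
            df.loc[ok, "hipp_atrophy_z"] = residualize_and_z(
                df.loc[ok, "hippocampal_volume"].to_numpy(),
                df.loc[ok, "icv"].to_numpy(),
            )
    prog = cdr_progression_by_subject(cohort)
    df["cdr_progressor"] = df["subject_id"].map(prog)

    classes = sorted(df["class"].unique())
    groups = [(c, df[df["class"] == c]) for c in classes] + [("Overall", df)]

    cont_rows = []
    for var, _label in CONTINUOUS_SUMMARY_VARS:
        if var not in df.columns:
            continue
        for cname, sub in groups:
            vals = pd.to_numeric(sub[var], errors="coerce").dropna()
            cont_rows.append(
                {
                    "variable": var,
                    "class": cname,
                    "n": int(len(vals)),
                    "mean": vals.mean() if len(vals) else np.nan,
                    "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                }
            )

    cat_rows = []
    cat_vars = CATEGORICAL_SUMMARY_VARS + [("cdr_progressor", "CDR Progressor")]
    for var, _label in cat_vars:
        if var not in df.columns:
            continue
        levels = sorted(v for v in df[var].dropna().unique())
        for level in levels:
            for cname, sub in groups:
                denom = int(sub[var].notna().sum())
                count = int((sub[var] == level).sum())
                cat_rows.append(
                    {
                        "variable": var,
                        "level": level,
                        "class": cname,
                        "count": count,
                        "denom": denom,
                        "pct": 100.0 * count / denom if denom else np.nan,
                    }
                )

    arm_by_class = pd.crosstab(df["arm"], df["class"], margins=True, margins_name="Overall")
    class_counts = df["class"].value_counts().reindex(classes).rename("n")
    return ClassSummary(
        continuous=pd.DataFrame(cont_rows),
        categorical=pd.DataFrame(cat_rows),
        arm_by_class=arm_by_class,
        class_counts=class_counts,
    )
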