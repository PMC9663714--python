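"""Cohorting: event tables -> filtered, cohort-assigned analysis snapshots.

A *snapshot* is a pair of consecutive HbA1c lab events for one patient.
Snapshots are retained when the observation period is 90-365 days and the
index value is >= 9% (poorly controlled disease). The treatment regimen of
a snapshot is the set of drug classes whose prescriptions cover the
terminal lab date (days supply plus a 30-day non-adherence grace period);
a regimen change during the snapshot is thereby attributed to the new
regimen. Each retained snapshot is assigned to one of ten clinical cohorts
(A-J) by insulin status at the index lab, age, and unweighted Charlson
comorbidity count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from glycorank.simulate import (
    CHARLSON_CATEGORIES,
    EXCLUSION_CATEGORIES,
    RACE_GROUPS,
    regimen_key,
)

__all__ = [
    "GRACE_PERIOD_DAYS",
    "MIN_SNAPSHOT_DAYS",
    "MAX_SNAPSHOT_DAYS",
    "MIN_INDEX_HBA1C",
    "COHORT_LABELS",
    "apply_exclusions",
    "build_snapshots",
    "attribute_treatment",
    "compute_cci",
    "assign_cohort",
    "build_snapshot_table",
    "ConfounderImputer",
    "split_train_test",
    "cohort_summary",
]

logger = logging.getLogger(__name__)

GRACE_PERIOD_DAYS = 30
MIN_SNAPSHOT_DAYS = 90
MAX_SNAPSHOT_DAYS = 365
MIN_INDEX_HBA1C = 9.0
MIN_ADULT_AGE = 18.0
DAYS_PER_YEAR = 365.25

COHORT_LABELS = tuple("ABCDEFGHIJ")

#: Numeric confounders (beyond comorbidity flags) entering the propensity
#: model. Race fractions are collapsed to the non-reference groups.
NUMERIC_CONFOUNDERS = (
    "age_years",
    "sex_male",
    "index_hba1c",
    "egfr",
    "creatinine",
    "zcta_income",
    "zcta_frac_black",
    "zcta_frac_asian",
    "zcta_frac_other",
)
FLAG_CONFOUNDERS = tuple(f"cc_{c}" for c in CHARLSON_CATEGORIES)
CONFOUNDER_COLUMNS = NUMERIC_CONFOUNDERS + FLAG_CONFOUNDERS

#: Fields the source data never lacks; absence is a data error, not a
#: missingness pattern to impute.
NEVER_IMPUTED = ("age_years", "sex_male", "index_hba1c")


@dataclass
class Snapshot:
    patient_id: str
    index_day: int
    terminal_day: int
    index_hba1c: float
    terminal_hba1c: float
    regimen: str
    prior_regimen: str | None
    insulin_at_index: bool

    @property
    def delta_hba1c(self) -> float:
        return self.terminal_hba1c - self.index_hba1c

    @property
    def duration(self) -> int:
        return self.terminal_day - self.index_day


def apply_exclusions(histories, drop_log: list | None = None):
    """Drop patients carrying exclusion diagnoses or under 18 at any index lab.

    Exclusions: type-1 diabetes, gestational diabetes, diabetic
    ketoacidosis, cystic fibrosis, solid-organ transplant, age < 18 at any
    HbA1c lab. ``drop_log`` (optional) collects (patient_id, reason) pairs.
    """
    kept = []
    for h in histories:
        reason = None
        flagged = set(h.diagnoses.condition_category) & set(EXCLUSION_CATEGORIES)
        if flagged:
            reason = f"excluded_condition:{sorted(flagged)[0]}"
        else:
            hba1c = h.labs[h.labs.test_name == "hba1c"]
            if len(hba1c):
                birth = h.demographics["birth_day"]
                min_age = (hba1c.day.min() - birth) / DAYS_PER_YEAR
                if min_age < MIN_ADULT_AGE:
                    reason = "under_18_at_index"
        if reason is None:
            kept.append(h)
        else:
            if drop_log is not None:
                drop_log.append((h.patient_id, reason))
            logger.debug("dropped patient %s: %s", h.patient_id, reason)
    return kept


def _attribute(fill, supply, classes, at_day):
    mask = (fill <= at_day) & (at_day < fill + supply + GRACE_PERIOD_DAYS)
    found = set(classes[mask])
    return regimen_key(found) if found else None


def attribute_treatment(prescriptions: pd.DataFrame, at_day: int):
    """Regimen covering ``at_day``: classes with fill <= day < fill + supply + 30.

    Returns the canonical regimen string, or None when no class covers the
    day (an untreated interval).
    """
    if not len(prescriptions):
        return None
    supply = prescriptions.days_supply.to_numpy()
    if (supply < 0).any():
        raise ValueError("negative days_supply")
    return _attribute(
        prescriptions.fill_day.to_numpy(), supply,
        prescriptions.drug_class.to_numpy(), at_day,
    )


def build_snapshots(history, drop_log: list | None = None):
    """One candidate snapshot per consecutive HbA1c pair; keep those in-window.

    Retention: duration in [90, 365] days, index value >= 9%, and a
    non-empty regimen at the terminal lab. Duplicate same-day HbA1c values
    keep the last recorded (with a warning). Patients with a single HbA1c
    lab yield no snapshots.
    """
    labs = history.labs[history.labs.test_name == "hba1c"].sort_values(
        "day", kind="stable"
    )
    if labs.day.duplicated().any():
        logger.warning(
            "patient %s has duplicate same-day HbA1c values; keeping last",
            history.patient_id,
        )
        labs = labs.drop_duplicates("day", keep="last")
    days = labs.day.to_numpy()
    values = labs.value.to_numpy()
    rx = history.prescriptions
    if len(rx):
        rx_fill = rx.fill_day.to_numpy()
        rx_supply = rx.days_supply.to_numpy()
        rx_class = rx.drug_class.to_numpy()
        if (rx_supply < 0).any():
            raise ValueError("negative days_supply")
    else:
        rx_fill = rx_supply = rx_class = np.array([])
    out = []
    for k in range(len(days) - 1):
        t0, t1 = int(days[k]), int(days[k + 1])
        v0, v1 = float(values[k]), float(values[k + 1])
        duration = t1 - t0
        reason = None
        if not MIN_SNAPSHOT_DAYS <= duration <= MAX_SNAPSHOT_DAYS:
            reason = "duration_out_of_window"
        elif v0 < MIN_INDEX_HBA1C:
            reason = "index_below_9"
        if reason is None:
            regimen = (
                _attribute(rx_fill, rx_supply, rx_class, t1) if len(rx) else None
            )
            if regimen is None:
                reason = "untreated"
        if reason is not None:
            if drop_log is not None:
                drop_log.append((history.patient_id, t0, reason))
            continue
        prior = _attribute(rx_fill, rx_supply, rx_class, t0) if len(rx) else None
        insulin = prior is not None and "insulin" in prior.split("+")
        out.append(
            Snapshot(
                patient_id=history.patient_id,
                index_day=t0,
                terminal_day=t1,
                index_hba1c=v0,
                terminal_hba1c=v1,
                regimen=regimen,
                prior_regimen=prior,
                insulin_at_index=insulin,
            )
        )
    return out


def compute_cci(diagnoses: pd.DataFrame, as_of_day: int) -> int:
    """Unweighted Charlson count: distinct comorbidity categories on record
    up to ``as_of_day`` (each category contributes 1 regardless of repeats)."""
    if not len(diagnoses):
        return 0
    past = diagnoses[diagnoses.day <= as_of_day].condition_category
    return int(past[past.isin(CHARLSON_CATEGORIES)].nunique())


def assign_cohort(insulin_user: bool, age_years: float, cci: int) -> str:
    """Map (insulin status at index, age, CCI) to one of the ten cohorts A-J.

    Non-users under 65 split at CCI <=2 / 3-4 / >=5 (A/B/C); non-users 65+
    at CCI <5 / >=5 (D/E); insulin users mirror this as F/G/H and I/J.
    Total on its domain: every input maps to exactly one label.
    """
    if not insulin_user:
        if age_years < 65:
            if cci <= 2:
                return "A"
            return "B" if cci < 5 else "C"
        return "D" if cci < 5 else "E"
    if age_years < 65:
        if cci <= 2:
            return "F"
        return "G" if cci < 5 else "H"
    return "I" if cci < 5 else "J"


def build_snapshot_table(histories, drop_log: list | None = None) -> pd.DataFrame:
    """Assemble the per-snapshot analysis table (one row per snapshot).

    Columns: snapshot identity and outcome, regimen strings, cohort label,
    and the raw (unimputed) confounder vector — comorbidity flags, most
    recent EGFR/creatinine at the index day, age, sex, area income and race
    fractions, and the index HbA1c.
    """
    rows = []
    for h in histories:
        demo = h.demographics
        birth = demo["birth_day"]
        dx_day = h.diagnoses.day.to_numpy() if len(h.diagnoses) else np.array([])
        dx_cat = (
            h.diagnoses.condition_category.to_numpy()
            if len(h.diagnoses)
            else np.array([])
        )
        lab_day = h.labs.day.to_numpy()
        lab_test = h.labs.test_name.to_numpy()
        lab_value = h.labs.value.to_numpy()

        def most_recent(test, as_of):
            sel = (lab_test == test) & (lab_day <= as_of)
            if not sel.any():
                return np.nan
            return float(lab_value[sel][np.argmax(lab_day[sel])])

        for s in build_snapshots(h, drop_log=drop_log):
            age = (s.index_day - birth) / DAYS_PER_YEAR
            flags = set(dx_cat[dx_day <= s.index_day]) & set(CHARLSON_CATEGORIES)
            cci = len(flags)
            row = {
                "patient_id": s.patient_id,
                "index_day": s.index_day,
                "terminal_day": s.terminal_day,
                "duration_days": s.duration,
                "index_hba1c": s.index_hba1c,
                "terminal_hba1c": s.terminal_hba1c,
                "delta_hba1c": s.delta_hba1c,
                "regimen": s.regimen,
                "prior_regimen": s.prior_regimen or "",
                "insulin_at_index": s.insulin_at_index,
                "age_years": age,
                "sex_male": 1.0 if demo["sex"] == "M" else 0.0,
                "cci": cci,
                "cohort": assign_cohort(s.insulin_at_index, age, cci),
                "egfr": most_recent("egfr", s.index_day),
                "creatinine": most_recent("creatinine", s.index_day),
                "zcta_income": demo.get("zcta_income", np.nan),
            }
            for g in RACE_GROUPS:
                row[f"zcta_frac_{g}"] = demo.get(f"zcta_frac_{g}", np.nan)
            for c in CHARLSON_CATEGORIES:
                row[f"cc_{c}"] = 1.0 if c in flags else 0.0
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["patient_id", "index_day"], kind="stable").reset_index(
            drop=True
        )
    return df


class ConfounderImputer:
    """Mean-impute missing numeric confounders, fit on training data only.

    sklearn-style transformer: ``fit`` learns per-column training means
    (within a cohort when used per cohort), ``transform`` fills missing
    entries with those means and appends a ``<col>_missing`` indicator for
    every column that required imputation. Age, sex, and the index HbA1c
    are never imputed — a missing value there raises.
    """

    def __init__(self, columns=None):
        self.columns = columns

    def fit(self, df: pd.DataFrame):
        cols = list(self.columns) if self.columns is not None else [
            c for c in NUMERIC_CONFOUNDERS if c not in NEVER_IMPUTED
        ]
        for c in NEVER_IMPUTED:
            if c in df.columns and df[c].isna().any():
                raise ValueError(f"{c} must never be missing")
        self.columns_ = cols
        means = {}
        for c in cols:
            m = df[c].mean(skipna=True)
            if pd.isna(m):
                # Every training value missing: fall back to zero and warn.
                logger.warning("all values missing for %s; imputing 0", c)
                m = 0.0
            means[c] = float(m)
        self.means_ = means
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "means_"):
            raise RuntimeError("ConfounderImputer not fitted")
        for c in NEVER_IMPUTED:
            if c in df.columns and df[c].isna().any():
                raise ValueError(f"{c} must never be missing")
        out = df.copy()
        for c in self.columns_:
            missing = out[c].isna()
            out[f"{c}_missing"] = missing.astype(float)
            out.loc[missing, c] = self.means_[c]
        return out

    def fit_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return self.fit(df).transform(df)

    def get_params(self, deep=True):
        return {"columns": self.columns}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self


def imputed_confounder_columns(df: pd.DataFrame):
    """Confounder columns present in an imputed snapshot table, including
    the missingness indicators."""
    cols = [c for c in CONFOUNDER_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c.endswith("_missing")]
    return cols


def split_train_test(df: pd.DataFrame, fraction: float = 0.8, seed: int = 0,
                     by_patient: bool = False):
    """Random train/test split with a covariate-comparison report.

    Snapshot-level by default; ``by_patient=True`` keeps all snapshots of a
    patient on the same side (snapshot-level splitting lets a patient span
    both sets). Returns ``(train, test, report)`` where ``report`` lists
    the standardized mean difference of every numeric column between the
    two sets.
    """
    if not len(df):
        raise ValueError("cannot split an empty snapshot table")
    rng = np.random.default_rng(seed)
    if by_patient:
        patients = df.patient_id.unique()
        n_train = int(round(fraction * len(patients)))
        shuffled = rng.permutation(patients)
        train_ids = set(shuffled[:n_train])
        mask = df.patient_id.isin(train_ids).to_numpy()
    else:
        n_train = int(round(fraction * len(df)))
        idx = rng.permutation(len(df))
        mask = np.zeros(len(df), dtype=bool)
        mask[idx[:n_train]] = True
    train, test = df[mask].reset_index(drop=True), df[~mask].reset_index(drop=True)

    rows = []
    for c in df.columns:
        if not pd.api.types.is_numeric_dtype(df[c]):
            continue
        a, b = train[c].dropna(), test[c].dropna()
        if not len(a) or not len(b):
            continue
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        smd = 0.0 if pooled == 0 or np.isnan(pooled) else abs(a.mean() - b.mean()) / pooled
        rows.append({"column": c, "train_mean": a.mean(), "test_mean": b.mean(),
                     "smd": smd})
    return train, test, pd.DataFrame(rows)


def cohort_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort table: snapshot count, patient count, distinct regimens."""
    rows = []
    for label in COHORT_LABELS:
        sub = df[df.cohort == label]
        rows.append(
            {
                "cohort": label,
                "n_snapshots": len(sub),
                "n_patients": sub.patient_id.nunique(),
                "n_treatments": sub.regimen.nunique(),
            }
        )
    return pd.DataFrame(rows)
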