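"""Synthetic longitudinal claims generator with known causal ground truth.

Emulates the statistical structure a comparative-effectiveness analysis of
antihyperglycemic regimens assumes: per-patient dated HbA1c trajectories
starting in the poorly controlled range (index values around 9-13%),
multi-class drug regimens (1-5 concomitant classes) whose assignment is
confounded by clinical and social covariates, and additive per-regimen
effects on the change in HbA1c between consecutive labs.

Treatment assignment follows a multinomial logistic model over standardized
covariates; the coefficients are drawn once per simulation and scaled by
``confounding_strength``, so the true propensity of every snapshot is known
and recoverable. The terminal HbA1c of each inter-lab interval is

    terminal = index + true_effect(regimen) + x' beta + Normal(0, sd)

with the same covariates entering assignment and outcome — the source of
confounding. A :class:`GroundTruth` sidecar records assigned regimens, true
effects and true propensities per snapshot; the analysis pipeline never
reads it.

Dates are integer day offsets from a simulation epoch (day 0 is roughly the
first HbA1c lab). Diagnoses are abstract comorbidity-category codes, one
per Charlson category, not ICD codes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DRUG_CLASSES",
    "DEFAULT_REGIMEN_CATALOG",
    "RegimenSpec",
    "SimulationConfig",
    "GroundTruth",
    "PatientHistory",
    "simulate_population",
    "write_tables",
    "read_tables",
]

DRUG_CLASSES = (
    "metformin",
    "sulfonylurea",
    "dpp4",
    "sglt2",
    "glp1",
    "thiazolidinedione",
    "insulin",
)

#: Charlson comorbidity categories used as chronic-condition flags.
CHARLSON_CATEGORIES = (
    "myocardial_infarction",
    "congestive_heart_failure",
    "peripheral_vascular_disease",
    "cerebrovascular_disease",
    "dementia",
    "chronic_pulmonary_disease",
    "rheumatic_disease",
    "peptic_ulcer_disease",
    "liver_disease",
    "hemiplegia",
    "renal_disease",
    "malignancy",
    "metastatic_tumor",
    "hiv_aids",
)

#: Condition categories that exclude a patient from the analysis.
EXCLUSION_CATEGORIES = (
    "type1_diabetes",
    "gestational_diabetes",
    "diabetic_ketoacidosis",
    "cystic_fibrosis",
    "solid_organ_transplant",
)

RACE_GROUPS = ("white", "black", "asian", "other")


def regimen_key(classes) -> str:
    """Canonical string form of a regimen: sorted '+'-joined class names."""
    classes = sorted(set(classes))
    if not classes:
        raise ValueError("a regimen must contain at least one drug class")
    return "+".join(classes)


@dataclass(frozen=True)
class RegimenSpec:
    """One catalog entry: a drug-class set and its true additive effect.

    ``true_effect`` is the additive change in HbA1c percentage points
    attributable to the regimen over one snapshot; negative = reduction.
    """

    classes: frozenset
    true_effect: float

    def __post_init__(self):
        if not self.classes:
            raise ValueError("regimen must be non-empty")
        if not 1 <= len(self.classes) <= 5:
            raise ValueError("regimens span 1-5 drug classes")
        unknown = set(self.classes) - set(DRUG_CLASSES)
        if unknown:
            raise ValueError(f"unknown drug classes: {sorted(unknown)}")

    @property
    def key(self) -> str:
        return regimen_key(self.classes)


def _spec(classes, effect):
    return RegimenSpec(frozenset(classes), effect)


#: Default regimen catalog: monotherapies up to a five-class combination,
#: with effect sizes in the range reported for add-on therapy in poorly
#: controlled type-2 diabetes (roughly -0.9 to -1.9 HbA1c points).
DEFAULT_REGIMEN_CATALOG = (
    _spec(["metformin"], -0.9),
    _spec(["glp1"], -1.1),
    _spec(["insulin"], -1.2),
    _spec(["metformin", "sulfonylurea"], -1.2),
    _spec(["metformin", "glp1"], -1.7),
    _spec(["metformin", "sglt2"], -1.5),
    _spec(["metformin", "insulin"], -1.6),
    _spec(["metformin", "sulfonylurea", "dpp4"], -1.0),
    _spec(["metformin", "sglt2", "glp1"], -1.9),
    _spec(
        ["metformin", "sulfonylurea", "dpp4", "thiazolidinedione", "insulin"], -1.3
    ),
)

#: Reference (mean, sd) used to standardize covariates inside the
#: assignment and outcome models; stored in GroundTruth so the true
#: propensity model is exactly invertible.
_COVARIATE_REFERENCE = {
    "age": (55.0, 17.32),
    "sex": (0.5, 0.5),
    "cci": (1.4, 1.3),
    "egfr": (94.0, 18.0),
    "creatinine": (0.9, 0.25),
    "log_income": (np.log(55000.0), 0.4),
    "index_hba1c": (10.3, 1.0),
}
ASSIGNMENT_COVARIATES = tuple(_COVARIATE_REFERENCE)

#: Fixed clinical-severity axis (standardized-covariate scale) shared by
#: the assignment and outcome models; the backbone of the confounding.
_SEVERITY_LOADING = {
    "age": 0.3,
    "sex": 0.0,
    "cci": 0.5,
    "egfr": -0.4,
    "creatinine": 0.4,
    "log_income": -0.2,
    "index_hba1c": 0.6,
}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults define the reference study conditions.

    Parameters
    ----------
    n_patients
        Number of simulated members.
    drug_classes
        Universe of antihyperglycemic class identifiers.
    regimen_catalog
        The regimens a snapshot can be assigned to, each with a known
        additive HbA1c effect.
    confounding_strength
        Scale of the covariate coefficients in the multinomial assignment
        model. 0 means assignment is independent of covariates.
    outcome_noise_sd
        SD (HbA1c points) of the Gaussian noise on the change in HbA1c.
    outcome_covariate_scale
        Scale of the covariate coefficients in the outcome model; together
        with ``confounding_strength`` > 0 this makes naive contrasts biased.
    labs_per_patient
        Inclusive (lo, hi) range of HbA1c lab counts per patient.
    inter_lab_gap_days
        Inclusive (lo, hi) range of days between consecutive HbA1c labs.
    missingness_rates
        Per-covariate probability that the value is absent from the emitted
        tables (``egfr``, ``creatinine``, ``zcta_income``, ``zcta_race``).
    exclusion_flag_rate
        Per-category probability of carrying one of the exclusion
        diagnoses (type-1 diabetes, gestational diabetes, ketoacidosis,
        cystic fibrosis, solid-organ transplant).
    lead_in_rate
        Probability that a patient has a prescription covering the first
        index lab (defines insulin status at index for first snapshots).
    seed
        Seed for the single generator driving every draw.
    """

    n_patients: int = 2000
    drug_classes: tuple = DRUG_CLASSES
    regimen_catalog: tuple = DEFAULT_REGIMEN_CATALOG
    confounding_strength: float = 1.0
    outcome_noise_sd: float = 1.0
    outcome_covariate_scale: float = 0.3
    labs_per_patient: tuple = (2, 4)
    inter_lab_gap_days: tuple = (95, 360)
    missingness_rates: dict = field(
        default_factory=lambda: {
            "egfr": 0.10,
            "creatinine": 0.10,
            "zcta_income": 0.05,
            "zcta_race": 0.05,
        }
    )
    exclusion_flag_rate: float = 0.0
    lead_in_rate: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not self.regimen_catalog:
            raise ValueError("regimen_catalog must be non-empty")
        for spec in self.regimen_catalog:
            unknown = set(spec.classes) - set(self.drug_classes)
            if unknown:
                raise ValueError(f"regimen uses classes outside drug_classes: {unknown}")
        if self.outcome_noise_sd <= 0:
            raise ValueError("outcome_noise_sd must be > 0")
        if self.confounding_strength < 0:
            raise ValueError("confounding_strength must be >= 0")
        for name, p in self.missingness_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missingness rate for {name} outside [0, 1]")
        if not 0.0 <= self.lead_in_rate <= 1.0:
            raise ValueError("lead_in_rate outside [0, 1]")
        lo, hi = self.labs_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("labs_per_patient must be a nondecreasing range >= 1")
        lo, hi = self.inter_lab_gap_days
        if lo < 1 or hi < lo:
            raise ValueError("inter_lab_gap_days must be a nondecreasing range >= 1")


@dataclass
class PatientHistory:
    """One patient's dated events: labs, prescriptions, diagnoses, demographics."""

    patient_id: str
    demographics: dict
    labs: pd.DataFrame           # columns: day, test_name, value
    prescriptions: pd.DataFrame  # columns: fill_day, drug_class, days_supply
    diagnoses: pd.DataFrame      # columns: day, condition_category


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must not read.

    ``snapshots`` has one row per simulated inter-lab interval keyed by
    (patient_id, index_day), with the assigned regimen, its true effect,
    and the true assignment probability of every catalog regimen
    (columns ``p_<regimen>``). ``gamma`` are the assignment-model
    coefficients (regimen x covariate), ``beta`` the outcome-model
    coefficients, both on the standardized covariate scale.
    """

    snapshots: pd.DataFrame
    gamma: pd.DataFrame
    beta: pd.Series
    regimen_effects: dict
    covariate_reference: dict

    def true_effect(self, regimen: str) -> float:
        return self.regimen_effects[regimen]

    def lookup(self, patient_id: str, index_day: int) -> pd.Series:
        df = self.snapshots
        rows = df[(df.patient_id == patient_id) & (df.index_day == index_day)]
        if rows.empty:
            raise KeyError((patient_id, index_day))
        return rows.iloc[0]

    def true_binary_propensity(self, case: str, comparator: str) -> pd.Series:
        """P(assigned case | assigned case or comparator) per snapshot."""
        pc = self.snapshots[f"p_{case}"]
        pk = self.snapshots[f"p_{comparator}"]
        return pc / (pc + pk)


def _standardize(raw: dict) -> np.ndarray:
    x = np.empty(len(ASSIGNMENT_COVARIATES))
    for j, name in enumerate(ASSIGNMENT_COVARIATES):
        mu, sd = _COVARIATE_REFERENCE[name]
        x[j] = (raw[name] - mu) / sd
    return x


def simulate_population(config: SimulationConfig):
    """Generate patient histories and the matching ground truth.

    Returns ``(histories, truth)`` where ``histories`` is a list of
    :class:`PatientHistory` and ``truth`` a :class:`GroundTruth`.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    catalog = list(config.regimen_catalog)
    keys = [s.key for s in catalog]
    n_cov = len(ASSIGNMENT_COVARIATES)

    # Model coefficients drawn once per simulation. Confounding has a
    # clinically structured core: a fixed "severity" axis (older, more
    # comorbid, worse kidney function, higher index HbA1c) that both
    # attracts more-intensive regimens and attenuates HbA1c reduction,
    # plus a seeded idiosyncratic component per regimen.
    severity = np.array(
        [_SEVERITY_LOADING[name] for name in ASSIGNMENT_COVARIATES]
    )
    intensity = np.array([len(s.classes) for s in catalog], dtype=float)
    intensity -= intensity.mean()
    if intensity.std() > 0:
        intensity /= intensity.std()
    noise = rng.normal(size=(len(catalog), n_cov)) / np.sqrt(n_cov)
    gamma = config.confounding_strength * (
        0.8 * intensity[:, None] * severity[None, :] + 0.4 * noise
    )
    beta = config.outcome_covariate_scale * severity

    histories: list[PatientHistory] = []
    truth_rows: list[dict] = []

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        age0 = rng.uniform(25.0, 85.0)
        birth_day = -int(round(age0 * 365.25))
        sex = int(rng.random() < 0.5)
        income = float(np.exp(rng.normal(np.log(55000.0), 0.4)))
        race = rng.dirichlet([6.0, 2.0, 1.0, 1.0])
        egfr = float(np.clip(rng.normal(94.0, 18.0), 15.0, 150.0))
        creatinine = float(
            np.clip(0.9 - 0.006 * (egfr - 94.0) + rng.normal(0.0, 0.15), 0.4, 3.0)
        )

        # Chronic-condition flags; prevalence rises with age so that the
        # comorbidity count is a genuine confounder.
        p_flag = 1.0 / (1.0 + np.exp(-(-2.2 + 0.03 * (age0 - 55.0))))
        flags = [c for c in CHARLSON_CATEGORIES if rng.random() < p_flag]
        diag_rows = [
            {"day": int(rng.integers(-1500, 0)), "condition_category": c}
            for c in flags
        ]
        if config.exclusion_flag_rate > 0:
            for c in EXCLUSION_CATEGORIES:
                if rng.random() < config.exclusion_flag_rate:
                    diag_rows.append(
                        {"day": int(rng.integers(-1500, 0)), "condition_category": c}
                    )
        cci = len(flags)

        n_labs = int(rng.integers(config.labs_per_patient[0], config.labs_per_patient[1] + 1))
        day0 = int(rng.integers(0, 61))
        gaps = rng.integers(
            config.inter_lab_gap_days[0], config.inter_lab_gap_days[1] + 1, size=max(n_labs - 1, 0)
        )
        lab_days = np.concatenate([[day0], day0 + np.cumsum(gaps)]).astype(int)

        lab_rows = []
        rx_rows = []
        # EGFR / creatinine measured shortly before the first HbA1c unless
        # the covariate is missing from this patient's record.
        miss = config.missingness_rates
        if rng.random() >= miss.get("egfr", 0.0):
            lab_rows.append({"day": day0 - 30, "test_name": "egfr", "value": egfr})
        if rng.random() >= miss.get("creatinine", 0.0):
            lab_rows.append(
                {"day": day0 - 30, "test_name": "creatinine", "value": creatinine}
            )

        index_value = float(np.clip(rng.normal(10.3, 1.0), 7.5, 16.0))

        # Optional lead-in regimen covering the first index lab only.
        base_raw = {
            "age": age0,
            "sex": sex,
            "cci": cci,
            "egfr": egfr,
            "creatinine": creatinine,
            "log_income": np.log(income),
            "index_hba1c": index_value,
        }
        if rng.random() < config.lead_in_rate:
            x = _standardize(base_raw)
            probs = _softmax(gamma @ x)
            r = catalog[rng.choice(len(catalog), p=probs)]
            for cls in sorted(r.classes):
                rx_rows.append(
                    {"fill_day": day0 - 40, "drug_class": cls, "days_supply": 20}
                )

        for k in range(n_labs):
            t_index = int(lab_days[k])
            lab_rows.append(
                {"day": t_index, "test_name": "hba1c", "value": round(index_value, 2)}
            )
            if k == n_labs - 1:
                break
            t_term = int(lab_days[k + 1])
            age_at_index = age0 + t_index / 365.25
            raw = dict(base_raw, age=age_at_index, index_hba1c=index_value)
            x = _standardize(raw)
            probs = _softmax(gamma @ x)
            choice = int(rng.choice(len(catalog), p=probs))
            regimen = catalog[choice]

            # Fills cover the terminal lab (within supply + 30-day grace)
            # but expire before the following snapshot's terminal lab.
            fill_day = t_index + int(rng.integers(1, 16))
            supply = (t_term - fill_day) - 20
            for cls in sorted(regimen.classes):
                rx_rows.append(
                    {"fill_day": fill_day, "drug_class": cls, "days_supply": int(supply)}
                )

            delta = (
                regimen.true_effect
                + float(x @ beta)
                + rng.normal(0.0, config.outcome_noise_sd)
            )
            terminal_value = index_value + delta
            truth_rows.append(
                {
                    "patient_id": pid,
                    "index_day": t_index,
                    "terminal_day": t_term,
                    "regimen": regimen.key,
                    "true_effect": regimen.true_effect,
                    "index_hba1c": round(index_value, 2),
                    **{f"p_{key}": probs[j] for j, key in enumerate(keys)},
                }
            )
            index_value = terminal_value

        demo = {
            "patient_id": pid,
            "birth_day": birth_day,
            "sex": "F" if sex == 0 else "M",
            "zcta_income": (
                np.nan if rng.random() < miss.get("zcta_income", 0.0) else round(income, 2)
            ),
        }
        race_missing = rng.random() < miss.get("zcta_race", 0.0)
        for g, frac in zip(RACE_GROUPS, race):
            demo[f"zcta_frac_{g}"] = np.nan if race_missing else round(float(frac), 4)

        histories.append(
            PatientHistory(
                patient_id=pid,
                demographics=demo,
                labs=pd.DataFrame(lab_rows, columns=["day", "test_name", "value"]),
                prescriptions=pd.DataFrame(
                    rx_rows, columns=["fill_day", "drug_class", "days_supply"]
                ),
                diagnoses=pd.DataFrame(
                    diag_rows, columns=["day", "condition_category"]
                ),
            )
        )

    truth = GroundTruth(
        snapshots=pd.DataFrame(
            truth_rows,
            columns=[
                "patient_id",
                "index_day",
                "terminal_day",
                "regimen",
                "true_effect",
                "index_hba1c",
                *[f"p_{k}" for k in keys],
            ],
        ),
        gamma=pd.DataFrame(gamma, index=keys, columns=ASSIGNMENT_COVARIATES),
        beta=pd.Series(beta, index=ASSIGNMENT_COVARIATES),
        regimen_effects={s.key: s.true_effect for s in catalog},
        covariate_reference=dict(_COVARIATE_REFERENCE),
    )
    return histories, truth


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


_TABLE_COLUMNS = {
    "labs": ["patient_id", "day", "test_name", "value"],
    "prescriptions": ["patient_id", "fill_day", "drug_class", "days_supply"],
    "diagnoses": ["patient_id", "day", "condition_category"],
}


def histories_to_tables(histories) -> dict:
    """Stack per-patient events into the four flat tables."""
    if not histories:
        raise ValueError("histories must be non-empty")
    out = {}
    for name in ("labs", "prescriptions", "diagnoses"):
        frames = []
        for h in histories:
            df = getattr(h, name)
            if len(df):
                frames.append(df.assign(patient_id=h.patient_id))
        cols = _TABLE_COLUMNS[name]
        out[name] = (
            pd.concat(frames, ignore_index=True)[cols]
            if frames
            else pd.DataFrame(columns=cols)
        )
    out["demographics"] = pd.DataFrame([h.demographics for h in histories])
    return out


def write_tables(histories, path) -> dict:
    """Write the four-table schema as headed CSVs under ``path``.

    Returns the mapping of table name to file path.
    """
    tables = histories_to_tables(histories)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in tables.items():
        f = path / f"{name}.csv"
        df.to_csv(f, index=False)
        files[name] = f
    return files


def read_tables(path) -> list:
    """Read the four-table schema back into :class:`PatientHistory` objects."""
    path = Path(path)
    tabs = {}
    for name in ("labs", "prescriptions", "diagnoses", "demographics"):
        f = path / f"{name}.csv"
        if not f.exists():
            raise FileNotFoundError(f"missing table: {f}")
        tabs[name] = pd.read_csv(f)
    histories = []
    for _, demo in tabs["demographics"].iterrows():
        pid = demo["patient_id"]
        labs = tabs["labs"][tabs["labs"].patient_id == pid].drop(columns="patient_id")
        rx = tabs["prescriptions"][tabs["prescriptions"].patient_id == pid].drop(
            columns="patient_id"
        )
        dx = tabs["diagnoses"][tabs["diagnoses"].patient_id == pid].drop(
            columns="patient_id"
        )
        histories.append(
            PatientHistory(
                patient_id=pid,
                demographics=demo.to_dict(),
                labs=labs.reset_index(drop=True),
                prescriptions=rx.reset_index(drop=True),
                diagnoses=dx.reset_index(drop=True),
            )
        )
    return histories


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Serialize the ground-truth sidecar (never read by the pipeline)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    truth.snapshots.to_csv(path / "truth_snapshots.csv", index=False)
    truth.gamma.to_csv(path / "truth_gamma.csv")
    truth.beta.to_csv(path / "truth_beta.csv")
    with open(path / "truth_effects.json", "w") as fh:
        json.dump(truth.regimen_effects, fh, indent=2)
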