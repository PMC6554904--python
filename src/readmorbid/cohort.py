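"""Synthetic hip-fracture case-control cohort generator.

Emulates the structure of a UK primary-care (CPRD-GOLD-style) extract: cases
with a first hip-fracture index date in the 1999-01-01 .. 2013-10-09 study
window and at least three years of prior registration, 2:1 age- and
sex-matched controls, coded comorbidity events scattered over the record,
and death dates driven by a known logistic mortality model.  Because the
mortality model and the latent comorbidity flags are known, every
downstream stage (scoring, model fitting, discrimination) can be validated
against ground truth without access to restricted data.

Conventions
-----------
* sex is encoded 1 = female, 0 = male throughout.
* age at index = index year - year of birth (primary-care extracts supply
  year of birth only).
* controls inherit their matched case's index date as the reference date
  for look-back windows and mortality outcomes.
* latent flags are drawn independently per measure: the charlson and
  elixhauser flag matrices for one patient are not correlated, even for
  categories the two measures share.

Cohort tables are plain pandas DataFrames (see ``PATIENT_COLUMNS`` and
``EVENT_COLUMNS``); dates are datetime64 in memory and ISO-8601 on disk.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .codelists import CodeList

STUDY_START = pd.Timestamp("1999-01-01")
STUDY_END = pd.Timestamp("2013-10-09")
FOLLOWUP_END = pd.Timestamp("2015-12-31")
MIN_REGISTRATION_YEARS = 3

PATIENT_COLUMNS = [
    "patient_id", "sex", "year_of_birth", "registration_start",
    "registration_end", "death_date", "role", "matched_case_id", "index_date",
    "age_at_index",
]
EVENT_COLUMNS = ["patient_id", "event_date", "code"]


@dataclass(frozen=True)
class PatientRecord:
    """One row of the patient table (provided for row-wise interop)."""

    patient_id: str
    sex: int
    year_of_birth: int
    registration_start: pd.Timestamp
    registration_end: pd.Timestamp
    death_date: pd.Timestamp | None
    role: str
    matched_case_id: str | None
    index_date: pd.Timestamp
    age_at_index: int


@dataclass(frozen=True)
class ClinicalEvent:
    """One dated, coded clinical event."""

    patient_id: str
    event_date: pd.Timestamp
    code: str


class ConfigError(ValueError):
    """Invalid generator configuration."""


# Default per-category prevalences for cases.  The relative sizes are a
# plausibility judgement for an elderly hip-fracture population; the overall
# level is calibrated exactly (under cross-category independence, via
# sum log(1-p)) so that P(CCI count = 0) = 0.276 and P(EM count = 0) = 0.092
# match the target cohort's marginals.  Controls are scaled down by
# control_prevalence_scale.
_DEFAULT_PREVALENCE = {
    "charlson": {
        "myocardial_infarction": 0.0851, "congestive_heart_failure": 0.1134,
        "peripheral_vascular": 0.0851, "cerebrovascular": 0.1229,
        "dementia": 0.0945, "chronic_pulmonary": 0.1607, "rheumatic": 0.0473,
        "peptic_ulcer": 0.0662, "liver_mild": 0.0189,
        "diabetes_uncomplicated": 0.1229, "diabetes_complicated": 0.0378,
        "hemiplegia_paraplegia": 0.0284, "renal": 0.0756,
        "malignancy": 0.1134, "liver_moderate_severe": 0.0095,
        "metastatic_solid_tumour": 0.0378, "aids_hiv": 0.0019,
    },
    "elixhauser": {
        "congestive_heart_failure": 0.1084, "cardiac_arrhythmias": 0.1265,
        "valvular_disease": 0.0542, "pulmonary_circulation": 0.0181,
        "peripheral_vascular": 0.0813, "hypertension_uncomplicated": 0.3614,
        "hypertension_complicated": 0.0361, "paralysis": 0.0271,
        "other_neurological": 0.0542, "chronic_pulmonary": 0.1536,
        "diabetes_uncomplicated": 0.1174, "diabetes_complicated": 0.0361,
        "hypothyroidism": 0.0813, "renal_failure": 0.0723,
        "liver_disease": 0.0271, "peptic_ulcer": 0.0632, "aids_hiv": 0.0018,
        "lymphoma": 0.0136, "metastatic_cancer": 0.0361,
        "solid_tumour": 0.0813, "rheumatoid_arthritis": 0.0452,
        "coagulopathy": 0.0271, "obesity": 0.0723, "weight_loss": 0.0452,
        "fluid_electrolyte": 0.1084, "blood_loss_anaemia": 0.0181,
        "deficiency_anaemia": 0.0903, "alcohol_abuse": 0.0452,
        "drug_abuse": 0.0181, "psychoses": 0.0361, "depression": 0.1536,
    },
}

# Default mortality log-odds.  Intercepts offset beta_age * (age ~ 82) so the
# marginal 30-day rate lands near 8% and the 365-day rate near 30% for cases.
_DEFAULT_BETAS = {
    "charlson": {
        "dementia": 0.55, "congestive_heart_failure": 0.45,
        "metastatic_solid_tumour": 0.90, "renal": 0.40,
    },
    "elixhauser": {
        "congestive_heart_failure": 0.50, "metastatic_cancer": 0.90,
        "renal_failure": 0.40, "fluid_electrolyte": 0.50, "weight_loss": 0.60,
        "cardiac_arrhythmias": 0.30, "coagulopathy": 0.40,
        "chronic_pulmonary": 0.30, "psychoses": 0.35, "dementia": 0.0,
    },
}


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort."""

    n_cases: int = 1000
    control_ratio: int = 2
    female_fraction: float = 0.751
    age_median: float = 82.0
    age_iqr_low: float = 75.0
    age_iqr_high: float = 87.0
    category_prevalence: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(d) for m, d in _DEFAULT_PREVALENCE.items()}
    )
    control_prevalence_scale: float = 0.7
    events_per_flag: float = 2.0
    recent_event_fraction: float | None = None
    mortality_intercept_30d: float = -6.9
    mortality_intercept_365d: float = -5.6
    beta_age: float = 0.05
    beta_sex: float = -0.30
    beta_category: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(d) for m, d in _DEFAULT_BETAS.items()}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ConfigError("n_cases must be >= 0")
        if self.control_ratio < 1:
            raise ConfigError("control_ratio must be >= 1")
        for name, p in (("female_fraction", self.female_fraction),
                        ("control_prevalence_scale", self.control_prevalence_scale)):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        for measure, prevs in self.category_prevalence.items():
            for cat, p in prevs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"prevalence {measure}:{cat}={p} outside [0, 1]")
        if self.events_per_flag < 1.0:
            raise ConfigError("events_per_flag must be >= 1 (a flag implies >=1 event)")
        if self.recent_event_fraction is not None and not (
            0.0 <= self.recent_event_fraction <= 1.0
        ):
            raise ConfigError("recent_event_fraction outside [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False),
            encoding="utf-8",
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _age_quantile_anchors(
    median: float, q_low: float, q_high: float
) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-function anchors for the age-at-index distribution.

    The target distribution is left-skewed (the IQR sits asymmetrically
    around the median), more so than common parametric families allow, so
    ages are drawn by inverse transform through a piecewise-linear quantile
    function pinned at the configured quartiles — median and IQR are then
    matched by construction.  The tails extend linearly to plausible
    extremes of a hip-fracture population.
    """
    lower_tail = q_low - 4.0 * (median - q_low)  # ~ age 47 at defaults
    upper_tail = q_high + 3.0 * (q_high - median)  # ~ age 102 at defaults
    ps = np.array([0.001, 0.25, 0.5, 0.75, 0.999])
    qs = np.array([lower_tail, q_low, median, q_high, upper_tail])
    if not np.all(np.diff(qs) > 0):
        raise ConfigError("age quantiles must satisfy q_low < median < q_high")
    return ps, qs


def _draw_ages(n: int, config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    ps, qs = _age_quantile_anchors(
        config.age_median, config.age_iqr_low, config.age_iqr_high
    )
    ages = np.interp(rng.random(n), ps, qs)
    return np.clip(np.rint(ages), 40, 105).astype(int)


def _registration_starts(
    index_dates: pd.Series, rng: np.random.Generator
) -> pd.Series:
    """Registration start >= 3 years before index, with exponential extra."""
    extra_days = rng.exponential(scale=5 * 365.0, size=len(index_dates))
    offset = pd.to_timedelta(
        np.ceil(MIN_REGISTRATION_YEARS * 365.25 + extra_days), unit="D"
    )
    return index_dates - offset


def generate_cases(
    config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Generate the hip-fracture case table.

    Sex is Bernoulli(female_fraction); age at index follows the calibrated
    skew-normal rounded to whole years; the index date is uniform over the
    study window; registration starts at least three years before index.
    """
    config.validate()
    n = config.n_cases
    if n == 0:
        return pd.DataFrame(columns=PATIENT_COLUMNS)
    sex = (rng.random(n) < config.female_fraction).astype(int)
    ages = _draw_ages(n, config, rng)
    span_days = (STUDY_END - STUDY_START).days
    index_dates = STUDY_START + pd.to_timedelta(
        rng.integers(0, span_days + 1, size=n), unit="D"
    )
    reg_start = _registration_starts(pd.Series(index_dates), rng)
    reg_end = pd.Series(index_dates) + pd.to_timedelta(
        rng.integers(365, 5 * 365, size=n), unit="D"
    )
    reg_end = reg_end.clip(upper=FOLLOWUP_END)
    df = pd.DataFrame(
        {
            "patient_id": [f"case_{i:06d}" for i in range(n)],
            "sex": sex,
            "year_of_birth": index_dates.year - ages,
            "registration_start": reg_start.to_numpy(),
            "registration_end": reg_end.to_numpy(),
            "death_date": pd.NaT,
            "role": "case",
            "matched_case_id": None,
            "index_date": index_dates,
            "age_at_index": ages,
        }
    )
    return df


def match_controls(
    cases: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Synthesize ``control_ratio`` controls per case.

    Matching is exact by construction: each control copies its case's sex,
    age at index and index date, and receives its own registration window
    satisfying the three-year rule.
    """
    config.validate()
    k = config.control_ratio
    if len(cases) == 0:
        return pd.DataFrame(columns=PATIENT_COLUMNS)
    rep = cases.loc[cases.index.repeat(k)].reset_index(drop=True)
    n = len(rep)
    index_dates = pd.Series(rep["index_date"])
    reg_start = _registration_starts(index_dates, rng)
    reg_end = index_dates + pd.to_timedelta(rng.integers(365, 5 * 365, size=n), unit="D")
    reg_end = reg_end.clip(upper=FOLLOWUP_END)
    df = pd.DataFrame(
        {
            "patient_id": [f"ctrl_{i:06d}" for i in range(n)],
            "sex": rep["sex"].to_numpy(),
            "year_of_birth": rep["year_of_birth"].to_numpy(),
            "registration_start": reg_start.to_numpy(),
            "registration_end": reg_end.to_numpy(),
            "death_date": pd.NaT,
            "role": "control",
            "matched_case_id": rep["patient_id"].to_numpy(),
            "index_date": rep["index_date"].to_numpy(),
            "age_at_index": rep["age_at_index"].to_numpy(),
        }
    )
    return df


def _prevalence_matrix(
    patients: pd.DataFrame, prevs: dict[str, float], cats: list[str],
    control_scale: float,
) -> np.ndarray:
    base = np.array([prevs.get(c, 0.0) for c in cats])
    scale = np.where(patients["role"].to_numpy() == "control", control_scale, 1.0)
    return np.minimum(scale[:, None] * base[None, :], 1.0)


def generate_comorbidity_events(
    patients: pd.DataFrame,
    codelists: dict[str, CodeList],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Draw latent comorbidity flags and emit coded events for them.

    For each patient and category a latent flag is Bernoulli(prevalence);
    each present flag emits ``1 + Poisson(events_per_flag - 1)`` events whose
    codes are sampled uniformly from that category's code list and whose
    dates are uniform over [registration_start, index_date).  With
    ``recent_event_fraction`` set, that fraction of event dates is instead
    drawn from the final year before index (look-back stress testing).

    Returns the event table and the latent flag matrices per measure — the
    ground truth that the scoring engine should recover under a
    complete-record window.
    """
    config.validate()
    events_frames: list[pd.DataFrame] = []
    flags: dict[str, pd.DataFrame] = {}
    pids = patients["patient_id"].to_numpy()
    reg_start = patients["registration_start"].to_numpy().astype("datetime64[D]")
    index_date = patients["index_date"].to_numpy().astype("datetime64[D]")
    record_days = (index_date - reg_start).astype(int)  # >= ~3*365 by construction

    for measure, codelist in codelists.items():
        prevs = config.category_prevalence.get(measure, {})
        cats = list(codelist.category_ids)
        codes_by_cat: dict[str, np.ndarray] = {c: np.array([], dtype=object) for c in cats}
        cl_frame = codelist.to_frame()
        for c, grp in cl_frame.groupby("category"):
            codes_by_cat[c] = grp["code"].to_numpy()
        for c in cats:
            if prevs.get(c, 0.0) > 0 and len(codes_by_cat[c]) == 0:
                raise ConfigError(
                    f"{measure}:{c} has prevalence {prevs[c]} but no codes"
                )
        pmat = _prevalence_matrix(
            patients, prevs, cats, config.control_prevalence_scale
        )
        flag_mat = rng.random(pmat.shape) < pmat
        flags[measure] = pd.DataFrame(flag_mat, index=pids, columns=cats)

        pat_idx, cat_idx = np.nonzero(flag_mat)
        if len(pat_idx) == 0:
            continue
        n_events = 1 + rng.poisson(config.events_per_flag - 1.0, size=len(pat_idx))
        ev_pat = np.repeat(pat_idx, n_events)
        ev_cat = np.repeat(cat_idx, n_events)
        total = len(ev_pat)
        # date offsets: uniform over the pre-index record, optionally
        # concentrated in the final year
        span = record_days[ev_pat]
        offsets = (rng.random(total) * span).astype(int)  # days after reg_start
        if config.recent_event_fraction is not None:
            recent = rng.random(total) < config.recent_event_fraction
            last_year = np.minimum(365, span)
            recent_off = span - 1 - (rng.random(total) * last_year).astype(int)
            offsets = np.where(recent, np.maximum(recent_off, 0), offsets)
        ev_dates = reg_start[ev_pat] + offsets.astype("timedelta64[D]")
        codes = np.empty(total, dtype=object)
        for ci, cat in enumerate(cats):
            mask = ev_cat == ci
            if mask.any():
                codes[mask] = rng.choice(codes_by_cat[cat], size=int(mask.sum()))
        events_frames.append(
            pd.DataFrame(
                {
                    "patient_id": pids[ev_pat],
                    "event_date": pd.to_datetime(ev_dates),
                    "code": codes,
                }
            )
        )
    if events_frames:
        events = pd.concat(events_frames, ignore_index=True)
        events = events.sort_values(["patient_id", "event_date"], kind="stable")
        events = events.reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    return events, flags


def mortality_linear_predictors(
    patients: pd.DataFrame,
    flags: dict[str, pd.DataFrame],
    config: GeneratorConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """True log-odds of 30-day death and of death in (30, 365] given survival."""
    base = (
        config.beta_age * patients["age_at_index"].to_numpy(dtype=float)
        + config.beta_sex * patients["sex"].to_numpy(dtype=float)
    )
    comorb = np.zeros(len(patients))
    for measure, betas in config.beta_category.items():
        if measure not in flags:
            continue
        fl = flags[measure].loc[patients["patient_id"].to_numpy()]
        for cat, b in betas.items():
            if b != 0.0 and cat in fl.columns:
                comorb += b * fl[cat].to_numpy(dtype=float)
    lp30 = config.mortality_intercept_30d + base + comorb
    lp365 = config.mortality_intercept_365d + base + comorb
    return lp30, lp365


def simulate_mortality(
    patients: pd.DataFrame,
    flags: dict[str, pd.DataFrame],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw death dates from the two-stage logistic mortality model.

    Death within 30 days of index (inclusive) is Bernoulli(expit(lp30));
    survivors draw death in the (30, 365] window from the second model.
    The death date is placed uniformly within the realized window and
    registration_end is clipped to it.  True linear predictors are retained
    in ``lp30_true`` / ``lp365_true`` for diagnostics.
    """
    config.validate()
    out = patients.copy()
    n = len(out)
    if n == 0:
        out["lp30_true"] = np.array([], dtype=float)
        out["lp365_true"] = np.array([], dtype=float)
        return out
    lp30, lp365 = mortality_linear_predictors(out, flags, config)
    die30 = rng.random(n) < expit(lp30)
    die365 = (~die30) & (rng.random(n) < expit(lp365))
    offsets = np.zeros(n, dtype=int)
    offsets[die30] = rng.integers(0, 31, size=int(die30.sum()))
    offsets[die365] = rng.integers(31, 366, size=int(die365.sum()))
    death = pd.Series(pd.NaT, index=out.index, dtype="datetime64[ns]")
    dead = die30 | die365
    death[dead] = pd.Series(out.loc[dead, "index_date"]) + pd.to_timedelta(
        offsets[dead], unit="D"
    )
    out["death_date"] = death
    out.loc[dead, "registration_end"] = np.minimum(
        out.loc[dead, "registration_end"].to_numpy(), death[dead].to_numpy()
    )
    out["lp30_true"] = lp30
    out["lp365_true"] = lp365
    return out


def generate_cohort(
    config: GeneratorConfig, codelists: dict[str, CodeList]
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """End-to-end generation: cases, matched controls, events, mortality.

    One root seed spawns independent per-stage streams, so adding a stage
    never perturbs earlier stages' draws.  Returns (patients, events, flags).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_cases, rng_ctrl, rng_events, rng_death = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    cases = generate_cases(config, rng_cases)
    controls = match_controls(cases, config, rng_ctrl)
    patients = pd.concat([cases, controls], ignore_index=True)
    events, flags = generate_comorbidity_events(patients, codelists, config, rng_events)
    patients = simulate_mortality(patients, flags, config, rng_death)
    return patients, events, flags


# ---------------------------------------------------------------------------
# cohort I/O


def write_cohort(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    out_dir: str | Path,
    flags: dict[str, pd.DataFrame] | None = None,
) -> None:
    """Write patients.csv / events.csv (and flags_truth.csv) with ISO dates."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pat = patients.copy()
    for col in ("registration_start", "registration_end", "death_date", "index_date"):
        if col in pat.columns:
            pat[col] = pd.to_datetime(pat[col]).dt.strftime("%Y-%m-%d")
    if "death_date" in pat.columns:
        pat["death_date"] = pat["death_date"].fillna("")
    if "matched_case_id" in pat.columns:
        pat["matched_case_id"] = pat["matched_case_id"].fillna("")
    pat.to_csv(out_dir / "patients.csv", index=False)
    ev = events.copy()
    if len(ev):
        ev["event_date"] = pd.to_datetime(ev["event_date"]).dt.strftime("%Y-%m-%d")
    ev.to_csv(out_dir / "events.csv", index=False)
    if flags is not None:
        wide = pd.concat(
            {m: df.astype(int) for m, df in flags.items()}, axis=1
        )
        wide.columns = [f"{m}__{c}" for m, c in wide.columns]
        wide.index.name = "patient_id"
        wide.to_csv(out_dir / "flags_truth.csv")


def _parse_date_column(s: pd.Series, table: str, column: str) -> pd.Series:
    parsed = pd.to_datetime(s.replace("", pd.NA), format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & s.replace("", pd.NA).notna()
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"{table}: unparseable date {s[row]!r} in column {column}, row {row}"
        )
    return parsed


def read_cohort(
    in_dir: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame] | None]:
    """Read a cohort directory back; inverse of :func:`write_cohort`."""
    in_dir = Path(in_dir)
    pat = pd.read_csv(in_dir / "patients.csv", dtype=str, keep_default_na=False)
    for col in ("registration_start", "registration_end", "death_date", "index_date"):
        if col in pat.columns:
            pat[col] = _parse_date_column(pat[col], "patients.csv", col)
    for col in ("sex", "year_of_birth", "age_at_index"):
        if col in pat.columns:
            pat[col] = pat[col].astype(int)
    for col in ("lp30_true", "lp365_true"):
        if col in pat.columns:
            pat[col] = pat[col].astype(float)
    if "matched_case_id" in pat.columns:
        pat["matched_case_id"] = pat["matched_case_id"].replace("", None)
    ev = pd.read_csv(in_dir / "events.csv", dtype=str, keep_default_na=False)
    if len(ev):
        ev["event_date"] = _parse_date_column(ev["event_date"], "events.csv", "event_date")
    else:
        ev = pd.DataFrame(columns=EVENT_COLUMNS)
    flags = None
    flags_path = in_dir / "flags_truth.csv"
    if flags_path.exists():
        wide = pd.read_csv(flags_path, index_col="patient_id")
        flags = {}
        for measure in ("charlson", "elixhauser"):
            cols = [c for c in wide.columns if c.startswith(f"{measure}__")]
            if cols:
                sub = wide[cols].astype(bool)
                sub.columns = [c.split("__", 1)[1] for c in cols]
                flags[measure] = sub
    return pat, ev, flags
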