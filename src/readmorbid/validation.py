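"""Mortality-model validation: logistic fits, AUROC, ROC equality, KM.

The validation mirrors a standard comorbidity-measure evaluation design:
logistic regression models for 30- and 365-day mortality with age
(continuous) and sex as base covariables, comorbidity summaries layered on
top (the Charlson index as a single integer score; the 31 Elixhauser
categories as separate indicators; optionally the 17 Charlson categories as
indicators), fixed covariable menus with no stepwise selection, and
discrimination compared via the area under the ROC curve.

AUROC is the Mann-Whitney estimator with ties counted 1/2.  Its variance —
and the chi-square test of equality for k correlated ROC curves computed on
the same subjects — uses the DeLong structural-components estimator (the
approach behind Stata's ``roccomp``).  A paired-bootstrap comparison is
provided as a cross-check, not a default.  Cases and controls are analysed
separately; no case-control conditional analysis is performed.

Kaplan-Meier curves by comorbidity stratum use the product-limit estimator
with follow-up capped at 365 days (survivors censored there).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from scipy import stats
from scipy.linalg import qr

from .engine import LookbackWindow

logger = logging.getLogger(__name__)

COVARIABLE_SETS = (
    "base",
    "base+CCI",
    "base+EM_flags",
    "CCI_alone",
    "EM_flags_alone",
    "base+charlson_flags",
    "charlson_flags_alone",
)


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the fixed model menu (no stepwise selection)."""

    outcome: str  # death_30d | death_365d
    covariable_set: str
    window: LookbackWindow | str = LookbackWindow.COMPLETE_RECORD
    population: str = "cases"  # cases | controls
    weight_scheme: str = "original"  # original | quan (CCI models only)

    def __post_init__(self) -> None:
        if self.outcome not in ("death_30d", "death_365d"):
            raise ValueError(f"unknown outcome: {self.outcome!r}")
        if self.covariable_set not in COVARIABLE_SETS:
            raise ValueError(
                f"unknown covariable set: {self.covariable_set!r} "
                f"(expected one of {COVARIABLE_SETS})"
            )
        if self.population not in ("cases", "controls"):
            raise ValueError(f"unknown population: {self.population!r}")
        if self.weight_scheme not in ("original", "quan"):
            raise ValueError(f"unknown weight scheme: {self.weight_scheme!r}")


@dataclass
class FitResult:
    """Maximum-likelihood logistic fit."""

    params: pd.Series
    bse: pd.Series
    converged: bool
    log_likelihood: float
    linear_predictor: np.ndarray
    dropped_columns: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class RocResult:
    """AUROC with DeLong variance and normal-approximation 95% CI."""

    auc: float
    variance: float
    ci95_low: float
    ci95_high: float


@dataclass(frozen=True)
class RocComparison:
    """Chi-square test of equality for k correlated ROC curves."""

    statistic: float
    df: int
    p_value: float
    aucs: tuple[float, ...]


# ---------------------------------------------------------------------------
# design construction


def build_design(
    profiles: pd.DataFrame,
    patients: pd.DataFrame,
    spec: ModelSpec,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the covariable table and outcome vector for one model.

    Outcomes are inclusive at the boundary: death on day 30 counts as a
    30-day death.  Population filtering uses the ``role`` column ("cases"
    selects role == "case").
    """
    window = LookbackWindow.parse(spec.window)
    prof_window = profiles.attrs.get("window")
    if prof_window is not None and prof_window != window.value:
        raise ValueError(
            f"profiles were computed under window {prof_window!r} but the "
            f"model spec requests {window.value!r}"
        )
    role = "case" if spec.population == "cases" else "control"
    pats = patients.loc[patients["role"] == role]
    if len(pats) == 0:
        raise ValueError(f"no patients with role {role!r}")
    df = pats.set_index("patient_id").join(profiles, how="inner")
    # patients dying before index cannot contribute (excluded defensively;
    # the synthetic generator cannot produce them)
    death_days = (df["death_date"] - df["index_date"]).dt.days
    df = df.loc[~(death_days < 0)]
    death_days = (df["death_date"] - df["index_date"]).dt.days
    horizon = 30 if spec.outcome == "death_30d" else 365
    y = ((death_days.notna()) & (death_days <= horizon)).to_numpy(dtype=float)

    cols: dict[str, np.ndarray] = {}
    cset = spec.covariable_set
    if cset.startswith("base") or cset == "base":
        cols["age"] = df["age_at_index"].to_numpy(dtype=float)
        cols["sex"] = df["sex"].to_numpy(dtype=float)
    if "CCI" in cset:
        cci_col = "cci_original" if spec.weight_scheme == "original" else "cci_quan"
        cols["cci"] = df[cci_col].to_numpy(dtype=float)
    if "EM_flags" in cset:
        for c in profiles.columns:
            if c.startswith("elixhauser__"):
                cols[c] = df[c].to_numpy(dtype=float)
    if "charlson_flags" in cset:
        for c in profiles.columns:
            if c.startswith("charlson__"):
                cols[c] = df[c].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=df.index)
    return X, y


# ---------------------------------------------------------------------------
# logistic fitting


def _drop_degenerate(X: pd.DataFrame, y: np.ndarray) -> tuple[pd.DataFrame, list[str]]:
    """Drop degenerate design columns before fitting.

    Removes (a) constant columns, (b) binary indicator columns that predict
    the outcome perfectly (all flagged subjects share one outcome — the
    classic sparse-cell separation; standard regression software omits
    these), and (c) perfectly collinear columns found by pivoted QR.
    Unlike some packages, observations are never discarded.
    """
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    Xr = X.drop(columns=dropped)
    separating = []
    for c in Xr.columns:
        col = Xr[c].to_numpy(dtype=float)
        if set(np.unique(col)) <= {0.0, 1.0}:
            y_on = y[col == 1.0]
            if len(y_on) and (y_on.min() == y_on.max()):
                separating.append(c)
    if separating:
        dropped.extend(separating)
        Xr = Xr.drop(columns=separating)
    if Xr.shape[1] > 1:
        mat = np.column_stack([np.ones(len(Xr)), Xr.to_numpy(dtype=float)])
        r, piv = qr(mat, mode="r", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(mat.shape) * np.finfo(float).eps
        rank = int((diag > tol).sum())
        if rank < mat.shape[1]:
            redundant = sorted(piv[rank:])
            names = [Xr.columns[i - 1] for i in redundant if i > 0]
            dropped.extend(names)
            Xr = Xr.drop(columns=names)
    if dropped:
        logger.warning("dropped degenerate design columns: %s", dropped)
    return Xr, dropped


def fit_logistic(X: pd.DataFrame, y: np.ndarray) -> FitResult:
    """Newton-Raphson maximum-likelihood logistic regression.

    Deterministic given its input (no stochastic optimizer); converges to
    tolerance 1e-8 within 100 iterations or is reported non-converged.
    Complete separation is flagged rather than raised.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both events and non-events")
    Xr, dropped = _drop_degenerate(X, y)
    design = sm.add_constant(Xr.to_numpy(dtype=float), has_constant="add")
    names = ["const", *Xr.columns]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0, warn_convergence=False
            )
        converged = bool(res.mle_retvals.get("converged", False))
        params = pd.Series(res.params, index=names)
        bse = pd.Series(res.bse, index=names)
        llf = float(res.llf)
        lp = design @ res.params
    except Exception as exc:  # e.g. PerfectSeparationError, singular Hessian
        logger.warning("logistic fit failed: %s", exc)
        nan = pd.Series(np.nan, index=names)
        return FitResult(nan, nan.copy(), False, np.nan, np.full(len(y), np.nan), dropped)
    return FitResult(params, bse, converged, llf, np.asarray(lp), dropped)


# ---------------------------------------------------------------------------
# AUROC and DeLong machinery


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _structural_components(
    scores: np.ndarray, outcomes: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-positive (V10) and per-negative (V01) placement values."""
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return auc, v10, v01


def auroc(scores: np.ndarray, outcomes: np.ndarray) -> RocResult:
    """Mann-Whitney AUROC (ties counted 1/2) with DeLong variance.

    The 95% CI is the normal approximation ``auc +/- 1.96 sqrt(var)``
    clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    classes = np.unique(outcomes)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("outcomes must contain both classes coded 0/1")
    auc, v10, v01 = _structural_components(scores, outcomes)
    m, n = len(v10), len(v01)
    var10 = v10.var(ddof=1) if m > 1 else 0.0
    var01 = v01.var(ddof=1) if n > 1 else 0.0
    var = var10 / m + var01 / n
    half = 1.96 * np.sqrt(var)
    return RocResult(
        auc=float(auc),
        variance=float(var),
        ci95_low=float(np.clip(auc - half, 0.0, 1.0)),
        ci95_high=float(np.clip(auc + half, 0.0, 1.0)),
    )


def compare_roc(
    score_sets: "list[np.ndarray] | np.ndarray", outcomes: np.ndarray
) -> RocComparison:
    """DeLong test of equality for k correlated ROC curves.

    All score vectors must be computed on the same subjects, in the same
    order.  The AUC covariance matrix is estimated from paired structural
    components; equality is tested with a chi-square contrast on k-1
    degrees of freedom (for k = 2 this is exactly the squared two-sample
    z statistic).
    """
    outcomes = np.asarray(outcomes, dtype=float)
    score_sets = [np.asarray(s, dtype=float) for s in score_sets]
    k = len(score_sets)
    if k < 2:
        raise ValueError("compare_roc requires at least two score vectors")
    if any(len(s) != len(outcomes) for s in score_sets):
        raise ValueError("all score vectors must align with the outcome vector")
    aucs = np.empty(k)
    v10s, v01s = [], []
    for i, s in enumerate(score_sets):
        a, v10, v01 = _structural_components(s, outcomes)
        aucs[i] = a
        v10s.append(v10)
        v01s.append(v01)
    V10 = np.vstack(v10s)  # k x m
    V01 = np.vstack(v01s)  # k x n
    m, n = V10.shape[1], V01.shape[1]
    S = np.cov(V10, ddof=1) / m + np.cov(V01, ddof=1) / n
    S = np.atleast_2d(S)
    L = np.hstack([np.ones((k - 1, 1)), -np.eye(k - 1)])  # curve 1 vs each other
    d = L @ aucs
    cov_d = L @ S @ L.T
    statistic = float(d @ np.linalg.pinv(cov_d) @ d)
    df = k - 1
    p = float(stats.chi2.sf(statistic, df))
    return RocComparison(statistic=statistic, df=df, p_value=p, aucs=tuple(aucs))


def compare_roc_bootstrap(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    outcomes: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Paired-bootstrap p-value for the difference of two correlated AUCs.

    Resamples subjects with replacement (stratified by outcome so both
    classes persist), recomputes the AUC difference, and converts its
    bootstrap standard error into a two-sided normal p-value.  Cross-check
    for :func:`compare_roc`, not a replacement.
    """
    rng = np.random.default_rng(seed)
    outcomes = np.asarray(outcomes, dtype=float)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    pos_idx = np.flatnonzero(outcomes == 1)
    neg_idx = np.flatnonzero(outcomes == 0)
    d_obs = auroc(scores_a, outcomes).auc - auroc(scores_b, outcomes).auc
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, size=len(pos_idx), replace=True),
                rng.choice(neg_idx, size=len(neg_idx), replace=True),
            ]
        )
        y = outcomes[idx]
        diffs[b] = auroc(scores_a[idx], y).auc - auroc(scores_b[idx], y).auc
    se = diffs.std(ddof=1)
    if se == 0.0:
        return 1.0 if d_obs == 0.0 else 0.0
    z = d_obs / se
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Kaplan-Meier


def km_estimate(
    time_to_event: np.ndarray,
    event_flag: np.ndarray,
    group: np.ndarray,
) -> pd.DataFrame:
    """Product-limit survival per group, long format.

    Times are days since index, capped at 365 by the caller (patients alive
    then are censored).  Returns columns group, time, survival, at_risk;
    S(0) = 1 and the curve drops only at event times.  Empty groups are
    skipped with a warning.
    """
    time_to_event = np.asarray(time_to_event, dtype=float)
    event_flag = np.asarray(event_flag, dtype=bool)
    group = np.asarray(group)
    if (time_to_event < 0).any():
        raise ValueError("negative follow-up time")
    out = []
    for g in pd.unique(group):
        mask = group == g
        if not mask.any():
            logger.warning("empty KM group %r skipped", g)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time_to_event[mask], event_observed=event_flag[mask])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index)
        out.append(
            pd.DataFrame(
                {
                    "group": g,
                    "time": sf.index.to_numpy(dtype=float),
                    "survival": sf.iloc[:, 0].to_numpy(),
                    "at_risk": at_risk.to_numpy(),
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["group", "time", "survival", "at_risk"])
    return pd.concat(out, ignore_index=True)


def km_by_stratum(
    patients: pd.DataFrame,
    strata: pd.Series,
    horizon_days: int = 365,
) -> pd.DataFrame:
    """KM of death within ``horizon_days`` of index, by stratum.

    ``strata`` is indexed by patient_id (e.g. banded CCI or EM counts).
    """
    df = patients.set_index("patient_id").join(strata.rename("stratum"), how="inner")
    death_days = (df["death_date"] - df["index_date"]).dt.days
    event = death_days.notna() & (death_days <= horizon_days)
    time = np.where(event, death_days, horizon_days)
    return km_estimate(time.astype(float), event.to_numpy(), df["stratum"].to_numpy())


# ---------------------------------------------------------------------------
# full validation sweep


@dataclass
class ValidationPlan:
    """Which cells of the validation grid to run."""

    populations: tuple[str, ...] = ("cases", "controls")
    outcomes: tuple[str, ...] = ("death_30d", "death_365d")
    covariable_sets: tuple[str, ...] = (
        "base",
        "base+CCI",
        "base+EM_flags",
        "CCI_alone",
        "EM_flags_alone",
    )
    weight_scheme: str = "original"


#: contrast partner per covariable set (comparison column of the results)
_DEFAULT_CONTRASTS = {
    "base+CCI": "base",
    "base+EM_flags": "base",
    "EM_flags_alone": "CCI_alone",
    "charlson_flags_alone": "CCI_alone",
    "base+charlson_flags": "base",
}


def run_validation(
    patients: pd.DataFrame,
    profiles_by_window: dict[str, pd.DataFrame],
    plan: ValidationPlan | None = None,
) -> pd.DataFrame:
    """Fit every requested model and tabulate AUROC with contrasts.

    One row per (population, outcome, model, window) with the DeLong 95%
    CI, plus the ROC-equality p-value against the model's contrast partner
    (fitted on the same subjects).  Deterministic given the cohort.
    """
    plan = plan or ValidationPlan()
    rows = []
    for population in plan.populations:
        for outcome in plan.outcomes:
            for window, profiles in profiles_by_window.items():
                window = LookbackWindow.parse(window)
                scores: dict[str, np.ndarray] = {}
                aucs: dict[str, RocResult] = {}
                y_ref: np.ndarray | None = None
                for cset in plan.covariable_sets:
                    spec = ModelSpec(
                        outcome=outcome,
                        covariable_set=cset,
                        window=window,
                        population=population,
                        weight_scheme=plan.weight_scheme,
                    )
                    X, y = build_design(profiles, patients, spec)
                    y_ref = y
                    fit = fit_logistic(X, y)
                    if not fit.converged:
                        logger.warning(
                            "model %s/%s/%s/%s did not converge; skipped",
                            population, outcome, cset, window.value,
                        )
                        continue
                    scores[cset] = fit.linear_predictor
                    aucs[cset] = auroc(fit.linear_predictor, y)
                for cset in plan.covariable_sets:
                    if cset not in aucs:
                        continue
                    partner = _DEFAULT_CONTRASTS.get(cset)
                    comparison, p_value = "", np.nan
                    if partner in scores:
                        cmp = compare_roc([scores[cset], scores[partner]], y_ref)
                        comparison = f"vs {partner}"
                        p_value = cmp.p_value
                    r = aucs[cset]
                    rows.append(
                        {
                            "population": population,
                            "outcome": outcome,
                            "model": cset,
                            "window": window.value,
                            "auc": r.auc,
                            "ci_low": r.ci95_low,
                            "ci_high": r.ci95_high,
                            "comparison": comparison,
                            "p_value": p_value,
                        }
                    )
    return pd.DataFrame(rows)
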