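"""Logistic fits, AUROC/DeLong machinery, ROC comparison, KM."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import readmorbid as rm
from readmorbid.validation import ModelSpec, _structural_components


def _exhaustive_auc(scores, outcomes):
    """Pair-counting oracle: concordant pairs + half the tied ones."""
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_worked_example(self):
        r = rm.auroc(np.array([0.8, 0.6, 0.4, 0.2]), np.array([1, 0, 1, 0]))
        assert r.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        r = rm.auroc(np.array([1, 2, 3, 10, 11, 12]), np.array([0, 0, 0, 1, 1, 1]))
        assert r.auc == 1.0

    def test_all_ties_is_half(self):
        r = rm.auroc(np.ones(10), np.array([0, 1] * 5))
        assert r.auc == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            rm.auroc(np.arange(4.0), np.ones(4))

    def test_matches_pair_counting_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 50))
            scores = rng.integers(0, 5, n).astype(float)  # heavy ties
            outcomes = np.r_[0, 1, rng.integers(0, 2, n - 2)].astype(float)
            assert rm.auroc(scores, outcomes).auc == pytest.approx(
                _exhaustive_auc(scores, outcomes), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=300)
        outcomes = (rng.random(300) < expit(scores)).astype(float)
        assert rm.auroc(scores, outcomes).auc == pytest.approx(
            roc_auc_score(outcomes, scores), abs=1e-12
        )

    def test_negation_complements(self, rng):
        scores = rng.normal(size=100)
        outcomes = np.r_[np.zeros(50), np.ones(50)]
        a = rm.auroc(scores, outcomes).auc
        b = rm.auroc(-scores, outcomes).auc
        assert a + b == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=200)
        outcomes = np.r_[np.zeros(100), np.ones(100)]
        a = rm.auroc(scores, outcomes)
        b = rm.auroc(np.exp(scores), outcomes)
        assert a.auc == pytest.approx(b.auc)
        assert a.variance == pytest.approx(b.variance)

    def test_ci_contains_auc_and_clipped(self, rng):
        scores = rng.normal(size=40)
        outcomes = np.r_[np.zeros(20), np.ones(20)]
        r = rm.auroc(scores + outcomes * 3, outcomes)
        assert 0.0 <= r.ci95_low <= r.auc <= r.ci95_high <= 1.0

    def test_delong_variance_shrinks_with_n(self, rng):
        variances = []
        for n in (100, 1000, 10_000):
            scores = rng.normal(size=n)
            outcomes = (rng.random(n) < expit(scores)).astype(float)
            variances.append(rm.auroc(scores, outcomes).variance)
        assert variances[0] > variances[1] > variances[2]


class TestCompareRoc:
    def test_identical_curves(self):
        s = np.array([0.1, 0.4, 0.35, 0.8])
        y = np.array([0, 0, 1, 1])
        c = rm.compare_roc([s, s.copy()], y)
        assert c.statistic == 0.0
        assert c.p_value == 1.0
        assert c.df == 1

    def test_chi_square_equals_squared_z_for_two_curves(self, rng):
        n = 200
        y = np.r_[np.zeros(100), np.ones(100)]
        s1 = rng.normal(size=n) + y
        s2 = rng.normal(size=n) + 0.5 * y
        c = rm.compare_roc([s1, s2], y)
        # z from the 2x2 covariance directly
        a1, v10_1, v01_1 = _structural_components(s1, y)
        a2, v10_2, v01_2 = _structural_components(s2, y)
        m, k = len(v10_1), len(v01_1)
        cov = np.cov(np.vstack([v10_1, v10_2]), ddof=1) / m + np.cov(
            np.vstack([v01_1, v01_2]), ddof=1
        ) / k
        z = (a1 - a2) / np.sqrt(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
        assert c.statistic == pytest.approx(z**2, rel=1e-10)

    def test_three_curves_df(self, rng):
        y = np.r_[np.zeros(60), np.ones(60)]
        curves = [rng.normal(size=120) + y * s for s in (1.0, 1.0, 0.2)]
        c = rm.compare_roc(curves, y)
        assert c.df == 2
        assert 0.0 <= c.p_value <= 1.0

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError, match="align"):
            rm.compare_roc([np.arange(4.0), np.arange(5.0)], np.array([0, 1, 0, 1]))

    def test_detects_genuine_difference(self, rng):
        n = 2000
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        informative = rng.normal(size=n) + 1.5 * y
        noise = rng.normal(size=n)
        c = rm.compare_roc([informative, noise], y)
        assert c.p_value < 1e-6

    def test_agrees_with_paired_bootstrap(self, rng):
        """Normal-approximation bootstrap on a fixed dataset, within 0.03."""
        n = 200
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        s1 = rng.normal(size=n) + 0.8 * y
        s2 = rng.normal(size=n) + 0.55 * y
        p_delong = rm.compare_roc([s1, s2], y).p_value
        p_boot = rm.compare_roc_bootstrap(s1, s2, y, n_boot=2000, seed=99)
        assert abs(p_delong - p_boot) < 0.03


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        X = pd.DataFrame(index=range(100))
        fit = rm.fit_logistic(X, y)
        assert fit.converged
        assert fit.params["const"] == pytest.approx(logit(0.3), abs=1e-8)

    def test_parameter_recovery(self, rng):
        n = 20_000
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n).astype(float)
        lp = -1.0 + 0.7 * x1 - 0.4 * x2
        y = (rng.random(n) < expit(lp)).astype(float)
        fit = rm.fit_logistic(pd.DataFrame({"x1": x1, "x2": x2}), y)
        truth = {"const": -1.0, "x1": 0.7, "x2": -0.4}
        for name, b in truth.items():
            assert abs(fit.params[name] - b) < 3 * fit.bse[name]

    def test_null_covariate_near_zero(self, rng):
        n = 20_000
        signal = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = (rng.random(n) < expit(signal)).astype(float)
        fit = rm.fit_logistic(pd.DataFrame({"signal": signal, "noise": noise}), y)
        assert abs(fit.params["noise"]) < 3 * fit.bse["noise"]

    def test_deterministic(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=500)})
        y = (rng.random(500) < 0.3).astype(float)
        a = rm.fit_logistic(X, y)
        b = rm.fit_logistic(X, y)
        assert (a.params == b.params).all()
        assert (a.linear_predictor == b.linear_predictor).all()

    def test_constant_column_dropped(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=200), "k": np.ones(200)})
        y = np.r_[np.zeros(100), np.ones(100)]
        fit = rm.fit_logistic(X, y)
        assert "k" in fit.dropped_columns
        assert "k" not in fit.params.index

    def test_collinear_column_dropped(self, rng):
        x = rng.normal(size=300)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        y = (rng.random(300) < expit(x)).astype(float)
        fit = rm.fit_logistic(X, y)
        assert len(fit.dropped_columns) == 1
        assert fit.dropped_columns[0] in {"x", "x2"}
        assert fit.converged

    def test_perfectly_predictive_indicator_dropped(self):
        y = np.r_[np.ones(10), np.zeros(90)]
        flag = np.r_[np.ones(5), np.zeros(95)]  # only ever with y=1
        X = pd.DataFrame({"flag": flag, "z": np.arange(100) % 3})
        fit = rm.fit_logistic(X, y)
        assert "flag" in fit.dropped_columns

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rm.fit_logistic(pd.DataFrame({"x": [1.0, 2.0]}), np.ones(2))


@pytest.fixture(scope="module")
def scored(small_cohort, codelists):
    _, patients, events, _ = small_cohort
    profiles = rm.score_cohort(patients, events, codelists, "full")
    return patients, profiles


class TestBuildDesign:
    def test_base_has_two_columns(self, scored):
        patients, profiles = scored
        X, y = rm.build_design(profiles, patients, ModelSpec("death_30d", "base"))
        assert list(X.columns) == ["age", "sex"]
        assert len(X) == len(y) == (patients["role"] == "case").sum()

    def test_em_flags_adds_31(self, scored):
        patients, profiles = scored
        X, _ = rm.build_design(
            profiles, patients, ModelSpec("death_30d", "base+EM_flags")
        )
        assert X.shape[1] == 2 + 31

    def test_charlson_flags_adds_17(self, scored):
        patients, profiles = scored
        X, _ = rm.build_design(
            profiles, patients, ModelSpec("death_365d", "charlson_flags_alone")
        )
        assert X.shape[1] == 17

    def test_outcome_boundaries_inclusive(self, scored, codelists):
        patients, _ = scored
        pats = patients[patients["role"] == "case"].head(3).copy()
        pats["death_date"] = pats["index_date"] + pd.to_timedelta(
            [30, 31, 366], unit="D"
        )
        profiles = rm.score_cohort(
            pats, pd.DataFrame(columns=["patient_id", "event_date", "code"]),
            codelists, "full",
        )
        _, y30 = rm.build_design(profiles, pats, ModelSpec("death_30d", "base"))
        _, y365 = rm.build_design(profiles, pats, ModelSpec("death_365d", "base"))
        assert list(y30) == [1.0, 0.0, 0.0]
        assert list(y365) == [1.0, 1.0, 0.0]

    def test_window_mismatch_rejected(self, small_cohort, codelists):
        _, patients, events, _ = small_cohort
        profiles = rm.score_cohort(patients, events, codelists, "1y")
        with pytest.raises(ValueError, match="window"):
            rm.build_design(
                profiles, patients,
                ModelSpec("death_30d", "base", window="full"),
            )

    def test_quan_scheme_selects_quan_column(self, scored):
        patients, profiles = scored
        X_orig, _ = rm.build_design(
            profiles, patients, ModelSpec("death_30d", "CCI_alone")
        )
        X_quan, _ = rm.build_design(
            profiles, patients,
            ModelSpec("death_30d", "CCI_alone", weight_scheme="quan"),
        )
        assert (X_orig["cci"].to_numpy() == profiles.loc[X_orig.index, "cci_original"].to_numpy()).all()
        assert (X_quan["cci"].to_numpy() == profiles.loc[X_quan.index, "cci_quan"].to_numpy()).all()


class TestKaplanMeier:
    def test_no_deaths_flat_at_one(self):
        km = rm.km_estimate(np.full(8, 365.0), np.zeros(8, bool), np.repeat("g", 8))
        assert (km["survival"] == 1.0).all()

    def test_hand_worked_product_limit(self):
        """10 subjects: deaths at 5 and 20, censoring at 10 -> 0.9, 0.7875."""
        time = np.array([5, 10, 20] + [365] * 7, dtype=float)
        event = np.array([1, 0, 1] + [0] * 7, dtype=bool)
        km = rm.km_estimate(time, event, np.repeat("all", 10))
        sv = km.set_index("time")["survival"]
        assert sv.loc[5.0] == pytest.approx(0.9)
        assert sv.loc[20.0] == pytest.approx(0.9 * (1 - 1 / 8))

    def test_all_die_day_one(self):
        km = rm.km_estimate(np.ones(5), np.ones(5, bool), np.repeat("g", 5))
        assert km.set_index("time")["survival"].loc[1.0] == 0.0

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.integers(1, 300, 40).astype(float)
        km = rm.km_estimate(t, np.ones(40, bool), np.repeat("g", 40))
        for _, row in km.iterrows():
            assert row["survival"] == pytest.approx((t > row["time"]).mean())

    def test_monotone_nonincreasing_starts_at_one(self, rng):
        t = rng.integers(1, 365, 60).astype(float)
        e = rng.random(60) < 0.5
        km = rm.km_estimate(t, e, np.repeat("g", 60))
        s = km["survival"].to_numpy()
        assert s[0] == 1.0
        assert (np.diff(s) <= 1e-12).all()

    def test_by_stratum_groups(self, small_cohort):
        _, patients, _, _ = small_cohort
        strata = pd.Series(
            np.where(patients["sex"] == 1, "female", "male"),
            index=patients["patient_id"],
        )
        km = rm.km_by_stratum(patients, strata)
        assert set(km["group"]) == {"female", "male"}


class TestRunValidation:
    def test_grid_shape_and_determinism(self, small_cohort, codelists):
        _, patients, events, _ = small_cohort
        profiles = {
            w: rm.score_cohort(patients, events, codelists, w) for w in ("1y", "full")
        }
        plan = rm.ValidationPlan(
            populations=("cases",),
            outcomes=("death_365d",),
            covariable_sets=("base", "base+CCI", "CCI_alone"),
        )
        a = rm.run_validation(patients, profiles, plan)
        b = rm.run_validation(patients, profiles, plan)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 1 * 1 * 3 * 2
        assert set(a["window"]) == {"1y", "full"}
        base_rows = a[a["model"] == "base"]
        assert base_rows["auc"].nunique() == 1  # base ignores the window
        layered = a[a["model"] == "base+CCI"]
        assert (layered["comparison"] == "vs base").all()
        assert layered["p_value"].notna().all()
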