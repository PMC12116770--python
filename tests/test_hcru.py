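"""PPPY metrics, relapse counting, stratified comparisons, NB regression and
marginal standardization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cogehr.hcru_analysis import (
    adjusted_rates,
    bucket_by_note_count,
    build_regression_design,
    chi_square_2x2,
    cohort_metrics,
    detect_relapse_episodes,
    fit_nb_regression,
    pppy_metrics,
    summarize_strata,
)
from cogehr.lexicon import DOMAINS
from cogehr.nlp_extractor import PatientImpairmentProfile


def _claim(day, ctype, dx="I10", los=None, sclass="", pid="p1", cid=None):
    return {
        "claim_id": cid or f"c{day}{ctype}",
        "patient_id": pid,
        "service_date": day,
        "claim_type": ctype,
        "primary_dx": dx,
        "length_of_stay_days": los,
        "service_class": sclass,
    }


class TestPPPYMetrics:
    def test_window_restriction(self):
        claims = [
            _claim("2018-06-01", "outpatient"),
            _claim("2018-09-01", "outpatient"),
            _claim("2019-04-30", "outpatient"),
            _claim("2019-06-01", "outpatient"),  # after month 12
        ]
        rec = pppy_metrics(claims, "2018-05-01")
        assert rec["outpatient_visits"] == 3
        assert rec["claims_out_of_window"] == 1

    def test_los_per_admission_arithmetic(self):
        claims = [
            _claim("2018-06-01", "inpatient", los=10, cid="a"),
            _claim("2018-08-01", "inpatient", los=24, cid="b"),
        ]
        rec = pppy_metrics(claims, "2018-05-01")
        assert rec["total_hospitalized_days"] == 34
        assert rec["los_per_admission"] == 17.0

    def test_no_admissions_los_undefined(self):
        rec = pppy_metrics([_claim("2018-06-01", "outpatient")], "2018-05-01")
        assert rec["los_per_admission"] is None

    def test_all_cause_is_sum_of_types(self):
        claims = [
            _claim("2018-06-01", "outpatient"),
            _claim("2018-06-02", "pharmacy"),
            _claim("2018-06-03", "er"),
            _claim("2018-06-04", "inpatient", los=3),
        ]
        rec = pppy_metrics(claims, "2018-05-01")
        assert rec["all_cause_claims"] == 4


class TestRelapse:
    def test_er_with_psychiatric_dx(self):
        assert detect_relapse_episodes([_claim("2018-06-01", "er", dx="F41.1")]) == 1

    def test_er_with_somatic_dx(self):
        assert detect_relapse_episodes([_claim("2018-06-01", "er", dx="I10")]) == 0

    def test_inpatient_primary_schizoaffective(self):
        assert detect_relapse_episodes(
            [_claim("2018-06-01", "inpatient", dx="F25.0", los=5)]
        ) == 1

    def test_inpatient_primary_hypertension(self):
        assert detect_relapse_episodes(
            [_claim("2018-06-01", "inpatient", dx="I10", los=5)]
        ) == 0

    def test_same_day_er_and_admission_count_twice(self):
        claims = [
            _claim("2018-06-01", "er", dx="F32.9", cid="x"),
            _claim("2018-06-01", "inpatient", dx="F20.9", los=4, cid="y"),
        ]
        assert detect_relapse_episodes(claims) == 2

    def test_window_filtering(self):
        claims = [_claim("2019-06-01", "er", dx="F41.1")]
        assert detect_relapse_episodes(claims, ("2018-05-01", "2019-05-01")) == 0


class TestComparisons:
    def test_chi_square_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 60, size=4)
            n = a + b + c + d
            closed = (
                n * (a * d - b * c) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            stat, p = chi_square_2x2(a, b, c, d)
            assert stat == pytest.approx(closed, rel=1e-10)
            assert p == pytest.approx(stats.chi2.sf(closed, 1), rel=1e-10)

    def test_worked_proportion_comparison(self):
        # 20/30 vs 10/30 -> Pearson statistic 20/3
        stat, _ = chi_square_2x2(20, 10, 10, 20)
        assert stat == pytest.approx(20 / 3, rel=1e-12)

    def test_degenerate_margin_flagged(self):
        stat, p = chi_square_2x2(0, 0, 3, 5)
        assert np.isnan(stat) and np.isnan(p)

    def _metrics_frame(self, values_by_pid):
        claims = []
        for pid, n in values_by_pid.items():
            claims += [
                _claim("2018-06-01", "outpatient", pid=pid, cid=f"{pid}_{j}")
                for j in range(n)
            ]
        idx = {pid: "2018-05-01" for pid in values_by_pid}
        return cohort_metrics(pd.DataFrame(claims), idx)

    def test_identical_strata_pvalues_trivial(self):
        mx = self._metrics_frame({"a": 3, "b": 5, "c": 3, "d": 5})
        impaired = pd.Series({"a": True, "b": True, "c": False, "d": False})
        summ = summarize_strata(mx, impaired).set_index("metric")
        assert summ.loc["outpatient_visits", "p_value"] == pytest.approx(1.0)

    def test_welch_antisymmetry(self):
        mx = self._metrics_frame({"a": 3, "b": 9, "c": 2, "d": 4, "e": 7})
        flags = pd.Series({"a": True, "b": True, "c": False, "d": False, "e": False})
        p1 = summarize_strata(mx, flags).set_index("metric").loc[
            "outpatient_visits", "p_value"]
        p2 = summarize_strata(mx, ~flags).set_index("metric").loc[
            "outpatient_visits", "p_value"]
        assert p1 == pytest.approx(p2)

    def test_empty_stratum_flagged_not_raised(self):
        mx = self._metrics_frame({"a": 3, "b": 5})
        impaired = pd.Series({"a": True, "b": True})
        summ = summarize_strata(mx, impaired).set_index("metric")
        assert summ.loc["outpatient_visits", "unimpaired_n"] == 0
        assert np.isnan(summ.loc["outpatient_visits", "p_value"])


class TestNBRegression:
    def _simulate(self, n, beta_imp, seed, k=2.0):
        rng = np.random.default_rng(seed)
        impaired = rng.random(n) < 0.3
        z = rng.normal(size=n)
        mu = np.exp(np.log(0.35) + beta_imp * impaired + 0.15 * z)
        y = rng.negative_binomial(k, k / (k + mu))
        X = pd.DataFrame({"impaired": impaired.astype(int), "z": z})
        return y, X

    def test_recovers_known_coefficients(self):
        y, X = self._simulate(20000, beta_imp=0.25, seed=0)
        res = fit_nb_regression(y, X)
        assert res.converged
        assert res.params["impaired"] == pytest.approx(0.25, abs=0.06)
        assert res.alpha == pytest.approx(0.5, abs=0.12)  # alpha = 1/k

    def test_poisson_limit_agreement(self):
        """On equidispersed counts the NB fit collapses to the Poisson GLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 8000
        impaired = (rng.random(n) < 0.5).astype(int)
        mu = np.exp(-1.0 + 0.3 * impaired)
        y = rng.poisson(mu)
        X = pd.DataFrame({"impaired": impaired})
        nb = fit_nb_regression(y, X)
        pois = sm.GLM(y, sm.add_constant(X.astype(float)),
                      family=sm.families.Poisson()).fit()
        assert nb.alpha < 0.05
        assert nb.params["impaired"] == pytest.approx(
            pois.params["impaired"], abs=0.02)

    def test_all_zero_outcomes_fail_loudly(self):
        X = pd.DataFrame({"impaired": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="zero"):
            fit_nb_regression([0, 0, 0, 0], X)

    def test_non_integer_outcomes_rejected(self):
        X = pd.DataFrame({"impaired": [0, 1]})
        with pytest.raises(ValueError, match="integer"):
            fit_nb_regression([0.5, 1.0], X)

    def test_missing_impairment_indicator_rejected(self):
        with pytest.raises(ValueError, match="impaired"):
            fit_nb_regression([1, 2], pd.DataFrame({"x": [0, 1]}))


class TestAdjustedRates:
    def test_null_impairment_effect_gives_ratio_near_one(self):
        rng = np.random.default_rng(2)
        n = 8000
        impaired = (rng.random(n) < 0.3).astype(int)
        y = rng.negative_binomial(2, 2 / (2 + 0.4), size=n)
        X = pd.DataFrame({"impaired": impaired})
        res = fit_nb_regression(y, X)
        r1, r0, ratio = adjusted_rates(res)
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_intercept_only_rates_equal_sample_mean(self):
        rng = np.random.default_rng(3)
        y = rng.negative_binomial(2, 2 / (2 + 0.5), size=4000)
        X = pd.DataFrame({"impaired": np.zeros(len(y), dtype=int)})
        # degenerate indicator -> model is effectively intercept-only
        res = fit_nb_regression(y + 0, X.assign(impaired=(np.arange(len(y)) % 2)))
        # with a balanced but outcome-independent indicator both adjusted
        # rates approach the sample mean
        r1, r0, _ = adjusted_rates(res)
        assert r1 == pytest.approx(y.mean(), rel=0.1)
        assert r0 == pytest.approx(y.mean(), rel=0.1)

    def test_invariance_to_covariate_recoding(self):
        rng = np.random.default_rng(4)
        n = 5000
        impaired = (rng.random(n) < 0.3).astype(int)
        flag = (rng.random(n) < 0.4).astype(int)
        mu = np.exp(-1.0 + 0.2 * impaired + 0.3 * flag)
        y = rng.negative_binomial(2, 2 / (2 + mu))
        X = pd.DataFrame({"impaired": impaired, "flag": flag})
        Xflip = X.assign(flag=1 - X["flag"])  # equivalent model, recoded level
        r_a = adjusted_rates(fit_nb_regression(y, X))
        r_b = adjusted_rates(fit_nb_regression(y, Xflip))
        assert r_a[2] == pytest.approx(r_b[2], rel=1e-4)
        assert r_a[0] == pytest.approx(r_b[0], rel=1e-4)


class TestDesignBuilder:
    def test_reference_level_is_largest_category(self):
        base = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c"],
                "age_at_index": [30, 40, 50],
                "cci": [0, 1, 2],
                "gender": ["male", "male", "female"],
                "race": ["white", "black", "white"],
                "region": ["west", "west", "south"],
                "anxiety": [0, 1, 0],
                "bipolar_disorder": [0, 0, 0],
                "depression": [1, 0, 0],
                "panic_disorder": [0, 0, 0],
                "ptsd": [0, 0, 0],
                "substance_use_disorder": [0, 0, 1],
            }
        )
        impaired = pd.Series([1, 0, 1], index=["a", "b", "c"])
        X = build_regression_design(base, impaired)
        assert "gender_male" not in X.columns  # male is reference
        assert "gender_female" in X.columns
        assert "race_white" not in X.columns
        assert {"impaired", "age", "cci", "anxiety"} <= set(X.columns)


class TestNoteBuckets:
    def _profile(self, pid, notes, impaired):
        return PatientImpairmentProfile(
            patient_id=pid,
            domain_flags={d: impaired for d in DOMAINS},
            category_flags={},
            any_impairment=impaired,
            retained_mention_count=int(impaired),
            note_count=notes,
        )

    def test_single_note_unimpaired_population(self):
        profiles = [self._profile(f"p{i}", 1, False) for i in range(5)]
        buckets = bucket_by_note_count(profiles).set_index("bucket")
        assert buckets.loc["<=5", "prevalence_pct"] == 0.0
        assert pd.isna(buckets.loc[">50", "prevalence_pct"])  # empty bucket

    def test_bucket_membership_boundaries(self):
        profiles = [
            self._profile("a", 5, True),
            self._profile("b", 6, True),
            self._profile("c", 50, False),
            self._profile("d", 51, True),
        ]
        buckets = bucket_by_note_count(profiles).set_index("bucket")
        assert buckets.loc["<=5", "n"] == 1
        assert buckets.loc["6-50", "n"] == 2
        assert buckets.loc[">50", "n"] == 1

    def test_coupled_generator_yields_monotone_prevalence(self):
        """Under the bundled logistic note-count link, documentation
        prevalence rises across the note buckets (~2.5% to ~52% at scale)."""
        from cogehr.synthetic_ehr import generate_dataset, published_calibration_config

        cfg = published_calibration_config().updated(
            {"n_patients": 4000, "include_notes": False}
        )
        ds = generate_dataset(cfg, seed=17)
        profiles = [
            self._profile(r["patient_id"], int(r["n_notes"]), bool(r["impaired"]))
            for r in ds.gold.to_dict("records")
        ]
        buckets = bucket_by_note_count(profiles)
        prevs = [p for p in buckets["prevalence_pct"] if p is not None]
        assert prevs == sorted(prevs)
        by = buckets.set_index("bucket")["prevalence_pct"]
        assert by["<=5"] < 8.0
        assert by[">50"] > 40.0
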