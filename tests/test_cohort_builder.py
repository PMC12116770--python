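"""Index dating, eligibility criteria, enrollment spans, baseline variables,
and whole-dataset cohorting against the generator's recorded draws."""

import numpy as np
import pytest

from cogehr.cohort_builder import (
    CohortCriteria,
    apply_ehr_criteria,
    baseline_characteristics,
    build_cohorts,
    check_continuous_enrollment,
    code_matches,
    find_index_date,
    normalize_code,
)


def _dx(day, code, setting="outpatient"):
    return {"patient_id": "p", "service_date": day, "code": code,
            "code_system": "icd9" if code[0].isdigit() else "icd10cm",
            "setting": setting, "primary": 1}


def _cov(start, end, benefit):
    return {"patient_id": "p", "start": start, "end": end, "benefit": benefit}


class TestCodeMatching:
    def test_normalization_strips_dots(self):
        assert normalize_code("F20.9") == "F209"
        assert code_matches("295.90", ["295"])
        assert code_matches("f20.9", ["F20"])
        assert not code_matches("F25.0", ["F20"])

    def test_prefix_match_agrees_with_naive_scan(self):
        rng = np.random.default_rng(0)
        pool = ["F20.9", "F25.0", "295.90", "296.1", "G30.9", "F2", "F419"]
        prefixes = ["295", "F20", "F41.9"]
        for _ in range(50):
            code = pool[rng.integers(len(pool))]
            naive = any(
                code.replace(".", "").upper().startswith(p.replace(".", "").upper())
                for p in prefixes
            )
            assert code_matches(code, prefixes) == naive


class TestFindIndexDate:
    def test_earliest_in_window(self):
        dx = [_dx("2017-01-10", "F20.9"), _dx("2016-03-15", "295.90")]
        assert find_index_date(dx) == "2016-03-15"

    def test_outside_window_absent(self):
        assert find_index_date([_dx("2015-06-01", "F20.9")]) is None
        assert find_index_date([_dx("2022-03-01", "F20.9")]) is None

    def test_leap_day_prefix_match(self):
        assert find_index_date([_dx("2020-02-29", "F20.9")]) == "2020-02-29"

    def test_non_sz_codes_ignored(self):
        assert find_index_date([_dx("2018-01-01", "I10")]) is None


class TestApplyCriteria:
    def _eligible_bundle(self):
        dx = [
            _dx("2018-05-01", "F20.9"),
            _dx("2018-07-01", "F20.0"),
            _dx("2017-01-15", "I10"),  # activity >12 months pre-index
        ]
        return dx, ["2018-04-01"]

    def test_all_criteria_met(self):
        dx, act = self._eligible_bundle()
        res = apply_ehr_criteria("p", 1980, dx, act)
        assert res.eligible_ehr and res.reasons == ()
        assert res.index_date == "2018-05-01"

    def test_single_encounter_insufficient(self):
        dx = [_dx("2018-05-01", "F20.9"), _dx("2017-01-15", "I10")]
        res = apply_ehr_criteria("p", 1980, dx, [])
        assert not res.eligible_ehr
        assert "insufficient_sz_encounters" in res.reasons

    def test_same_day_encounters_do_not_count_twice(self):
        dx = [_dx("2018-05-01", "F20.9"), _dx("2018-05-01", "F20.0"),
              _dx("2017-01-15", "I10")]
        res = apply_ehr_criteria("p", 1980, dx, [])
        assert "insufficient_sz_encounters" in res.reasons

    def test_under_18_at_index(self):
        dx, act = self._eligible_bundle()
        res = apply_ehr_criteria("p", 2003, dx, act)
        assert "under_18" in res.reasons

    def test_no_index_short_circuits(self):
        res = apply_ehr_criteria("p", 1980, [_dx("2015-01-01", "F20.9")], [])
        assert res.reasons == ("no_index_date",)
        assert res.index_date is None

    def test_insufficient_pre_index_activity(self):
        dx = [_dx("2018-05-01", "F20.9"), _dx("2018-07-01", "F20.0"),
              _dx("2018-01-15", "I10")]
        res = apply_ehr_criteria("p", 1980, dx, ["2018-02-01"])
        assert "no_pre_index_activity" in res.reasons

    def test_dementia_prior_to_index_excludes(self):
        dx, act = self._eligible_bundle()
        res = apply_ehr_criteria("p", 1980, dx + [_dx("2018-01-01", "G30.9")], act)
        assert "excluded_dx:dementia" in res.reasons

    def test_dementia_after_index_does_not_exclude(self):
        dx, act = self._eligible_bundle()
        res = apply_ehr_criteria("p", 1980, dx + [_dx("2019-01-01", "G30.9")], act)
        assert res.eligible_ehr

    def test_autism_excludes_at_any_time(self):
        dx, act = self._eligible_bundle()
        res = apply_ehr_criteria("p", 1980, dx + [_dx("2019-01-01", "F84.0")], act)
        assert "excluded_dx:autism" in res.reasons

    def test_all_failures_recorded_not_just_first(self):
        dx = [_dx("2018-05-01", "F20.9"), _dx("2018-04-20", "I10"),
              _dx("2017-06-01", "G40.909")]
        res = apply_ehr_criteria("p", 2004, dx, [])
        assert set(res.reasons) == {
            "under_18", "insufficient_sz_encounters", "no_pre_index_activity",
            "excluded_dx:epilepsy",
        }


class TestContinuousEnrollment:
    def test_single_covering_interval(self):
        ivs = [_cov("2018-01-01", "2019-06-30", "medical"),
               _cov("2018-01-01", "2019-06-30", "pharmacy")]
        assert check_continuous_enrollment(ivs, "2018-05-01", 12)

    def test_pharmacy_ends_at_month_eleven(self):
        ivs = [_cov("2018-01-01", "2019-06-30", "medical"),
               _cov("2018-01-01", "2019-04-01", "pharmacy")]
        assert not check_continuous_enrollment(ivs, "2018-05-01", 12)

    def test_missing_pharmacy_benefit(self):
        ivs = [_cov("2018-01-01", "2019-06-30", "medical")]
        assert not check_continuous_enrollment(ivs, "2018-05-01", 12)

    def test_abutting_intervals_zero_gap(self):
        ivs = [
            _cov("2018-04-01", "2018-10-31", "medical"),
            _cov("2018-11-01", "2019-06-30", "medical"),
            _cov("2018-01-01", "2019-06-30", "pharmacy"),
        ]
        assert check_continuous_enrollment(ivs, "2018-05-01", 12)

    def test_one_day_gap_fails_then_allowance_bridges(self):
        ivs = [
            _cov("2018-04-01", "2018-10-31", "medical"),
            _cov("2018-11-02", "2019-06-30", "medical"),
            _cov("2018-01-01", "2019-06-30", "pharmacy"),
        ]
        assert not check_continuous_enrollment(ivs, "2018-05-01", 12, gap_days=0)
        assert check_continuous_enrollment(ivs, "2018-05-01", 12, gap_days=1)

    def test_interval_union_agrees_with_day_scan_oracle(self):
        import pandas as pd

        rng = np.random.default_rng(4)
        index = pd.Timestamp("2018-05-01")
        for _ in range(30):
            ivs = []
            for benefit in ("medical", "pharmacy"):
                for _ in range(int(rng.integers(1, 4))):
                    s = index + pd.Timedelta(days=int(rng.integers(-200, 200)))
                    e = s + pd.Timedelta(days=int(rng.integers(0, 500)))
                    ivs.append(_cov(s.date().isoformat(), e.date().isoformat(), benefit))
            end = index + pd.DateOffset(months=12)
            days = pd.date_range(index, end, freq="D")
            oracle = all(
                all(
                    any(
                        pd.Timestamp(iv["start"]) <= d <= pd.Timestamp(iv["end"])
                        for iv in ivs
                        if iv["benefit"] == benefit
                    )
                    for d in days
                )
                for benefit in ("medical", "pharmacy")
            )
            got = check_continuous_enrollment(ivs, "2018-05-01", 12)
            assert got == oracle


class TestBaseline:
    _demo = {"patient_id": "p", "birth_year": 1980, "gender": "female",
             "race": "white", "ethnicity": "non_hispanic", "region": "west",
             "payer": "medicaid", "age_band": "18-44", "cci": 2}

    def _obs(self, day, bmi):
        return {"patient_id": "p", "obs_date": day, "bmi": bmi}

    def test_bmi_closest_wins(self):
        out = baseline_characteristics(
            self._demo, [],
            [self._obs("2018-04-01", 31.0), self._obs("2018-05-11", 28.0)],
            "2018-05-01",
        )
        assert out["bmi"] == 28.0  # +10 days beats -30 days

    def test_bmi_tie_prefers_pre_index(self):
        out = baseline_characteristics(
            self._demo, [],
            [self._obs("2018-04-21", 31.0), self._obs("2018-05-11", 28.0)],
            "2018-05-01",
        )
        assert out["bmi"] == 31.0

    def test_bmi_outside_year_ignored(self):
        out = baseline_characteristics(
            self._demo, [], [self._obs("2016-01-01", 31.0)], "2018-05-01"
        )
        assert out["bmi"] is None

    def test_comorbidity_window_is_twelve_months(self):
        dx_in = [_dx("2017-06-01", "F41.1")]
        dx_out = [_dx("2017-04-01", "F41.1")]  # 13 months pre-index
        base_in = baseline_characteristics(self._demo, dx_in, [], "2018-05-01")
        base_out = baseline_characteristics(self._demo, dx_out, [], "2018-05-01")
        assert base_in["anxiety"] and not base_out["anxiety"]

    def test_index_day_code_not_in_baseline_window(self):
        base = baseline_characteristics(
            self._demo, [_dx("2018-05-01", "F41.1")], [], "2018-05-01"
        )
        assert not base["anxiety"]  # window is [index - 12mo, index)

    def test_cci_and_age_carried(self):
        out = baseline_characteristics(self._demo, [], [], "2018-05-01")
        assert out["cci"] == 2 and out["age_at_index"] == 38


class TestBuildCohorts:
    def test_gold_agreement_and_subset_law(self, smoke_ds):
        res = build_cohorts(smoke_ds)
        gold = smoke_ds.gold.set_index("patient_id")
        elig = res["eligibility"].set_index("patient_id")
        assert (elig["eligible_ehr"].astype(int) == gold["eligible_ehr"]).all()
        assert (elig["eligible_linked"].astype(int) == gold["eligible_linked"]).all()
        assert set(res["linked_cohort"]) <= set(res["ehr_cohort"])

    def test_attrition_accounts_for_everyone(self, smoke_ds):
        res = build_cohorts(smoke_ds)
        assert res["attrition"]["dropped"].sum() == len(smoke_ds.patients)

    def test_row_order_invariance(self, smoke_ds):
        import copy

        shuffled = copy.copy(smoke_ds)
        rng = np.random.default_rng(0)
        shuffled.diagnoses = smoke_ds.diagnoses.sample(
            frac=1, random_state=1
        ).reset_index(drop=True)
        shuffled.coverage = smoke_ds.coverage.sample(
            frac=1, random_state=2
        ).reset_index(drop=True)
        shuffled.patients = smoke_ds.patients.sample(
            frac=1, random_state=3
        ).reset_index(drop=True)
        a = build_cohorts(smoke_ds)["eligibility"]
        b = build_cohorts(shuffled)["eligibility"]
        assert a.sort_values("patient_id").reset_index(drop=True).equals(
            b.sort_values("patient_id").reset_index(drop=True)
        )

    def test_forced_enrollment_gives_full_linked_cohort(self):
        from cogehr.synthetic_ehr import generate_dataset, smoke_small_config

        cfg = smoke_small_config().updated(
            {
                "n_patients": 40,
                "eligibility.p_under_18": 0.0,
                "eligibility.p_meets_sz_encounters": 1.0,
                "eligibility.p_pre_index_activity": 1.0,
                "eligibility.p_excluded_dx": 0.0,
                "eligibility.enrollment.impaired": 1.0,
                "eligibility.enrollment.not_impaired": 1.0,
            }
        )
        ds = generate_dataset(cfg, seed=2)
        res = build_cohorts(ds)
        assert len(res["ehr_cohort"]) == 40
        assert len(res["linked_cohort"]) == 40

    def test_zero_enrollment_empties_linked_cohort(self):
        from cogehr.synthetic_ehr import generate_dataset, smoke_small_config

        cfg = smoke_small_config().updated(
            {
                "n_patients": 40,
                "eligibility.enrollment.impaired": 0.0,
                "eligibility.enrollment.not_impaired": 0.0,
            }
        )
        ds = generate_dataset(cfg, seed=2)
        assert build_cohorts(ds)["linked_cohort"] == []
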