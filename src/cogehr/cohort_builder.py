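"""Cohort construction: index dates, inclusion/exclusion criteria, continuous
enrollment, baseline characteristics, and attrition accounting.

Implements the retrospective design used throughout the package: adults with
at least two outpatient schizophrenia encounters (ICD-9 295.xx / ICD-10-CM
F20.x) on or after the study window start, at least 12 months of EHR activity
before the first in-window schizophrenia diagnosis (the index date), and no
disqualifying neurological/developmental diagnoses.  The linked-claims
subcohort additionally requires continuous medical and pharmacy coverage for
12 months after index.

ICD codes are matched by string prefix on normalized codes (dots removed);
both code systems are accepted everywhere.  "EHR activity" means any recorded
event — a diagnosis record or a clinical note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import pandas as pd

from .synthetic_ehr import (
    ANY_TIME_CONDITIONS,
    PRIOR_TO_INDEX_CONDITIONS,
    SyntheticDataset,
)

__all__ = [
    "CohortCriteria",
    "EligibilityResult",
    "normalize_code",
    "code_matches",
    "find_index_date",
    "apply_ehr_criteria",
    "check_continuous_enrollment",
    "baseline_characteristics",
    "build_cohorts",
    "DEFAULT_CRITERIA",
]


def normalize_code(code: str) -> str:
    return str(code).replace(".", "").upper()


def code_matches(code: str, prefixes) -> bool:
    norm = normalize_code(code)
    return any(norm.startswith(normalize_code(p)) for p in prefixes)


_DEFAULT_EXCLUSIONS = {
    "dementia": ["F01", "F02", "F03", "G30"],
    "frontotemporal_disease": ["G310"],
    "prion_disease": ["A81"],
    "autism": ["F84"],
    "epilepsy": ["G40"],
    "intellectual_disability": ["F70", "F71", "F72", "F73", "F78", "F79"],
    "multiple_sclerosis": ["G35"],
    "parkinsons": ["G20"],
    "stroke": ["I63"],
    "tbi": ["S06"],
}

_DEFAULT_COMORBIDITY_PREFIXES = {
    "anxiety": ["F411", "F419"],
    "bipolar_disorder": ["F31"],
    "depression": ["F32", "F33"],
    "panic_disorder": ["F410"],
    "ptsd": ["F431"],
    "substance_use_disorder": ["F10", "F11", "F12", "F13", "F14", "F15", "F16", "F19"],
}


@dataclass(frozen=True)
class CohortCriteria:
    window_start: str = "2016-01-01"
    window_end: str = "2022-02-28"  # last admissible index date
    min_sz_outpatient_encounters: int = 2
    pre_index_activity_months: int = 12
    post_index_enrollment_months: int = 12
    min_age_years: int = 18
    schizophrenia_code_prefixes: tuple[str, ...] = ("295", "F20")
    exclusion_code_sets: dict = field(
        default_factory=lambda: dict(_DEFAULT_EXCLUSIONS)
    )
    exclusion_timing: dict = field(
        default_factory=lambda: {
            **{c: "prior_to_index" for c in PRIOR_TO_INDEX_CONDITIONS},
            **{c: "any_time" for c in ANY_TIME_CONDITIONS},
        }
    )
    enrollment_gap_days: int = 0  # allowed gap between coverage intervals
    comorbidity_code_prefixes: dict = field(
        default_factory=lambda: dict(_DEFAULT_COMORBIDITY_PREFIXES)
    )

    def __post_init__(self) -> None:
        if not self.window_start < self.window_end:
            raise ValueError("window_start must precede window_end")
        for name in (
            "min_sz_outpatient_encounters",
            "pre_index_activity_months",
            "post_index_enrollment_months",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CRITERIA = CohortCriteria()


@dataclass(frozen=True)
class EligibilityResult:
    patient_id: str
    eligible_ehr: bool
    eligible_linked: bool
    index_date: str | None
    reasons: tuple[str, ...]  # ordered failure codes


# -- individual checks -------------------------------------------------------

def _dates(records, attr="service_date"):
    return [r[attr] if isinstance(r, dict) else getattr(r, attr) for r in records]


def find_index_date(dx_records, crit: CohortCriteria = DEFAULT_CRITERIA) -> str | None:
    """Earliest schizophrenia-coded record inside the index window, or None.

    ``dx_records`` is an iterable of objects/dicts with ``service_date`` and
    ``code`` fields (e.g. :class:`DiagnosisRecord` or claims-table rows).
    """
    best = None
    for r in dx_records:
        code = r["code"] if isinstance(r, dict) else r.code
        day = r["service_date"] if isinstance(r, dict) else r.service_date
        if not code_matches(code, crit.schizophrenia_code_prefixes):
            continue
        if not (crit.window_start <= day <= crit.window_end):
            continue
        if best is None or day < best:
            best = day
    return best


def check_continuous_enrollment(
    intervals,
    index: str,
    months: int = 12,
    gap_days: int = 0,
) -> bool:
    """True iff medical AND pharmacy coverage each span ``[index, index +
    months]`` with no between-interval gap exceeding ``gap_days``.

    ``intervals`` carry ``start``/``end`` (inclusive dates) and ``benefit``.
    """
    start_needed = pd.Timestamp(index)
    end_needed = start_needed + pd.DateOffset(months=months)
    for benefit in ("medical", "pharmacy"):
        ivs = sorted(
            (
                (pd.Timestamp(r["start"] if isinstance(r, dict) else r.start),
                 pd.Timestamp(r["end"] if isinstance(r, dict) else r.end))
                for r in intervals
                if (r["benefit"] if isinstance(r, dict) else r.benefit) == benefit
            ),
        )
        covered_to = None
        for s, e in ivs:
            if covered_to is None:
                if s > start_needed:
                    continue  # starts after index; cannot begin coverage
                covered_to = e
            else:
                if (s - covered_to).days > gap_days + 1:
                    break  # unbridgeable gap
                covered_to = max(covered_to, e)
            if covered_to >= end_needed:
                break
        if covered_to is None or covered_to < end_needed:
            return False
    return True


def _age_at(index: str, birth_year: int) -> int:
    return int(index[:4]) - int(birth_year)


def apply_ehr_criteria(
    patient_id: str,
    birth_year: int,
    dx_records,
    activity_dates,
    crit: CohortCriteria = DEFAULT_CRITERIA,
) -> EligibilityResult:
    """Evaluate the EHR-stage criteria for one patient, recording every
    failure (not just the first).

    Checks, in fixed order: index date exists -> age >= 18 at index ->
    >=2 outpatient schizophrenia encounters on distinct dates on/after the
    window start -> earliest EHR activity >= 12 months before index -> no
    exclusion diagnosis per its timing rule.  ``activity_dates`` is every
    recorded EHR event date (diagnoses, notes, encounters).
    """
    reasons: list[str] = []
    index = find_index_date(dx_records, crit)
    if index is None:
        return EligibilityResult(patient_id, False, False, None, ("no_index_date",))

    if _age_at(index, birth_year) < crit.min_age_years:
        reasons.append("under_18")

    sz_dates = set()
    for r in dx_records:
        code = r["code"] if isinstance(r, dict) else r.code
        day = r["service_date"] if isinstance(r, dict) else r.service_date
        setting = r["setting"] if isinstance(r, dict) else r.setting
        if (
            setting == "outpatient"
            and day >= crit.window_start
            and code_matches(code, crit.schizophrenia_code_prefixes)
        ):
            sz_dates.add(day)
    if len(sz_dates) < crit.min_sz_outpatient_encounters:
        reasons.append("insufficient_sz_encounters")

    all_dates = list(activity_dates) + _dates(dx_records)
    earliest = min(all_dates) if all_dates else None
    cutoff = (
        pd.Timestamp(index) - pd.DateOffset(months=crit.pre_index_activity_months)
    ).date().isoformat()
    if earliest is None or earliest > cutoff:
        reasons.append("no_pre_index_activity")

    for cond, prefixes in crit.exclusion_code_sets.items():
        timing = crit.exclusion_timing.get(cond, "any_time")
        for r in dx_records:
            code = r["code"] if isinstance(r, dict) else r.code
            day = r["service_date"] if isinstance(r, dict) else r.service_date
            if not code_matches(code, prefixes):
                continue
            if timing == "prior_to_index" and day >= index:
                continue
            reasons.append(f"excluded_dx:{cond}")
            break

    eligible = not reasons
    return EligibilityResult(
        patient_id=patient_id,
        eligible_ehr=eligible,
        eligible_linked=False,  # decided by the enrollment stage
        index_date=index,
        reasons=tuple(reasons),
    )


# -- baseline characteristics -------------------------------------------------

def baseline_characteristics(
    demographics: dict,
    dx_records,
    bmi_observations,
    index: str,
    crit: CohortCriteria = DEFAULT_CRITERIA,
) -> dict:
    """Baseline record at index: demographics, 12-month pre-index comorbidity
    flags, BMI closest to index within +/-12 months (tie -> pre-index value),
    and the CCI score carried on the patient record.
    """
    out = dict(demographics)
    out["index_date"] = index
    out["age_at_index"] = _age_at(index, int(demographics["birth_year"]))

    idx = pd.Timestamp(index)
    lo = idx - pd.DateOffset(months=12)
    hi = idx + pd.DateOffset(months=12)
    for cond, prefixes in crit.comorbidity_code_prefixes.items():
        flag = False
        for r in dx_records:
            code = r["code"] if isinstance(r, dict) else r.code
            day = pd.Timestamp(r["service_date"] if isinstance(r, dict) else r.service_date)
            if lo <= day < idx and code_matches(code, prefixes):
                flag = True
                break
        out[cond] = flag

    best = None  # (abs_days, is_post, value)
    for r in bmi_observations:
        day = pd.Timestamp(r["obs_date"] if isinstance(r, dict) else r.obs_date)
        if not (lo <= day <= hi):
            continue
        dist = abs((day - idx).days)
        is_post = day > idx  # pre-index wins ties
        key = (dist, is_post)
        if best is None or key < best[0]:
            best = (key, float(r["bmi"] if isinstance(r, dict) else r.bmi))
    out["bmi"] = best[1] if best else None
    return out


# -- whole-dataset cohorting ---------------------------------------------------

#: Ordered attrition stages (first failing stage claims the patient).
_ATTRITION_ORDER = (
    "no_index_date",
    "under_18",
    "insufficient_sz_encounters",
    "no_pre_index_activity",
    "excluded_dx",
    "no_continuous_enrollment",
)


def build_cohorts(
    ds: SyntheticDataset,
    crit: CohortCriteria = DEFAULT_CRITERIA,
) -> dict:
    """Apply all criteria to a dataset.

    Returns ``{"eligibility": DataFrame, "ehr_cohort": [ids],
    "linked_cohort": [ids], "attrition": DataFrame, "baseline": DataFrame}``
    with linked_cohort always a subset of ehr_cohort.  Input row order never
    affects the outcome.
    """
    dx_by_pid: dict[str, list[dict]] = {}
    for r in ds.diagnoses.to_dict("records"):
        dx_by_pid.setdefault(r["patient_id"], []).append(r)
    cov_by_pid: dict[str, list[dict]] = {}
    for r in ds.coverage.to_dict("records"):
        cov_by_pid.setdefault(r["patient_id"], []).append(r)
    obs_by_pid: dict[str, list[dict]] = {}
    for r in ds.observations.to_dict("records"):
        obs_by_pid.setdefault(r["patient_id"], []).append(r)
    notes_by_pid: dict[str, list[str]] = {}
    for n in ds.notes:
        notes_by_pid.setdefault(n.patient_id, []).append(n.note_date)

    results: list[EligibilityResult] = []
    baselines: list[dict] = []
    patients = ds.patients.sort_values("patient_id").to_dict("records")
    for prec in patients:
        pid = prec["patient_id"]
        res = apply_ehr_criteria(
            pid,
            int(prec["birth_year"]),
            sorted(dx_by_pid.get(pid, []), key=lambda r: (r["service_date"], r["code"])),
            sorted(notes_by_pid.get(pid, [])),
            crit,
        )
        if res.eligible_ehr:
            enrolled = check_continuous_enrollment(
                cov_by_pid.get(pid, []),
                res.index_date,
                crit.post_index_enrollment_months,
                crit.enrollment_gap_days,
            )
            if enrolled:
                res = replace(res, eligible_linked=True)
            else:
                res = replace(res, reasons=("no_continuous_enrollment",))
            baselines.append(
                baseline_characteristics(
                    prec, dx_by_pid.get(pid, []), obs_by_pid.get(pid, []),
                    res.index_date, crit,
                )
            )
        results.append(res)

    elig = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "eligible_ehr": r.eligible_ehr,
                "eligible_linked": r.eligible_linked,
                "index_date": r.index_date or "",
                "reasons": ";".join(r.reasons),
            }
            for r in results
        ]
    )
    ehr_cohort = [r.patient_id for r in results if r.eligible_ehr]
    linked_cohort = [r.patient_id for r in results if r.eligible_linked]

    drops = {stage: 0 for stage in _ATTRITION_ORDER}
    for r in results:
        if r.eligible_linked:
            continue
        first = r.reasons[0] if r.reasons else ""
        stage = "excluded_dx" if first.startswith("excluded_dx") else first
        if stage in drops:
            drops[stage] += 1
    attrition = pd.DataFrame(
        {
            "criterion": list(_ATTRITION_ORDER),
            "dropped": [drops[s] for s in _ATTRITION_ORDER],
        }
    )
    attrition.loc[len(attrition)] = ["eligible_linked", len(linked_cohort)]

    return {
        "eligibility": elig,
        "ehr_cohort": ehr_cohort,
        "linked_cohort": linked_cohort,
        "attrition": attrition,
        "baseline": pd.DataFrame(baselines),
    }
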