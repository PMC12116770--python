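"""Healthcare-resource-utilization analysis over the linked-claims cohort.

Computes per-patient-per-year (PPPY) utilization metrics over the fixed
12-month post-index window (with a fixed window the PPPY rate equals the raw
annual count), stratifies by documented-impairment status, runs the simple
comparisons (Welch t-test for means, Pearson chi-square without continuity
correction for proportions, no multiplicity adjustment), and produces
adjusted estimates of inpatient admissions from a negative binomial
regression via marginal standardization (g-computation): every patient's
expected count is predicted with the impairment indicator forced to 1 and
then to 0, and the two averages are the adjusted rates.

A relapse episode is an ER claim with any psychiatric diagnosis or an
inpatient claim with a primary schizophrenia/schizoaffective diagnosis; each
qualifying claim counts as one episode (no same-stay merging).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic_ehr import PHARMACY_CLASSES, PSYCHOSOCIAL_COMPONENTS
from .cohort_builder import code_matches

__all__ = [
    "RelapseDefinition",
    "RegressionResult",
    "pppy_metrics",
    "detect_relapse_episodes",
    "cohort_metrics",
    "summarize_strata",
    "build_regression_design",
    "fit_nb_regression",
    "adjusted_rates",
    "bucket_by_note_count",
]

COUNT_METRICS = (
    "all_cause_claims",
    "total_hospitalized_days",
    "inpatient_admissions",
    "er_visits",
    "outpatient_visits",
    "pharmacy_claims",
    "relapse_episodes",
)


@dataclass(frozen=True)
class RelapseDefinition:
    """Configurable code sets for relapse counting."""

    psychiatric_prefixes: tuple[str, ...] = ("F",)  # any ICD-10 F-chapter code
    sz_primary_prefixes: tuple[str, ...] = ("F20", "F25", "295")


DEFAULT_RELAPSE = RelapseDefinition()


def _claims_frame(claims) -> pd.DataFrame:
    if isinstance(claims, pd.DataFrame):
        return claims
    rows = []
    for c in claims:
        if isinstance(c, dict):
            rows.append(c)
        else:
            rows.append(
                {
                    "claim_id": c.claim_id,
                    "patient_id": c.patient_id,
                    "service_date": c.service_date,
                    "claim_type": c.claim_type,
                    "primary_dx": c.primary_dx,
                    "length_of_stay_days": c.length_of_stay_days,
                    "service_class": c.service_class,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "claim_id", "patient_id", "service_date", "claim_type",
            "primary_dx", "length_of_stay_days", "service_class",
        ],
    )


def _is_relapse(df: pd.DataFrame, definition: RelapseDefinition) -> pd.Series:
    dx = df["primary_dx"].fillna("").astype(str)
    er_psych = (df["claim_type"] == "er") & dx.map(
        lambda c: bool(c) and code_matches(c, definition.psychiatric_prefixes)
    )
    ip_sz = (df["claim_type"] == "inpatient") & dx.map(
        lambda c: bool(c) and code_matches(c, definition.sz_primary_prefixes)
    )
    return er_psych | ip_sz


def detect_relapse_episodes(
    claims,
    window: tuple[str, str] | None = None,
    definition: RelapseDefinition = DEFAULT_RELAPSE,
) -> int:
    """Count relapse episodes for one patient's claims.

    ``window`` is an optional half-open ISO-date interval ``[start, end)``.
    Each qualifying claim is one episode.
    """
    df = _claims_frame(claims)
    if df.empty:
        return 0
    if window is not None:
        mask = (df["service_date"] >= window[0]) & (df["service_date"] < window[1])
        df = df[mask]
    return int(_is_relapse(df, definition).sum())


def cohort_metrics(
    claims,
    index_dates: pd.Series | dict,
    months: int = 12,
    definition: RelapseDefinition = DEFAULT_RELAPSE,
) -> pd.DataFrame:
    """Per-patient PPPY metrics over ``[index, index + months)`` for every
    patient in ``index_dates``.

    Claims outside a patient's window are ignored (their count is reported in
    the ``claims_out_of_window`` column for audit).  Length of stay per
    admission is defined only for patients with at least one admission.
    """
    idx = pd.Series(index_dates, name="index_date")
    idx.index.name = "patient_id"
    df = _claims_frame(claims).merge(
        idx.rename("index_date").reset_index(), on="patient_id", how="inner"
    )
    if not df.empty:
        start = pd.to_datetime(df["index_date"])
        day = pd.to_datetime(df["service_date"])
        end = start + pd.DateOffset(months=months)
        df["in_window"] = (day >= start) & (day < end)
    else:
        df["in_window"] = pd.Series(dtype=bool)

    out = pd.DataFrame(index=pd.Index(idx.index, name="patient_id"))
    out_of = df[~df["in_window"]].groupby("patient_id").size()
    out["claims_out_of_window"] = out_of.reindex(out.index).fillna(0).astype(int)
    dfw = df[df["in_window"]].copy()

    counts = (
        dfw.pivot_table(index="patient_id", columns="claim_type",
                        values="claim_id", aggfunc="count", fill_value=0)
        if not dfw.empty
        else pd.DataFrame()
    )
    for ctype, name in [
        ("outpatient", "outpatient_visits"),
        ("pharmacy", "pharmacy_claims"),
        ("er", "er_visits"),
        ("inpatient", "inpatient_admissions"),
    ]:
        col = counts[ctype] if ctype in counts.columns else pd.Series(dtype=int)
        out[name] = col.reindex(out.index).fillna(0).astype(int)
    out["all_cause_claims"] = (
        out["outpatient_visits"] + out["pharmacy_claims"]
        + out["er_visits"] + out["inpatient_admissions"]
    )

    ip = dfw[dfw["claim_type"] == "inpatient"].copy()
    ip["length_of_stay_days"] = pd.to_numeric(
        ip["length_of_stay_days"], errors="coerce"
    )
    los = ip.groupby("patient_id")["length_of_stay_days"].sum()
    out["total_hospitalized_days"] = los.reindex(out.index).fillna(0).astype(float)
    out["los_per_admission"] = np.where(
        out["inpatient_admissions"] > 0,
        out["total_hospitalized_days"] / out["inpatient_admissions"].replace(0, np.nan),
        np.nan,
    )

    if not dfw.empty:
        rel = dfw[_is_relapse(dfw, definition)].groupby("patient_id").size()
    else:
        rel = pd.Series(dtype=int)
    out["relapse_episodes"] = rel.reindex(out.index).fillna(0).astype(int)

    psycho = dfw[dfw["service_class"].isin(PSYCHOSOCIAL_COMPONENTS)]
    tdays = psycho.groupby("patient_id")["service_date"].nunique()
    out["therapy_days"] = tdays.reindex(out.index).fillna(0).astype(int)
    out["any_psychosocial"] = out["therapy_days"] > 0
    for comp in PSYCHOSOCIAL_COMPONENTS:
        has = dfw[dfw["service_class"] == comp].groupby("patient_id").size()
        out[f"psychosocial_{comp}"] = has.reindex(out.index).notna()

    rx = dfw[(dfw["claim_type"] == "pharmacy")
             & dfw["service_class"].isin(PHARMACY_CLASSES)]
    out["any_psych_pharmacy"] = (
        rx.groupby("patient_id").size().reindex(out.index).notna()
    )
    for cls in PHARMACY_CLASSES:
        has = dfw[(dfw["claim_type"] == "pharmacy")
                  & (dfw["service_class"] == cls)].groupby("patient_id").size()
        out[f"pharmacy_{cls}"] = has.reindex(out.index).notna()
    return out


def pppy_metrics(
    claims,
    index: str,
    months: int = 12,
    definition: RelapseDefinition = DEFAULT_RELAPSE,
) -> dict:
    """PPPY metrics for a single patient (see :func:`cohort_metrics`)."""
    df = _claims_frame(claims)
    pid = df["patient_id"].iloc[0] if not df.empty else "_single"
    df["patient_id"] = pid
    table = cohort_metrics(df, {pid: index}, months, definition)
    rec = table.iloc[0].to_dict()
    if table["inpatient_admissions"].iloc[0] == 0:
        rec["los_per_admission"] = None
    return rec


# -- stratified summaries -----------------------------------------------------

MEAN_METRICS = (
    "all_cause_claims", "total_hospitalized_days", "los_per_admission",
    "inpatient_admissions", "er_visits", "outpatient_visits",
    "pharmacy_claims", "relapse_episodes", "therapy_days",
)
PROPORTION_METRICS = (
    ("any_psychosocial",)
    + tuple(f"psychosocial_{c}" for c in PSYCHOSOCIAL_COMPONENTS)
    + ("any_psych_pharmacy",)
    + tuple(f"pharmacy_{c}" for c in PHARMACY_CLASSES)
)
#: Metrics averaged over a restricted denominator.
_RESTRICTED = {
    "los_per_admission": lambda df: df["inpatient_admissions"] > 0,
    "therapy_days": lambda df: df["any_psychosocial"],
}


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return np.nan
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on the 2x2 table
    [[a, b], [c, d]]; returns (statistic, p)."""
    table = np.array([[a, b], [c, d]], float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan, np.nan
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def summarize_strata(metrics: pd.DataFrame, impaired: pd.Series) -> pd.DataFrame:
    """Stratified HCRU summary with per-metric comparisons.

    ``metrics`` is the :func:`cohort_metrics` table; ``impaired`` a boolean
    Series aligned on patient_id.  Means use Welch's t, proportions Pearson's
    chi-square; p-values are unadjusted.  An empty stratum yields summaries
    with comparisons flagged undefined (NaN).
    """
    flag = impaired.reindex(metrics.index).astype(bool)
    grp = {True: metrics[flag], False: metrics[~flag]}
    rows = []
    for metric in MEAN_METRICS:
        vals = {}
        for key, gdf in grp.items():
            sub = gdf[_RESTRICTED[metric](gdf)] if metric in _RESTRICTED else gdf
            v = sub[metric].astype(float).dropna()
            vals[key] = v
        rows.append(
            {
                "metric": metric,
                "kind": "mean",
                "impaired_n": len(vals[True]),
                "impaired_value": float(vals[True].mean()) if len(vals[True]) else np.nan,
                "impaired_sd": float(vals[True].std()) if len(vals[True]) > 1 else np.nan,
                "unimpaired_n": len(vals[False]),
                "unimpaired_value": float(vals[False].mean()) if len(vals[False]) else np.nan,
                "unimpaired_sd": float(vals[False].std()) if len(vals[False]) > 1 else np.nan,
                "p_value": _welch(vals[True], vals[False]),
            }
        )
    for metric in PROPORTION_METRICS:
        a = int(grp[True][metric].sum())
        na = len(grp[True])
        c = int(grp[False][metric].sum())
        nc = len(grp[False])
        _, p = chi_square_2x2(a, na - a, c, nc - c) if na and nc else (np.nan, np.nan)
        rows.append(
            {
                "metric": metric,
                "kind": "proportion",
                "impaired_n": na,
                "impaired_value": a / na if na else np.nan,
                "impaired_sd": np.nan,
                "unimpaired_n": nc,
                "unimpaired_value": c / nc if nc else np.nan,
                "unimpaired_sd": np.nan,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


# -- negative binomial regression ---------------------------------------------

REGRESSION_COVARIATES = (
    "age", "gender", "race", "region", "cci", "anxiety", "bipolar_disorder",
    "depression", "panic_disorder", "ptsd", "substance_use_disorder",
)


def build_regression_design(
    baseline: pd.DataFrame, impaired: pd.Series
) -> pd.DataFrame:
    """Design matrix: impairment indicator plus the adjustment covariates
    (age, gender, race, region, CCI score, and the six psychiatric
    comorbidities).  Categorical covariates enter as indicators with the
    largest category as reference.
    """
    df = baseline.set_index("patient_id") if "patient_id" in baseline else baseline
    X = pd.DataFrame(index=df.index)
    X["impaired"] = impaired.reindex(df.index).astype(int)
    X["age"] = df["age_at_index"].astype(float)
    X["cci"] = df["cci"].astype(float)
    for cond in REGRESSION_COVARIATES[5:]:
        X[cond] = df[cond].astype(int)
    for cat in ("gender", "race", "region"):
        counts = df[cat].value_counts()
        ref = sorted(counts[counts == counts.max()].index)[0]
        for level in sorted(counts.index):
            if level == ref:
                continue
            X[f"{cat}_{level}"] = (df[cat] == level).astype(int)
    return X


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    alpha: float  # NB2 dispersion (variance = mu + alpha * mu^2)
    converged: bool
    llf: float
    design: pd.DataFrame = field(repr=False)
    _sm_result: object = field(repr=False, default=None)

    @property
    def impairment_pvalue(self) -> float:
        return float(self.pvalues["impaired"])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        exog = sm.add_constant(X, has_constant="add")[self.design.columns.insert(0, "const")]
        return np.asarray(self._sm_result.predict(exog))


def fit_nb_regression(outcome, design: pd.DataFrame) -> RegressionResult:
    """Maximum-likelihood NB2 regression with log link.

    ``outcome`` are nonnegative integer counts over the fixed 12-month
    exposure (no offset); ``design`` must contain the ``impaired`` indicator.
    Fails loudly on degenerate outcomes or non-convergence.
    """
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(design):
        raise ValueError("outcome and design lengths differ")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("outcome must be nonnegative integer counts")
    if y.max() == 0:
        raise ValueError("all outcomes are zero; count model is degenerate")
    if "impaired" not in design.columns:
        raise ValueError("design must include the 'impaired' indicator")
    exog = sm.add_constant(design.astype(float), has_constant="add")
    model = sm.NegativeBinomial(y, exog)
    with np.errstate(all="ignore"):
        res = model.fit(disp=0, maxiter=200, method="bfgs", gtol=1e-6)
        if not res.mle_retvals.get("converged", False):
            res = model.fit(disp=0, maxiter=500, method="nm",
                            start_params=res.params)
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        raise RuntimeError(
            "negative binomial fit did not converge; check for separation or "
            "a degenerate design"
        )
    params = res.params.drop(labels=["alpha"])
    return RegressionResult(
        params=params,
        bse=res.bse.drop(labels=["alpha"]),
        pvalues=res.pvalues.drop(labels=["alpha"]),
        alpha=float(res.params["alpha"]),
        converged=converged,
        llf=float(res.llf),
        design=design,
        _sm_result=res,
    )


def adjusted_rates(result: RegressionResult, design: pd.DataFrame | None = None):
    """Marginally standardized rates: predict every patient's expected count
    with the impairment indicator forced to 1 and then to 0, and average.

    Returns ``(rate_impaired, rate_unimpaired, ratio)``.
    """
    X = (design if design is not None else result.design).copy()
    X1, X0 = X.copy(), X.copy()
    X1["impaired"] = 1
    X0["impaired"] = 0
    r1 = float(np.mean(result.predict(X1)))
    r0 = float(np.mean(result.predict(X0)))
    return r1, r0, r1 / r0


# -- documentation vs note volume ---------------------------------------------

DEFAULT_NOTE_BUCKETS = (("<=5", 0, 5), ("6-50", 6, 50), (">50", 51, None))


def bucket_by_note_count(
    profiles, buckets=DEFAULT_NOTE_BUCKETS
) -> pd.DataFrame:
    """Documented-impairment prevalence per note-count bucket."""
    rows = []
    for label, lo, hi in buckets:
        members = [
            p for p in profiles
            if p.note_count >= lo and (hi is None or p.note_count <= hi)
        ]
        n = len(members)
        doc = sum(p.any_impairment for p in members)
        rows.append(
            {
                "bucket": label,
                "n": n,
                "documented": doc,
                "prevalence_pct": round(100.0 * doc / n, 2) if n else None,
            }
        )
    return pd.DataFrame(rows)
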