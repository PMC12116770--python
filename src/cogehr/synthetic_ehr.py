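"""Synthetic linked EHR + claims generator with gold labels.

Generates cohorts whose statistical structure matches what the downstream
pipeline assumes: a documented-impairment prevalence, per-domain phrase
planting with configurable conditional marginals, decoy sentences that
exercise the exclusion rules (negated / question / goal / family-history
phrasings of real lexicon terms), eligibility-criterion satisfaction recorded
per patient, and negative-binomial utilization streams per stratum.

Every negative-binomial stream uses the (mean ``mu``, dispersion ``k``)
parameterization with variance ``mu + mu**2 / k``.

Domain planting: the configured ``domain_marginals`` are *conditional* on a
patient having at least one documented domain (the form in which such
marginals are reported).  The generator back-solves unconditional Bernoulli
probabilities ``p_d = t_d * (1 - q)`` where ``q`` solves
``q = prod_d (1 - t_d * (1 - q))`` (the empty-set probability), then
rejection-samples non-empty domain sets, so the conditional marginals equal
the configured targets exactly in expectation.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .lexicon import DOMAINS, Lexicon, default_lexicon
from .nlp_extractor import ClinicalNote

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "DiagnosisRecord",
    "CoverageInterval",
    "ClaimRecord",
    "generate_dataset",
    "render_note",
    "write_dataset",
    "load_dataset",
    "load_config",
    "published_calibration_config",
    "smoke_small_config",
]

_DATA_DIR = Path(__file__).parent / "data"

PSYCHOSOCIAL_COMPONENTS = (
    "cbt", "psychotherapy", "family_therapy", "psychosocial_rehab", "group_therapy",
)
PHARMACY_CLASSES = ("fga", "sga", "mood_stabilizer", "antidepressant")
COMORBIDITIES = (
    "anxiety", "bipolar_disorder", "depression", "panic_disorder", "ptsd",
    "substance_use_disorder",
)

#: Exclusion conditions whose codes disqualify only when dated before index.
PRIOR_TO_INDEX_CONDITIONS = (
    "stroke", "dementia", "prion_disease", "multiple_sclerosis", "tbi",
    "frontotemporal_disease", "parkinsons",
)
#: Conditions disqualifying when coded at any time.
ANY_TIME_CONDITIONS = ("autism", "epilepsy", "intellectual_disability")


# -- structured-record domain types -----------------------------------------

@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    service_date: str  # ISO-8601
    code: str
    code_system: str  # icd9 | icd10cm
    setting: str  # outpatient | inpatient | er
    primary: bool = True


@dataclass(frozen=True)
class CoverageInterval:
    patient_id: str
    start: str  # inclusive
    end: str  # inclusive
    benefit: str  # medical | pharmacy


@dataclass(frozen=True)
class ClaimRecord:
    claim_id: str
    patient_id: str
    service_date: str
    claim_type: str  # inpatient | outpatient | er | pharmacy
    primary_dx: str
    other_dx: tuple[str, ...] = ()
    length_of_stay_days: int | None = None  # inpatient only
    service_class: str = ""


class ConfigError(ValueError):
    """Invalid generator configuration (raised before any output)."""


# -- configuration -----------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Validated wrapper around the YAML generator configuration."""

    raw: dict = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # mapping-style access helpers
    def __getitem__(self, key: str):
        return self.raw[key]

    def get(self, key: str, default=None):
        return self.raw.get(key, default)

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def n_patients(self) -> int:
        return int(self.raw["n_patients"])

    def to_dict(self) -> dict:
        return copy.deepcopy(self.raw)

    def updated(self, overrides: dict) -> "GeneratorConfig":
        """New config with dotted-key overrides, e.g.
        ``{"n_patients": 100, "note_count_coupling.enabled": False}``."""
        raw = copy.deepcopy(self.raw)
        for key, value in overrides.items():
            node = raw
            parts = key.split(".")
            for p in parts[:-1]:
                node = node.setdefault(p, {})
            node[parts[-1]] = value
        return GeneratorConfig(raw)

    def validate(self) -> None:
        r = self.raw
        if int(r.get("n_patients", -1)) < 0:
            raise ConfigError("n_patients must be a nonnegative integer")
        for key in ("impairment_prevalence", "html_markup_rate"):
            v = float(r[key])
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{key} must be a probability, got {v}")
        marg = r["domain_marginals"]
        for d in DOMAINS:
            if d not in marg:
                raise ConfigError(f"domain_marginals missing domain {d!r}")
            if not 0.0 <= float(marg[d]) <= 1.0:
                raise ConfigError(f"domain_marginals[{d}] not a probability")
        if sum(float(marg[d]) for d in DOMAINS) <= 1.0 and any(
            float(marg[d]) > 0 for d in DOMAINS
        ):
            # conditional marginals must average >= 1 domain per impaired patient
            raise ConfigError(
                "domain_marginals sum to <= 1; conditional-on-any marginals "
                "require the expected number of documented domains to exceed 1"
            )
        for kind, v in r["confounder_rates"].items():
            if not 0.0 <= float(v) <= 1.0:
                raise ConfigError(f"confounder_rates[{kind}] not a probability")
        for metric, groups in r["utilization"].items():
            for grp, ps in groups.items():
                if float(ps["dispersion"]) <= 0:
                    raise ConfigError(
                        f"utilization[{metric}][{grp}]: dispersion must be > 0"
                    )
                if float(ps["mean"]) < 0:
                    raise ConfigError(
                        f"utilization[{metric}][{grp}]: mean must be >= 0"
                    )
        win = r["date_window"]
        if not (str(win["start"]) < str(win["index_end"]) <= str(win["end"])):
            raise ConfigError("date_window must satisfy start < index_end <= end")


def load_config(path: str | Path) -> GeneratorConfig:
    """Load a generator config; a top-level ``inherits: <bundled name>`` key
    merges the file over the named bundled config."""
    raw = yaml.safe_load(Path(path).read_text())
    if "inherits" in raw:
        base = yaml.safe_load((_DATA_DIR / f"{raw.pop('inherits')}.yaml").read_text())
        merged = copy.deepcopy(base)
        merged.update(raw)
        raw = merged
    return GeneratorConfig(raw)


def published_calibration_config() -> GeneratorConfig:
    return load_config(_DATA_DIR / "published_calibration.yaml")


def smoke_small_config() -> GeneratorConfig:
    return load_config(_DATA_DIR / "smoke_small.yaml")


# -- dataset container -------------------------------------------------------

_TABLES = (
    "patients", "diagnoses", "coverage", "claims", "observations",
    "gold", "gold_mentions",
)


@dataclass
class SyntheticDataset:
    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    coverage: pd.DataFrame
    claims: pd.DataFrame
    observations: pd.DataFrame  # BMI measurements
    gold: pd.DataFrame
    gold_mentions: pd.DataFrame
    notes: list[ClinicalNote]
    config: dict
    seed: int

    def equals(self, other: "SyntheticDataset") -> bool:
        for name in _TABLES:
            a, b = getattr(self, name), getattr(other, name)
            try:
                pd.testing.assert_frame_equal(a, b, check_dtype=False)
            except AssertionError:
                return False
        return self.notes == other.notes and self.seed == other.seed


# -- note rendering ----------------------------------------------------------

_CLEAN_TEMPLATES = (
    "Patient demonstrates {p}.",
    "Exam notable for {p}.",
    "Patient reports {p}.",
    "Clinician observed {p} during the visit.",
    "{P} evident on assessment.",
)
_QUALIFIED_TEMPLATE = "{P} clearly impaired on exam."
_DECOY_TEMPLATES = {
    "negation": ("Denies {p}.", "Negative for {p}.", "Without {p}."),
    "question": ("Any {p}?", "Could this represent {p}?"),
    "goal": ("Goal: address {p} next visit.", "Will work on {p} strategies."),
    "family_history": ("Mother has {p}.", "Family history of {p}."),
}
_FILLERS = (
    "Vital signs stable.",
    "Medication refilled at this visit.",
    "Sleep reported as adequate.",
    "Appetite within normal limits.",
    "BMI 30.1 recorded today.",
    "Continues current treatment regimen.",
    "Attended appointment on time.",
    "Labs reviewed with patient.",
)


def _planted_phrase(entry) -> str:
    """Surface phrase for planting; qualifier-gated entries carry their
    qualifier so the phrase is detectable (e.g. 'impaired insight and
    judgment')."""
    if entry.sentence_qualifiers:
        return f"impaired {entry.canonical}"
    return entry.canonical


def _event_sentence(entry, kind: str, rng: np.random.Generator) -> str:
    if kind == "clean":
        if entry.sentence_qualifiers:
            return _QUALIFIED_TEMPLATE.format(P=entry.canonical.capitalize())
        tmpl = _CLEAN_TEMPLATES[rng.integers(len(_CLEAN_TEMPLATES))]
        return tmpl.format(p=entry.canonical, P=entry.canonical.capitalize())
    tmpls = _DECOY_TEMPLATES[kind]
    phrase = _planted_phrase(entry)
    return tmpls[rng.integers(len(tmpls))].format(p=phrase)


def render_note(
    events: list[tuple],
    rng: np.random.Generator,
    html_markup_rate: float = 0.0,
    n_filler: int | None = None,
) -> str:
    """Render one note from (LexiconEntry, kind) events plus filler sentences.

    ``kind`` is "clean" or one of the decoy kinds.  Clean phrases appear in
    affirmative declarative sentences; decoys appear under their trigger
    construction; fillers contain no lexicon phrase.  With probability
    ``html_markup_rate`` the note is wrapped in HTML paragraph markup.
    """
    if n_filler is None:
        n_filler = int(rng.integers(2, 5))
    sentences = [_event_sentence(e, kind, rng) for e, kind in events]
    sentences += [_FILLERS[rng.integers(len(_FILLERS))] for _ in range(n_filler)]
    order = rng.permutation(len(sentences))
    sentences = [sentences[i] for i in order]
    if rng.random() < html_markup_rate:
        return "<html><body>" + "".join(f"<p>{s}</p>" for s in sentences) + "</body></html>"
    return " ".join(sentences)


# -- planting-probability fixed point ----------------------------------------

def conditional_plant_probs(marginals: dict[str, float]) -> tuple[np.ndarray, float]:
    """Unconditional planting probabilities realizing the conditional
    marginals, and the empty-set probability ``q`` of the unconditional law."""
    t = np.array([float(marginals[d]) for d in DOMAINS])
    if t.sum() == 0:
        return t, 1.0

    def f(q: float) -> float:
        return float(np.prod(1.0 - t * (1.0 - q)) - q)

    if f(0.0) <= 1e-12:
        q = 0.0
    else:
        q = brentq(f, 0.0, 1.0 - 1e-9)
    return t * (1.0 - q), q


# -- generation ---------------------------------------------------------------

def _nb_draw(rng, mean: float, k: float, size=None):
    if mean <= 0:
        return np.zeros(size if size is not None else (), dtype=int)
    return rng.negative_binomial(k, k / (k + mean), size=size)


def _cci_draw(rng, mean: float, sd: float) -> int:
    var = sd * sd
    if var > mean > 0:
        return int(_nb_draw(rng, mean, mean * mean / (var - mean)))
    return int(rng.poisson(mean)) if mean > 0 else 0


def _choice(rng, dist: dict) -> str:
    keys = list(dist)
    probs = np.array([float(dist[k]) for k in keys])
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


_AGE_RANGES = {"18-44": (18, 45), "45-64": (45, 65), "65+": (65, 86)}


def generate_dataset(
    cfg: GeneratorConfig,
    seed: int | None = None,
    lexicon: Lexicon | None = None,
) -> SyntheticDataset:
    """Generate a linked synthetic dataset; reproducible for a fixed seed."""
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    lex = lexicon if lexicon is not None else default_lexicon()
    include_notes = bool(cfg.get("include_notes", True))

    win_start = date.fromisoformat(str(cfg["date_window"]["start"]))
    idx_end = date.fromisoformat(str(cfg["date_window"]["index_end"]))
    idx_span = (idx_end - win_start).days

    plant_p, _ = conditional_plant_probs(cfg["domain_marginals"])
    coupling = cfg.get("note_count_coupling", {"enabled": False})
    npp = cfg["notes_per_patient"]
    conf_rates = {k: float(v) for k, v in cfg["confounder_rates"].items()}
    conf_kinds = list(conf_rates)
    elig = cfg["eligibility"]
    demo = cfg["demographics"]
    codes = cfg["dx_codes"]
    relapse = cfg["relapse_content"]
    tx = cfg["treatment_patterns"]
    html_rate = float(cfg["html_markup_rate"])

    # entry lookup: domain -> (entries, weights) from category weights
    entries_by_domain: dict[str, tuple[list, np.ndarray]] = {}
    for d in DOMAINS:
        weights = cfg["category_weights"][d]
        ents = []
        ws = []
        for e in lex.by_domain(d):
            if e.category not in weights:
                raise ConfigError(
                    f"category_weights[{d}] missing category {e.category!r}"
                )
            ents.append(e)
            ws.append(float(weights[e.category]))
        w = np.array(ws)
        entries_by_domain[d] = (ents, w / w.sum())
    all_entries = list(lex.entries)

    patients_rows, dx_rows, cov_rows, claim_rows = [], [], [], []
    obs_rows, gold_rows, gmention_rows = [], [], []
    notes: list[ClinicalNote] = []

    for i in range(cfg.n_patients):
        pid = f"P{i:06d}"
        n_notes = int(npp.get("shift", 1)) + int(
            _nb_draw(rng, float(npp["mean"]) - 0, float(npp["dispersion"]))
        )

        if coupling.get("enabled", False):
            p_imp = 1.0 / (
                1.0
                + np.exp(
                    -(float(coupling["intercept"]) + float(coupling["slope"]) * np.log(n_notes))
                )
            )
        else:
            p_imp = float(cfg["impairment_prevalence"])
        impaired = bool(rng.random() < p_imp)
        group = "impaired" if impaired else "not_impaired"

        domains: list[str] = []
        if impaired:
            while not domains:
                mask = rng.random(len(DOMAINS)) < plant_p
                domains = [d for d, m in zip(DOMAINS, mask) if m]

        # eligibility draws
        under_18 = rng.random() < float(elig["p_under_18"])
        meets_sz = rng.random() < float(elig["p_meets_sz_encounters"])
        pre_activity = rng.random() < float(elig["p_pre_index_activity"])
        excluded_cond = ""
        if rng.random() < float(elig["p_excluded_dx"]):
            pool = PRIOR_TO_INDEX_CONDITIONS + ANY_TIME_CONDITIONS
            excluded_cond = pool[rng.integers(len(pool))]
        enrolled = rng.random() < float(elig["enrollment"][group])
        eligible_ehr = (not under_18) and meets_sz and pre_activity and not excluded_cond
        eligible_linked = eligible_ehr and enrolled

        index = win_start + timedelta(days=int(rng.integers(0, idx_span + 1)))

        band = _choice(rng, demo["age_bands"])
        lo, hi = _AGE_RANGES[band]
        age = int(rng.integers(lo, hi))
        if under_18:
            age = int(rng.integers(13, 18))
        birth_year = index.year - age

        cci_ps = cfg["cci_distribution"][group]
        cci = _cci_draw(rng, float(cci_ps["mean"]), float(cci_ps["sd"]))

        patients_rows.append(
            {
                "patient_id": pid,
                "birth_year": birth_year,
                "age_band": band,
                "gender": _choice(rng, demo["gender"]),
                "race": _choice(rng, demo["race"]),
                "ethnicity": _choice(rng, demo["ethnicity"]),
                "region": _choice(rng, demo["region"]),
                "payer": _choice(rng, demo["payer"]),
                "cci": cci,
            }
        )

        # BMI observations around index
        bmi_ps = cfg["bmi"][group]
        for _ in range(int(rng.integers(1, 4))):
            obs_rows.append(
                {
                    "patient_id": pid,
                    "obs_date": (index + timedelta(days=int(rng.integers(-330, 331)))).isoformat(),
                    "bmi": round(
                        float(
                            np.clip(
                                rng.normal(float(bmi_ps["mean"]), float(bmi_ps["sd"])),
                                15.0,
                                60.0,
                            )
                        ),
                        1,
                    ),
                }
            )

        # -- EHR diagnosis records
        def _dx(day: date, code: str, setting: str = "outpatient", primary: bool = True):
            dx_rows.append(
                {
                    "patient_id": pid,
                    "service_date": day.isoformat(),
                    "code": code,
                    "code_system": "icd9" if code[0].isdigit() else "icd10cm",
                    "setting": setting,
                    "primary": int(primary),
                }
            )

        sz_pool = codes["schizophrenia"]
        _dx(index, sz_pool[rng.integers(len(sz_pool))])  # index encounter
        if meets_sz:
            _dx(index + timedelta(days=int(rng.integers(1, 301))),
                sz_pool[rng.integers(len(sz_pool))])
        routine = codes["routine"]
        if pre_activity:
            anchor_day = index - timedelta(days=int(rng.integers(380, 701)))
        else:
            anchor_day = index - timedelta(days=int(rng.integers(30, 331)))
        _dx(anchor_day, routine[rng.integers(len(routine))])

        comorb = {}
        prevs = cfg["comorbidity_prevalences"][group]
        for cond in COMORBIDITIES:
            flag = rng.random() < float(prevs[cond])
            comorb[cond] = flag
            if flag:
                pool = codes["comorbidity"][cond]
                _dx(index - timedelta(days=int(rng.integers(10, 331))),
                    pool[rng.integers(len(pool))])

        if excluded_cond:
            pool = codes["exclusion"][excluded_cond]
            code = pool[rng.integers(len(pool))]
            if excluded_cond in PRIOR_TO_INDEX_CONDITIONS:
                day = index - timedelta(days=int(rng.integers(10, 301)))
            else:
                day = index + timedelta(days=int(rng.integers(-180, 301)))
            _dx(day, code)

        # -- coverage intervals
        if enrolled:
            start = index - timedelta(days=int(rng.integers(0, 181)))
            end = index + timedelta(days=366 + int(rng.integers(10, 181)))
            for benefit in ("medical", "pharmacy"):
                cov_rows.append(
                    {"patient_id": pid, "start": start.isoformat(),
                     "end": end.isoformat(), "benefit": benefit}
                )
        else:
            start = index - timedelta(days=int(rng.integers(0, 181)))
            end = index + timedelta(days=int(rng.integers(30, 301)))
            cov_rows.append(
                {"patient_id": pid, "start": start.isoformat(),
                 "end": end.isoformat(), "benefit": "medical"}
            )
            if rng.random() < 0.7:
                cov_rows.append(
                    {"patient_id": pid, "start": start.isoformat(),
                     "end": end.isoformat(), "benefit": "pharmacy"}
                )

        # -- claims over the 12 months post-index
        util = cfg["utilization"]
        counts = {
            m: int(_nb_draw(rng, float(util[m][group]["mean"]),
                            float(util[m][group]["dispersion"])))
            for m in ("outpatient", "pharmacy", "er", "inpatient")
        }
        psych_pool = codes["psychiatric"]
        szp_pool = codes["sz_primary"]
        cnum = 0

        def _claim(day_offset: int, ctype: str, primary_dx: str,
                   los: int | None = None, sclass: str = "") -> None:
            nonlocal cnum
            claim_rows.append(
                {
                    "claim_id": f"C{pid}_{cnum}",
                    "patient_id": pid,
                    "service_date": (index + timedelta(days=day_offset)).isoformat(),
                    "claim_type": ctype,
                    "primary_dx": primary_dx,
                    "length_of_stay_days": los,
                    "service_class": sclass,
                }
            )
            cnum += 1

        # psychosocial components -> service classes on outpatient claims
        psycho = {c: bool(rng.random() < float(tx["psychosocial"][group][c]))
                  for c in PSYCHOSOCIAL_COMPONENTS}
        active = [c for c in PSYCHOSOCIAL_COMPONENTS if psycho[c]]
        session_classes: list[str] = []
        if active:
            td_ps = tx["therapy_days"][group]
            t_days = 1 + int(_nb_draw(rng, float(td_ps["mean"]) - 1.0,
                                      float(td_ps["dispersion"])))
            n_sess = min(t_days, counts["outpatient"])
            session_classes = list(active[:n_sess])
            if n_sess > len(active):
                extra = rng.integers(len(active), size=n_sess - len(active))
                session_classes += [active[j] for j in extra]
        out_days = rng.integers(0, 365, size=counts["outpatient"])
        for j, off in enumerate(out_days):
            sclass = session_classes[j] if j < len(session_classes) else ""
            _claim(int(off), "outpatient", routine[rng.integers(len(routine))],
                   sclass=sclass)

        rx = {c: bool(rng.random() < float(tx["pharmacy_classes"][group][c]))
              for c in PHARMACY_CLASSES}
        rx_active = [c for c in PHARMACY_CLASSES if rx[c]]
        n_rx = counts["pharmacy"]
        rx_classes = []
        if n_rx:
            rx_classes = list(rx_active[:n_rx])
            if n_rx > len(rx_classes):
                if rx_active:
                    extra = rng.integers(len(rx_active) + 1, size=n_rx - len(rx_classes))
                    rx_classes += [
                        (rx_active + ["other"])[j] for j in extra
                    ]
                else:
                    rx_classes += ["other"] * (n_rx - len(rx_classes))
        for j, off in enumerate(rng.integers(0, 365, size=n_rx)):
            _claim(int(off), "pharmacy", "", sclass=rx_classes[j])

        for off in rng.integers(0, 365, size=counts["er"]):
            if rng.random() < float(relapse["er_psychiatric_rate"]):
                dx_code = psych_pool[rng.integers(len(psych_pool))]
            else:
                dx_code = routine[rng.integers(len(routine))]
            _claim(int(off), "er", dx_code)

        los_ps = cfg["length_of_stay"][group]
        for off in rng.integers(0, 365, size=counts["inpatient"]):
            if rng.random() < float(relapse["inpatient_primary_sz_rate"]):
                dx_code = szp_pool[rng.integers(len(szp_pool))]
            else:
                dx_code = routine[rng.integers(len(routine))]
            los = 1 + int(_nb_draw(rng, float(los_ps["mean"]) - 1.0,
                                   float(los_ps["dispersion"])))
            _claim(int(off), "inpatient", dx_code, los=los)

        # -- clinical notes with planted phrases and decoys
        if include_notes:
            note_events: list[list[tuple]] = [[] for _ in range(n_notes)]
            for d in domains:
                ents, w = entries_by_domain[d]
                entry = ents[rng.choice(len(ents), p=w)]
                note_j = int(rng.integers(n_notes))
                note_events[note_j].append((entry, "clean"))
                gmention_rows.append(
                    {"patient_id": pid, "note_index": note_j,
                     "entry_id": entry.entry_id, "kind": "clean"}
                )
            decoy_draws = rng.random((n_notes, len(conf_kinds)))
            for j in range(n_notes):
                for kk, kind in enumerate(conf_kinds):
                    if decoy_draws[j, kk] < conf_rates[kind]:
                        entry = all_entries[rng.integers(len(all_entries))]
                        note_events[j].append((entry, kind))
                        gmention_rows.append(
                            {"patient_id": pid, "note_index": j,
                             "entry_id": entry.entry_id, "kind": kind}
                        )
            note_offsets = rng.integers(-300, 361, size=n_notes)
            for j in range(n_notes):
                notes.append(
                    ClinicalNote(
                        note_id=f"N{pid}_{j}",
                        patient_id=pid,
                        note_date=(index + timedelta(days=int(note_offsets[j]))).isoformat(),
                        raw_text=render_note(note_events[j], rng, html_rate),
                    )
                )

        gold_rows.append(
            {
                "patient_id": pid,
                "impaired": int(impaired),
                "domains": ";".join(domains),
                "index_date": index.isoformat(),
                "n_notes": n_notes,
                "draw_under_18": int(under_18),
                "draw_meets_sz_encounters": int(meets_sz),
                "draw_pre_index_activity": int(pre_activity),
                "excluded_condition": excluded_cond,
                "enrolled": int(enrolled),
                "eligible_ehr": int(eligible_ehr),
                "eligible_linked": int(eligible_linked),
                **{f"comorb_{c}": int(comorb[c]) for c in COMORBIDITIES},
                **{f"psycho_{c}": int(psycho[c]) for c in PSYCHOSOCIAL_COMPONENTS},
                **{f"rx_{c}": int(rx[c]) for c in PHARMACY_CLASSES},
            }
        )

    def _frame(rows, columns):
        return pd.DataFrame(rows, columns=columns)

    return SyntheticDataset(
        patients=_frame(patients_rows, [
            "patient_id", "birth_year", "age_band", "gender", "race",
            "ethnicity", "region", "payer", "cci"]),
        diagnoses=_frame(dx_rows, [
            "patient_id", "service_date", "code", "code_system", "setting",
            "primary"]),
        coverage=_frame(cov_rows, ["patient_id", "start", "end", "benefit"]),
        claims=_frame(claim_rows, [
            "claim_id", "patient_id", "service_date", "claim_type",
            "primary_dx", "length_of_stay_days", "service_class"]),
        observations=_frame(obs_rows, ["patient_id", "obs_date", "bmi"]),
        gold=_frame(gold_rows, list(gold_rows[0].keys()) if gold_rows else [
            "patient_id", "impaired", "domains", "index_date", "n_notes",
            "draw_under_18", "draw_meets_sz_encounters",
            "draw_pre_index_activity", "excluded_condition", "enrolled",
            "eligible_ehr", "eligible_linked"]),
        gold_mentions=_frame(gmention_rows,
                             ["patient_id", "note_index", "entry_id", "kind"]),
        notes=notes,
        config=cfg.to_dict(),
        seed=seed,
    )


# -- persistence --------------------------------------------------------------

_STR_COLUMNS = {
    "patients": ["patient_id", "age_band", "gender", "race", "ethnicity",
                 "region", "payer"],
    "diagnoses": ["patient_id", "service_date", "code", "code_system", "setting"],
    "coverage": ["patient_id", "start", "end", "benefit"],
    "claims": ["claim_id", "patient_id", "service_date", "claim_type",
               "primary_dx", "service_class"],
    "observations": ["patient_id", "obs_date"],
    "gold": ["patient_id", "domains", "index_date", "excluded_condition"],
    "gold_mentions": ["patient_id", "entry_id", "kind"],
}


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict:
    """Write CSV tables + JSONL notes + a manifest; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(ds, name).to_csv(out / f"{name}.csv", index=False)
    with open(out / "notes.jsonl", "w") as fh:
        for n in ds.notes:
            fh.write(json.dumps({
                "note_id": n.note_id, "patient_id": n.patient_id,
                "note_date": n.note_date, "text": n.raw_text}) + "\n")
    manifest = {
        "seed": ds.seed,
        "n_patients": int(len(ds.patients)),
        "config": ds.config,
        "files": [f"{t}.csv" for t in _TABLES] + ["notes.jsonl"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Load a dataset written by :func:`write_dataset` (round-trips)."""
    src = Path(in_dir)
    if not src.exists():
        raise FileNotFoundError(f"dataset directory not found: {src}")
    manifest = json.loads((src / "manifest.json").read_text())
    frames = {}
    for name in _TABLES:
        path = src / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing dataset table: {path}")
        df = pd.read_csv(
            path,
            dtype={c: str for c in _STR_COLUMNS[name]},
            keep_default_na=False,
            na_values=[""],
        )
        for c in _STR_COLUMNS[name]:
            if c in df.columns:
                df[c] = df[c].fillna("")
        frames[name] = df
    notes = []
    with open(src / "notes.jsonl") as fh:
        for line in fh:
            rec = json.loads(line)
            notes.append(ClinicalNote(rec["note_id"], rec["patient_id"],
                                      rec["note_date"], rec["text"]))
    return SyntheticDataset(
        **frames, notes=notes, config=manifest["config"],
        seed=int(manifest["seed"]),
    )
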