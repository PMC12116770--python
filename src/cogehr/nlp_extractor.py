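"""Clinical-note pipeline: markup stripping, sentence segmentation, lexicon
matching, sentence-level context exclusion, and patient-level aggregation.

The pipeline turns free-text notes into per-patient documented-impairment
profiles.  A phrase match only counts as documentation when its sentence shows
no excluding context: negation ("denies poor memory"), a question ("any poor
memory?"), a care goal ("goal: improve concentration"), or a family-history
mention ("mother has poor memory").  Exclusion scope is the whole sentence —
a trigger anywhere in the sentence disqualifies every match inside it — and
when several rules apply the recorded label follows the fixed precedence
negation > question > goal > family_history.

All offsets are 0-based half-open; dates are ISO-8601 strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from html.parser import HTMLParser
from typing import Iterable, Sequence

import pandas as pd

from .lexicon import CompiledLexicon, DOMAINS

__all__ = [
    "ClinicalNote",
    "Sentence",
    "Mention",
    "PatientImpairmentProfile",
    "ExclusionRules",
    "ExtractionResult",
    "strip_markup",
    "segment_sentences",
    "match_sentence",
    "classify_exclusion",
    "extract_patient_profiles",
    "corpus_domain_report",
    "percentage",
]

EXCLUSION_LABELS = ("none", "negation", "question", "goal", "family_history")


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    patient_id: str
    note_date: str  # ISO-8601
    raw_text: str


@dataclass(frozen=True)
class Sentence:
    note_id: str
    sentence_index: int
    text: str
    start: int  # offsets into the stripped note text, half-open
    end: int


@dataclass(frozen=True)
class Mention:
    mention_id: str
    note_id: str
    sentence_index: int
    entry_id: str
    match_start: int  # offsets within the sentence, half-open
    match_end: int
    exclusion: str = "none"


@dataclass(frozen=True)
class PatientImpairmentProfile:
    patient_id: str
    domain_flags: dict[str, bool]
    category_flags: dict[tuple[str, str], bool]
    any_impairment: bool
    retained_mention_count: int
    note_count: int


# -- markup stripping -------------------------------------------------------

_BLOCK_TAGS = frozenset(
    "p div br li ul ol tr td th table h1 h2 h3 h4 h5 h6 section article header footer blockquote pre".split()
)


class _TextExtractor(HTMLParser):
    """Lenient tag stripper: visible text kept in order, entities decoded
    (``convert_charrefs``), block-level tags become newlines and inline tags a
    space so adjacent words never fuse."""

    def __init__(self) -> None:
        super().__init__(convert_charrefs=True)
        self.parts: list[str] = []
        self._skip_depth = 0  # inside <script>/<style>

    def handle_starttag(self, tag, attrs):
        if tag in ("script", "style"):
            self._skip_depth += 1
        self.parts.append("\n" if tag in _BLOCK_TAGS else " ")

    def handle_endtag(self, tag):
        if tag in ("script", "style") and self._skip_depth:
            self._skip_depth -= 1
        self.parts.append("\n" if tag in _BLOCK_TAGS else " ")

    def handle_startendtag(self, tag, attrs):
        self.parts.append("\n" if tag in _BLOCK_TAGS else " ")

    def handle_data(self, data):
        if not self._skip_depth:
            self.parts.append(data)


def strip_markup(raw_text: str) -> str:
    """Remove HTML markup, returning the visible text content.

    Tag-free input passes through unchanged.  Malformed markup is handled
    leniently (best-effort parse, never raises).
    """
    if "<" not in raw_text and "&" not in raw_text:
        return raw_text
    parser = _TextExtractor()
    try:
        parser.feed(raw_text)
        parser.close()
    except Exception:  # pragma: no cover - html.parser is already lenient
        return raw_text
    text = "".join(parser.parts)
    # collapse runs of spaces/newlines introduced by tags, keep single newlines
    text = re.sub(r"[ \t]*\n[ \t\n]*", "\n", text)
    text = re.sub(r"[ \t]{2,}", " ", text)
    return text.strip()


# -- sentence segmentation --------------------------------------------------

#: Word tokens whose trailing period does not end a sentence.
ABBREVIATIONS = frozenset(
    ["dr", "mr", "mrs", "ms", "st", "jr", "sr", "vs", "etc", "e.g", "i.e", "approx"]
)

_TOKEN_BEFORE = re.compile(r"[\w.]+$")


def _is_terminal(text: str, i: int) -> bool:
    """Is the punctuation mark at ``i`` a sentence boundary?"""
    if i + 1 < len(text) and not text[i + 1].isspace():
        return False  # mid-token: decimals ("30.1"), "?!" runs, file names
    if text[i] == ".":
        m = _TOKEN_BEFORE.search(text, 0, i)
        if m and m.group().lower() in ABBREVIATIONS:
            return False
    return True


def segment_sentences(text: str, note_id: str = "") -> list[Sentence]:
    """Split markup-free text into sentences with character-offset provenance.

    Terminal ``.``/``!``/``?`` end a sentence unless part of a decimal or a
    documented abbreviation; newlines (e.g. list items) are always boundaries.
    The returned spans are whitespace-trimmed, non-overlapping, ordered, and
    together cover every non-whitespace character of ``text``.
    """
    cuts: list[int] = []
    for i, ch in enumerate(text):
        if ch == "\n":
            cuts.append(i)
        elif ch in ".!?" and _is_terminal(text, i):
            cuts.append(i + 1)
    cuts.append(len(text))
    sentences: list[Sentence] = []
    prev = 0
    for cut in cuts:
        seg = text[prev:cut]
        lead = len(seg) - len(seg.lstrip())
        start, end = prev + lead, prev + len(seg.rstrip())
        if end > start:
            sentences.append(
                Sentence(note_id, len(sentences), text[start:end], start, end)
            )
        prev = cut
    return sentences


# -- lexicon matching -------------------------------------------------------

def match_sentence(sentence: Sentence, cl: CompiledLexicon) -> list[Mention]:
    """All raw lexicon matches in one sentence (exclusion not yet classified).

    One mention per (entry, span); overlapping matches from different entries
    are all reported, while within a single entry spans are the leftmost-
    longest non-overlapping set.  Entries with sentence qualifiers only match
    when a qualifier also occurs in the sentence.
    """
    text = sentence.text
    if not cl.prefilter.search(text):
        return []
    mentions: list[Mention] = []
    for ce in cl.entries:
        if ce.qualifier is not None and not ce.qualifier.search(text):
            continue
        for m in ce.pattern.finditer(text):
            mentions.append(
                Mention(
                    mention_id=(
                        f"{sentence.note_id}:{sentence.sentence_index}"
                        f":{ce.entry_id}:{m.start()}"
                    ),
                    note_id=sentence.note_id,
                    sentence_index=sentence.sentence_index,
                    entry_id=ce.entry_id,
                    match_start=m.start(),
                    match_end=m.end(),
                )
            )
    mentions.sort(key=lambda x: (x.match_start, x.match_end, x.entry_id))
    return mentions


# -- context exclusion ------------------------------------------------------

def _trigger_pattern(triggers: Sequence[str]) -> re.Pattern:
    parts = []
    for t in sorted(triggers, key=len, reverse=True):
        body = r"\s+".join(re.escape(w) for w in t.split())
        if t and t[0].isalnum():
            body = r"\b" + body
        if t and t[-1].isalnum():
            body = body + r"\b"
        parts.append(body)
    return re.compile("|".join(parts), re.IGNORECASE)


@dataclass(frozen=True)
class ExclusionRules:
    """Configurable sentence-level exclusion triggers with bundled defaults.

    The four criteria (negation, question, goal, family history) are fixed;
    their trigger vocabularies are not part of the source method description
    and are therefore explicit and overridable here.
    """

    negation_triggers: tuple[str, ...] = (
        "no", "not", "denies", "denied", "without", "negative for",
        "absence of", "intact",
    )
    goal_triggers: tuple[str, ...] = (
        "goal", "goals", "plan to", "will work on", "objective:",
    )
    family_history_triggers: tuple[str, ...] = (
        "mother", "father", "brother", "sister", "family history", "fh of",
        "parent",
    )
    question_terminal_mark: str = "?"

    @property
    def negation_re(self) -> re.Pattern:
        return _trigger_pattern(self.negation_triggers)

    @property
    def goal_re(self) -> re.Pattern:
        return _trigger_pattern(self.goal_triggers)

    @property
    def family_re(self) -> re.Pattern:
        return _trigger_pattern(self.family_history_triggers)


DEFAULT_RULES = ExclusionRules()


def classify_exclusion(
    sentence: Sentence, mention: Mention, rules: ExclusionRules = DEFAULT_RULES
) -> str:
    """Exclusion label for a mention, from its containing sentence.

    First matching rule in the fixed precedence order
    negation > question > goal > family_history; "none" if no rule fires.
    """
    if not (0 <= mention.match_start <= mention.match_end <= len(sentence.text)):
        raise ValueError(
            f"mention {mention.mention_id!r} span outside sentence"
        )
    text = sentence.text
    if rules.negation_re.search(text):
        return "negation"
    if text.rstrip().endswith(rules.question_terminal_mark):
        return "question"
    if rules.goal_re.search(text):
        return "goal"
    if rules.family_re.search(text):
        return "family_history"
    return "none"


# -- patient-level aggregation ----------------------------------------------

@dataclass(frozen=True)
class ExtractionResult:
    profiles: tuple[PatientImpairmentProfile, ...]
    mentions: tuple[Mention, ...]  # full audit log incl. excluded mentions
    note_patient: dict[str, str] = field(repr=False, default_factory=dict)

    def profile_for(self, patient_id: str) -> PatientImpairmentProfile:
        for p in self.profiles:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def mention_log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "patient_id": self.note_patient.get(m.note_id, ""),
                    "note_id": m.note_id,
                    "sentence_index": m.sentence_index,
                    "entry_id": m.entry_id,
                    "match_start": m.match_start,
                    "match_end": m.match_end,
                    "exclusion": m.exclusion,
                }
                for m in self.mentions
            ],
            columns=[
                "patient_id", "note_id", "sentence_index", "entry_id",
                "match_start", "match_end", "exclusion",
            ],
        )

    def profiles_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            row = {
                "patient_id": p.patient_id,
                "any_impairment": p.any_impairment,
                "retained_mention_count": p.retained_mention_count,
                "note_count": p.note_count,
            }
            for d in DOMAINS:
                row[d] = p.domain_flags[d]
            rows.append(row)
        return pd.DataFrame(rows)


def extract_patient_profiles(
    notes: Iterable[ClinicalNote],
    cl: CompiledLexicon,
    rules: ExclusionRules = DEFAULT_RULES,
    exclusion_enabled: bool = True,
    patient_ids: Sequence[str] | None = None,
) -> ExtractionResult:
    """Run the full pipeline over a note corpus.

    Deterministic for fixed inputs.  Profile flags derive only from mentions
    with exclusion "none"; excluded mentions are kept in the audit log with
    their labels.  ``patient_ids`` may list additional patients (e.g. with
    zero notes) who then receive all-false profiles.
    """
    by_patient: dict[str, list[ClinicalNote]] = {}
    if patient_ids is not None:
        for pid in patient_ids:
            by_patient[str(pid)] = []
    for note in notes:
        by_patient.setdefault(note.patient_id, []).append(note)

    if cl.source is None:
        raise ValueError("compiled lexicon lacks its source lexicon")
    categories = [(e.domain, e.category, e.entry_id) for e in cl.source.entries]
    entry_domain = cl.domain_of
    entry_category = {e.entry_id: e.category for e in cl.source.entries}

    all_mentions: list[Mention] = []
    note_patient: dict[str, str] = {}
    profiles: list[PatientImpairmentProfile] = []
    for pid, pnotes in by_patient.items():
        retained = 0
        domain_flags = {d: False for d in DOMAINS}
        category_flags = {(d, c): False for d, c, _ in categories}
        for note in pnotes:
            note_patient[note.note_id] = pid
            text = strip_markup(note.raw_text)
            for sent in segment_sentences(text, note.note_id):
                for m in match_sentence(sent, cl):
                    label = (
                        classify_exclusion(sent, m, rules)
                        if exclusion_enabled
                        else "none"
                    )
                    m = replace(m, exclusion=label)
                    all_mentions.append(m)
                    if label == "none":
                        retained += 1
                        d = entry_domain[m.entry_id]
                        domain_flags[d] = True
                        category_flags[(d, entry_category[m.entry_id])] = True
        profiles.append(
            PatientImpairmentProfile(
                patient_id=pid,
                domain_flags=domain_flags,
                category_flags=category_flags,
                any_impairment=any(domain_flags.values()),
                retained_mention_count=retained,
                note_count=len(pnotes),
            )
        )
    return ExtractionResult(
        profiles=tuple(profiles),
        mentions=tuple(all_mentions),
        note_patient=note_patient,
    )


# -- corpus-level reporting -------------------------------------------------

def percentage(numer: float, denom: float, ndigits: int = 1) -> float | None:
    """``100 * numer / denom`` rounded; None for a zero denominator."""
    if denom == 0:
        return None
    return round(100.0 * numer / denom, ndigits)


def corpus_domain_report(
    profiles: Sequence[PatientImpairmentProfile],
) -> pd.DataFrame:
    """Counts and percentages per domain and category among impaired patients.

    Domain and category rows use the number of patients with any documented
    impairment as denominator; the overall-prevalence row uses all patients.
    Zero denominators yield a null percentage rather than a division.
    """
    n_total = len(profiles)
    impaired = [p for p in profiles if p.any_impairment]
    n_imp = len(impaired)
    rows = [
        {
            "level": "overall",
            "domain": "",
            "category": "any_impairment",
            "count": n_imp,
            "denominator": n_total,
            "percent": percentage(n_imp, n_total, 4),
        }
    ]
    cat_keys: list[tuple[str, str]] = []
    if profiles:
        cat_keys = list(profiles[0].category_flags.keys())
    for d in DOMAINS:
        count = sum(p.domain_flags.get(d, False) for p in impaired)
        rows.append(
            {
                "level": "domain",
                "domain": d,
                "category": "",
                "count": count,
                "denominator": n_imp,
                "percent": percentage(count, n_imp, 4),
            }
        )
        for dd, cc in cat_keys:
            if dd != d:
                continue
            ccount = sum(p.category_flags.get((dd, cc), False) for p in impaired)
            rows.append(
                {
                    "level": "category",
                    "domain": d,
                    "category": cc,
                    "count": ccount,
                    "denominator": n_imp,
                    "percent": percentage(ccount, n_imp, 4),
                }
            )
    return pd.DataFrame(rows)


def domain_percent(report: pd.DataFrame, domain: str) -> float:
    """Convenience accessor: the percent for one domain row of a report."""
    row = report[(report["level"] == "domain") & (report["domain"] == domain)]
    if row.empty:
        raise KeyError(domain)
    return float(row["percent"].iloc[0])
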