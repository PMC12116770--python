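"""Five-domain cognitive-impairment lexicon: loading, validation, compilation.

The lexicon is a hierarchy domain -> category -> pattern list.  Domains are the
five MCCB-derived areas retained for clinical-note screening in schizophrenia
(attention/vigilance, reasoning/problem-solving, speed of processing, verbal
learning & memory, working memory); categories are phrase families such as
"poor concentration"; patterns are word-level regular expressions.

Matching semantics (applied at compile time):

* case-insensitive by default (``Lexicon.case_sensitive`` switches it off),
* every pattern alternative is anchored with ``\\b`` word boundaries at both
  ends, so "attention" does not fire inside "inattention",
* literal spaces inside a bundled pattern mean "one or more whitespace
  characters" only if the pattern says so (the bundled file uses ``\\s+``
  explicitly).

Entries may carry ``sentence_qualifiers``: extra patterns, one of which must
appear somewhere in the same sentence for a match to count.  The bundled
"insight and judgment" entry uses this to avoid flagging the bare
mental-status-exam heading; :func:`compile_lexicon` can disable enforcement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "DOMAINS",
    "LexiconEntry",
    "Lexicon",
    "CompiledLexicon",
    "CompiledEntry",
    "LexiconError",
    "load_lexicon",
    "write_lexicon",
    "default_lexicon",
    "compile_lexicon",
    "default_lexicon_path",
]

#: The five retained cognitive-impairment domains.
DOMAINS = (
    "attention_vigilance",
    "reasoning_problem_solving",
    "speed_of_processing",
    "verbal_learning_memory",
    "working_memory",
)


class LexiconError(ValueError):
    """Raised for malformed or invalid lexicon files/objects."""


@dataclass(frozen=True)
class LexiconEntry:
    """One phrase category and the regex alternatives that detect it.

    ``canonical`` is a plain-text surface form of the category used by the
    synthetic-note generator when planting detectable phrases; it must match
    the entry's own patterns.
    """

    entry_id: str
    domain: str
    category: str
    patterns: tuple[str, ...]
    canonical: str = ""
    sentence_qualifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise LexiconError(
                f"entry {self.entry_id!r}: unknown domain {self.domain!r}; "
                f"expected one of {', '.join(DOMAINS)}"
            )
        if not self.patterns:
            raise LexiconError(f"entry {self.entry_id!r}: empty pattern list")
        for pat in self.patterns:
            _try_compile(pat, self.entry_id)
        for pat in self.sentence_qualifiers:
            _try_compile(pat, self.entry_id)


def _try_compile(pattern: str, entry_id: str) -> None:
    if not pattern:
        raise LexiconError(f"entry {entry_id!r}: empty pattern")
    try:
        re.compile(pattern)
    except re.error as exc:
        raise LexiconError(
            f"entry {entry_id!r}: pattern {pattern!r} does not compile: {exc}"
        ) from exc


@dataclass(frozen=True)
class Lexicon:
    entries: tuple[LexiconEntry, ...]
    version: str = "0"
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        seen_keys: set[tuple[str, str]] = set()
        for e in self.entries:
            if e.entry_id in seen_ids:
                raise LexiconError(f"duplicate entry_id {e.entry_id!r}")
            seen_ids.add(e.entry_id)
            key = (e.domain, e.category)
            if key in seen_keys:
                raise LexiconError(f"duplicate (domain, category) {key!r}")
            seen_keys.add(key)
        present = {e.domain for e in self.entries}
        missing = [d for d in DOMAINS if d not in present]
        if missing:
            raise LexiconError(f"no entries for domain(s): {', '.join(missing)}")

    @property
    def domains(self) -> tuple[str, ...]:
        return DOMAINS

    def entry(self, entry_id: str) -> LexiconEntry:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e
        raise KeyError(entry_id)

    def by_domain(self, domain: str) -> tuple[LexiconEntry, ...]:
        return tuple(e for e in self.entries if e.domain == domain)


@dataclass(frozen=True)
class CompiledEntry:
    entry_id: str
    domain: str
    category: str
    pattern: re.Pattern
    qualifier: re.Pattern | None


@dataclass(frozen=True)
class CompiledLexicon:
    """Compiled matchers keyed by entry_id plus a combined prefilter pattern."""

    entries: tuple[CompiledEntry, ...]
    domain_of: dict[str, str] = field(repr=False, default_factory=dict)
    prefilter: re.Pattern = field(repr=False, default=re.compile("$^"))
    source: Lexicon | None = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.entries)


def _anchor(alternatives: Iterable[str]) -> str:
    # Longer alternatives first so alternation prefers the longest match at a
    # given start position (leftmost-longest within an entry).
    alts = sorted(alternatives, key=len, reverse=True)
    return "|".join(rf"\b(?:{a})\b" for a in alts)


def compile_lexicon(lex: Lexicon, enforce_qualifiers: bool = True) -> CompiledLexicon:
    """Compile every entry into a word-boundary-anchored regex.

    Deterministic for a fixed lexicon and idempotent: compiling twice yields
    equivalent matchers.  ``enforce_qualifiers=False`` drops the
    sentence-qualifier requirement (broad matching of exam headings).
    """
    flags = 0 if lex.case_sensitive else re.IGNORECASE
    compiled = []
    for e in lex.entries:
        try:
            pat = re.compile(_anchor(e.patterns), flags)
        except re.error as exc:  # pragma: no cover - entries pre-validated
            raise LexiconError(f"entry {e.entry_id!r} failed to compile: {exc}") from exc
        qual = None
        if enforce_qualifiers and e.sentence_qualifiers:
            qual = re.compile(_anchor(e.sentence_qualifiers), flags)
        compiled.append(CompiledEntry(e.entry_id, e.domain, e.category, pat, qual))
    prefilter = re.compile(
        "|".join(rf"(?:{a})" for e in lex.entries for a in (_anchor(e.patterns),)),
        flags,
    )
    return CompiledLexicon(
        entries=tuple(compiled),
        domain_of={e.entry_id: e.domain for e in lex.entries},
        prefilter=prefilter,
        source=lex,
    )


# -- serialization ----------------------------------------------------------

def load_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a lexicon from its YAML config format.

    The format is flat and human-editable: a top-level ``version``,
    ``case_sensitive`` flag and an ``entries`` list, each entry a mapping with
    ``id``, ``domain``, ``category``, ``patterns`` and optionally
    ``canonical`` / ``sentence_qualifiers``.  Entry order is preserved.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise LexiconError(f"cannot parse {path}{line}: {exc}") from exc
    if not isinstance(raw, dict) or "entries" not in raw:
        raise LexiconError(f"{path}: expected a mapping with an 'entries' list")
    entries = []
    for i, rec in enumerate(raw["entries"]):
        try:
            entries.append(
                LexiconEntry(
                    entry_id=str(rec["id"]),
                    domain=str(rec["domain"]),
                    category=str(rec["category"]),
                    patterns=tuple(rec["patterns"]),
                    canonical=str(rec.get("canonical", "")),
                    sentence_qualifiers=tuple(rec.get("sentence_qualifiers", ())),
                )
            )
        except KeyError as exc:
            raise LexiconError(f"{path}: entry #{i + 1} missing field {exc}") from exc
    return Lexicon(
        entries=tuple(entries),
        version=str(raw.get("version", "0")),
        case_sensitive=bool(raw.get("case_sensitive", False)),
    )


def write_lexicon(lex: Lexicon, path: str | Path) -> None:
    """Write a lexicon back to the YAML config format (round-trips)."""
    doc = {
        "version": lex.version,
        "case_sensitive": lex.case_sensitive,
        "entries": [
            {
                "id": e.entry_id,
                "domain": e.domain,
                "category": e.category,
                "patterns": list(e.patterns),
                **({"canonical": e.canonical} if e.canonical else {}),
                **(
                    {"sentence_qualifiers": list(e.sentence_qualifiers)}
                    if e.sentence_qualifiers
                    else {}
                ),
            }
            for e in lex.entries
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))


def default_lexicon_path() -> Path:
    return Path(__file__).parent / "data" / "lexicon_default.yaml"


def default_lexicon() -> Lexicon:
    """The bundled five-domain, 30-category lexicon."""
    return load_lexicon(default_lexicon_path())
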