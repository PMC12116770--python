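"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written with plain loops over words — no
compiled patterns — and stays independent of the library code paths it
checks.  The naive matcher handles lexicons whose pattern alternatives are
literal phrases (words joined by ``\\s+``), which is what the oracle-test
lexicons use.
"""

from __future__ import annotations

import re

WORD = re.compile(r"[a-z0-9']+")


def words_of(text: str) -> list[str]:
    return WORD.findall(text.lower())


def phrase_words(pattern: str) -> list[str]:
    """Literal pattern alternative -> its word list ('poor\\s+memory' ->
    ['poor', 'memory'])."""
    return [w for w in re.split(r"\\s\+|\s+", pattern.lower()) if w]


def naive_phrase_positions(sentence_words: list[str], phrase: list[str]) -> list[int]:
    hits = []
    for i in range(len(sentence_words) - len(phrase) + 1):
        if sentence_words[i:i + len(phrase)] == phrase:
            hits.append(i)
    return hits


def naive_entry_matches(sentence_words: list[str], entry) -> list[tuple[int, int]]:
    """Leftmost-longest non-overlapping (start, length) word spans for one
    entry across all its alternatives."""
    candidates = []
    for pat in entry.patterns:
        ph = phrase_words(pat)
        for pos in naive_phrase_positions(sentence_words, ph):
            candidates.append((pos, len(ph)))
    candidates.sort(key=lambda c: (c[0], -c[1]))
    chosen: list[tuple[int, int]] = []
    for pos, length in candidates:
        if all(pos >= p + l or pos + length <= p for p, l in chosen):
            chosen.append((pos, length))
    return chosen


def naive_excluded(sentence_text: str, rules) -> str:
    """Sentence-level exclusion label, re-derived with substring word scans."""
    sw = words_of(sentence_text)

    def has(trigger: str) -> bool:
        tw = [w for w in words_of(trigger)]
        return bool(naive_phrase_positions(sw, tw))

    if any(has(t) for t in rules.negation_triggers):
        return "negation"
    if sentence_text.rstrip().endswith("?"):
        return "question"
    if any(has(t) for t in rules.goal_triggers):
        return "goal"
    if any(has(t) for t in rules.family_history_triggers):
        return "family_history"
    return "none"


def naive_retained_mentions(notes, lex, rules, strip, segment):
    """Set of (note_id, sentence_index, entry_id, word_start) retained after
    exclusion, computed by loops only.  Reuses the library's markup stripping
    and segmentation (checked by their own independent oracles)."""
    out = set()
    for note in notes:
        text = strip(note.raw_text)
        for si, sent in enumerate(segment(text)):
            sw = words_of(sent.text)
            label = naive_excluded(sent.text, rules)
            if label != "none":
                continue
            for entry in lex.entries:
                if entry.sentence_qualifiers:
                    ok = any(
                        naive_phrase_positions(sw, phrase_words(q))
                        for q in entry.sentence_qualifiers
                    )
                    if not ok:
                        continue
                for pos, _ in naive_entry_matches(sw, entry):
                    out.add((note.note_id, si, entry.entry_id, pos))
    return out
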