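"""Statin-term dictionary matching, sentence segmentation, and assembly of the
per-patient statin-mention document.

The classifier input unit is not the raw note but the *statin-mention
document*: the concatenation, in chronological order, of every note sentence
inside the analysis window that contains at least one accepted statin term.
Matching is dictionary-based and case-insensitive, with an exclusion list for
tokens such as "nystatin" that contain a statin term as a substring without
being statins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

#: days of notes after the index diagnosis that enter the NLP dataset
NOTE_WINDOW_DAYS = 30


@dataclass(frozen=True)
class StatinDictionary:
    """A set of lowercase statin terms plus trap exclusions.

    ``terms`` are matched as case-insensitive substrings.  A match whose
    containing maximal alphabetic token is in ``trap_exclusions`` is rejected
    (e.g. the "statin" inside "nystatin").
    """

    terms: frozenset[str]
    trap_exclusions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("statin dictionary must contain at least one term")
        overlap = self.terms & self.trap_exclusions
        if overlap:
            raise ValueError(f"terms and exclusions overlap: {sorted(overlap)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "StatinDictionary":
        """Read a dictionary file: one term per line, ``!``-prefixed lines are
        exclusions, ``#`` lines are comments."""
        terms: set[str] = set()
        exclusions: set[str] = set()
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip().lower()
            if not line or line.startswith("#"):
                continue
            if line.startswith("!"):
                exclusions.add(line[1:].strip())
            else:
                terms.add(line)
        return cls(frozenset(terms), frozenset(exclusions))

    def to_file(self, path: str | Path) -> None:
        lines = sorted(self.terms) + [f"!{t}" for t in sorted(self.trap_exclusions)]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def default_dictionary() -> StatinDictionary:
    """The shipped statin dictionary: the drug class generics, US brand names,
    the bare token "statin", and known substring traps."""
    ref = resources.files("statinscope.data").joinpath("statin_terms.txt")
    with resources.as_file(ref) as path:
        return StatinDictionary.from_file(path)


_ALPHA = re.compile(r"[a-z]")


def match_statin_terms(text: str, dictionary: StatinDictionary) -> list[tuple[int, int]]:
    """Find accepted statin-term spans in ``text``.

    Returns 0-based half-open character spans, non-overlapping with
    longest-leftmost priority.  A candidate match is rejected when the maximal
    alphabetic token containing it is a trap exclusion.
    """
    low = text.lower()
    candidates: list[tuple[int, int]] = []
    for term in dictionary.terms:
        start = 0
        while True:
            i = low.find(term, start)
            if i < 0:
                break
            j = i + len(term)
            # expand to the maximal alphabetic token around the match
            a, b = i, j
            while a > 0 and _ALPHA.match(low[a - 1]):
                a -= 1
            while b < len(low) and _ALPHA.match(low[b]):
                b += 1
            if low[a:b] not in dictionary.trap_exclusions:
                candidates.append((i, j))
            start = i + 1
    candidates.sort(key=lambda s: (s[0], s[0] - s[1]))
    accepted: list[tuple[int, int]] = []
    last_end = -1
    for i, j in candidates:
        if i >= last_end:
            accepted.append((i, j))
            last_end = j
    return accepted


# Tokens that commonly precede a period without ending a sentence in clinical
# prose. Checked lowercased against the word immediately before the terminator.
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "vs", "st", "jr", "sr",
    "mg", "mcg", "ml", "dl", "tab", "tabs", "cap", "approx", "etc",
    "qd", "bid", "tid", "qid", "qhs", "prn", "po",
    "pt", "hx", "dx", "fx", "sx", "tx",
}

_WORD_BEFORE = re.compile(r"([A-Za-z]+)\.$")


def split_sentences(text: str) -> list[tuple[str, int, int]]:
    """Deterministic rule-based sentence segmentation.

    A boundary is a terminator in ``. ! ?`` followed by whitespace and then a
    capital letter or digit, or a newline followed (after optional whitespace)
    by a capital letter or digit.  Periods after known clinical abbreviations
    do not split; decimals and dotted dates never split because no whitespace
    follows the internal periods.

    Returns ``(sentence_text, start, end)`` with half-open character offsets
    into ``text``; joining the sentences restores the input up to
    inter-sentence whitespace.
    """
    boundaries: list[int] = []  # end offsets (exclusive) of sentences
    n = len(text)
    for m in re.finditer(r"[.!?\n]", text):
        i = m.start()
        ch = text[i]
        if ch == "\n":
            j = i + 1
            while j < n and text[j] in " \t\n":
                j += 1
            if j < n and (text[j].isupper() or text[j].isdigit()):
                boundaries.append(i)
            continue
        if i + 1 >= n or text[i + 1] not in " \t\n":
            continue
        j = i + 1
        while j < n and text[j] in " \t\n":
            j += 1
        if j >= n or not (text[j].isupper() or text[j].isdigit()):
            continue
        if ch == ".":
            w = _WORD_BEFORE.search(text[: i + 1])
            if w and w.group(1).lower() in _ABBREVIATIONS:
                continue
        boundaries.append(i + 1)
    sentences: list[tuple[str, int, int]] = []
    start = 0
    for end in boundaries:
        if end > start:
            seg = text[start:end]
            lead = len(seg) - len(seg.lstrip())
            if seg.strip():
                sentences.append((seg.strip(), start + lead, start + lead + len(seg.strip())))
        start = end
    tail = text[start:]
    if tail.strip():
        lead = len(tail) - len(tail.lstrip())
        sentences.append((tail.strip(), start + lead, start + lead + len(tail.strip())))
    return sentences


@dataclass(frozen=True)
class MentionSource:
    note_id: str
    sentence_index: int
    span: tuple[int, int]  # character span of the sentence in the source note


@dataclass(frozen=True)
class StatinMentionDocument:
    """Concatenated statin-mention sentences for one patient, with provenance."""

    patient_id: str
    text: str
    source: tuple[MentionSource, ...] = field(default_factory=tuple)


def build_mention_document(
    notes: Sequence,  # ClinicalNote-like: note_id, patient_id, date, text
    index_date: date,
    dictionary: StatinDictionary,
    window_days: int = NOTE_WINDOW_DAYS,
) -> StatinMentionDocument | None:
    """Assemble the statin-mention document from one patient's notes.

    Only notes dated in the closed window ``[index_date, index_date +
    window_days]`` contribute.  Sentences with at least one accepted statin
    match are kept, ordered by (note date, note id, sentence index) and joined
    with single spaces.  Returns ``None`` when no sentence matches.
    """
    pids = {n.patient_id for n in notes}
    if len(pids) > 1:
        raise ValueError(f"notes span multiple patients: {sorted(pids)}")
    lo, hi = index_date, index_date + timedelta(days=window_days)
    kept: list[tuple[date, str, int, str, tuple[int, int]]] = []
    for note in sorted(notes, key=lambda n: (n.date, n.note_id)):
        if not (lo <= note.date <= hi):
            continue
        for k, (sent, s, e) in enumerate(split_sentences(note.text)):
            if match_statin_terms(sent, dictionary):
                kept.append((note.date, note.note_id, k, sent, (s, e)))
    if not kept:
        return None
    return StatinMentionDocument(
        patient_id=next(iter(pids)) if pids else "",
        text=" ".join(k[3] for k in kept),
        source=tuple(MentionSource(nid, idx, span) for _, nid, idx, _, span in kept),
    )


def has_statin_term(text: str, dictionary: StatinDictionary) -> bool:
    return bool(match_statin_terms(text, dictionary))
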