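"""Dictionary-based clinical concept extraction with contextual modifier
detection, producing the binary concept-presence feature set (Tcon).

The extractor runs on raw note text (digits preserved, unlike the
bag-of-words preprocessing): notes are split into sentences at newlines
and terminal punctuation — GP notes are line-oriented shorthand, so every
line is its own sentence — then tokenized. Lexicon terms (single- or
multi-word) are matched case-insensitively as contiguous token sequences
with the leftmost-longest, non-overlapping convention.

Modifier detection follows the classic ConText design: trigger phrases
carry a category (negated, hypothetical, historical, experiencer_other)
and a direction; a trigger's scope runs from the trigger towards the
sentence boundary in its direction, truncated at the first scope
terminator and at a window of 10 tokens. A mention whose span intersects
a scope receives that trigger's category flag; categories accumulate
independently. A trigger occurrence overlapping a concept mention is
ignored (the concept wins), and so are terminator occurrences overlapping
a mention.

For the Tcon features, a concept counts as present in an observation iff
it has at least one qualifying mention in an in-window note. The default
qualification keeps historical mentions but drops mentions flagged
negated, hypothetical, or experiencer_other; the dropped categories are
configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import SchemaError
from .omop_io import CohortObservation, FeatureDescriptor, FeatureMatrix

SCOPE_WINDOW = 10  # max tokens a trigger reaches in its direction
CATEGORIES = ("negated", "hypothetical", "historical", "experiencer_other")
DEFAULT_DROP_FLAGS = ("negated", "hypothetical", "experiencer_other")

_SENT_SPLIT_RE = re.compile(r"(?<=[.!?;])\s+")
_WORD_RE = re.compile(r"\w+", re.UNICODE)


# ---------------------------------------------------------------------------
# Lexicon and rule tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LexiconEntry:
    term: str
    concept_id: str
    preferred_name: str


@dataclass
class Lexicon:
    """Surface term -> concept table with case-insensitive token lookup."""

    entries: list[LexiconEntry]
    source: str = "bundled-toy-dutch"

    def __post_init__(self) -> None:
        self._by_tokens: dict[tuple[str, ...], LexiconEntry] = {}
        self.max_len = 0
        for e in self.entries:
            toks = tuple(_tokenize(e.term))
            if not toks:
                raise SchemaError(f"lexicon term {e.term!r} has no tokens")
            self._by_tokens[toks] = e
            self.max_len = max(self.max_len, len(toks))

    def lookup(self, tokens: tuple[str, ...]) -> LexiconEntry | None:
        return self._by_tokens.get(tokens)

    def add(self, term: str, concept_id: str, preferred_name: str) -> "Lexicon":
        return Lexicon(
            self.entries + [LexiconEntry(term, concept_id, preferred_name)],
            source=self.source,
        )


@dataclass(frozen=True)
class ContextRule:
    trigger: str
    category: str  # empty for pure terminators
    direction: str  # forward | backward | bidirectional
    terminator: bool = False

    def __post_init__(self) -> None:
        if not self.trigger.strip():
            raise SchemaError("context trigger must be non-empty")
        if self.terminator and self.category:
            raise SchemaError("scope terminators carry no category")
        if not self.terminator and self.category not in CATEGORIES:
            raise SchemaError(f"unknown context category {self.category!r}")

    @property
    def tokens(self) -> tuple[str, ...]:
        return tuple(_tokenize(self.trigger))


def load_lexicon(path: str | Path | None = None) -> Lexicon:
    """Load a 3-column lexicon CSV (term, concept_id, preferred_name);
    defaults to the small bundled Dutch lexicon."""
    if path is None:
        with resources.as_file(
            resources.files("textpred.data") / "lexicon.csv"
        ) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    for col in ("term", "concept_id", "preferred_name"):
        if col not in df.columns:
            raise SchemaError(f"lexicon file is missing column {col!r}")
    entries = [
        LexiconEntry(str(t), str(c), str(n))
        for t, c, n in zip(df["term"], df["concept_id"], df["preferred_name"])
    ]
    return Lexicon(entries)


def load_context_rules(path: str | Path | None = None) -> list[ContextRule]:
    """Load a 4-column trigger CSV (trigger, category, direction,
    terminator); defaults to the bundled Dutch trigger table."""
    if path is None:
        with resources.as_file(
            resources.files("textpred.data") / "context_rules.csv"
        ) as p:
            df = pd.read_csv(p, keep_default_na=False)
    else:
        df = pd.read_csv(path, keep_default_na=False)
    for col in ("trigger", "category", "direction", "terminator"):
        if col not in df.columns:
            raise SchemaError(f"context rule file is missing column {col!r}")
    return [
        ContextRule(
            trigger=str(r.trigger),
            category=str(r.category),
            direction=str(r.direction),
            terminator=str(r.terminator) in ("1", "true", "True"),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Sentence splitting and matching
# ---------------------------------------------------------------------------


def _tokenize(text: str) -> list[str]:
    return [t.lower() for t in _WORD_RE.findall(text)]


def split_sentences(text: str) -> list[str]:
    """Split raw note text into sentences at newlines and after terminal
    punctuation. Digits are preserved (this is not the bag-of-words
    preprocessing)."""
    sentences = []
    for line in re.split(r"[\r\n]+", text):
        line = line.strip()
        if not line:
            continue
        for part in _SENT_SPLIT_RE.split(line):
            part = part.strip()
            if part:
                sentences.append(part)
    return sentences


def sentence_tokens(sentence: str) -> list[str]:
    """Lowercased word tokens of one sentence (digits kept)."""
    return _tokenize(sentence)


@dataclass
class ConceptMention:
    """One matched lexicon span with its contextual modifier flags.

    Token spans are 0-based, half-open, within the sentence's token list.
    """

    concept_id: str
    sentence_index: int
    start: int
    end: int
    negated: bool = False
    hypothetical: bool = False
    historical: bool = False
    experiencer_other: bool = False

    def flag(self, category: str) -> bool:
        return getattr(self, category)

    def set_flag(self, category: str) -> None:
        setattr(self, category, True)


def match_concepts(tokens: list[str], lexicon: Lexicon,
                   sentence_index: int = 0) -> list[ConceptMention]:
    """Leftmost-longest, non-overlapping lexicon matches over one
    tokenized sentence."""
    mentions = []
    i = 0
    n = len(tokens)
    while i < n:
        hit = None
        for length in range(min(lexicon.max_len, n - i), 0, -1):
            entry = lexicon.lookup(tuple(tokens[i:i + length]))
            if entry is not None:
                hit = (entry, length)
                break
        if hit is None:
            i += 1
        else:
            entry, length = hit
            mentions.append(
                ConceptMention(entry.concept_id, sentence_index, i, i + length)
            )
            i += length
    return mentions


def _find_phrase_spans(tokens: list[str], phrase: tuple[str, ...]
                       ) -> list[tuple[int, int]]:
    spans = []
    k = len(phrase)
    for i in range(len(tokens) - k + 1):
        if tuple(tokens[i:i + k]) == phrase:
            spans.append((i, i + k))
    return spans


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def apply_context(tokens: list[str], mentions: list[ConceptMention],
                  rules: list[ContextRule]) -> list[ConceptMention]:
    """Set modifier flags on mentions according to trigger scopes.

    Mutates and returns ``mentions``. Trigger or terminator occurrences
    overlapping a concept span are ignored; a mention is flagged when its
    span intersects a trigger's scope.
    """
    spans = [(m.start, m.end) for m in mentions]

    def clear(span: tuple[int, int]) -> bool:
        return not any(_overlaps(span, s) for s in spans)

    term_starts = sorted(
        s for rule in rules if rule.terminator
        for s in _find_phrase_spans(tokens, rule.tokens) if clear(s)
    )
    for rule in rules:
        if rule.terminator:
            continue
        for tspan in _find_phrase_spans(tokens, rule.tokens):
            if not clear(tspan):
                continue
            scopes = []
            if rule.direction in ("forward", "bidirectional"):
                lo = tspan[1]
                hi = min(len(tokens), lo + SCOPE_WINDOW)
                for ts, _ in term_starts:
                    if lo <= ts < hi:
                        hi = ts
                        break
                scopes.append((lo, hi))
            if rule.direction in ("backward", "bidirectional"):
                hi = tspan[0]
                lo = max(0, hi - SCOPE_WINDOW)
                for ts, te in reversed(term_starts):
                    if lo <= ts < hi:
                        lo = te
                        break
                scopes.append((lo, hi))
            for m in mentions:
                if any(_overlaps((m.start, m.end), s) for s in scopes):
                    m.set_flag(rule.category)
    return mentions


def extract_mentions(text: str, lexicon: Lexicon,
                     rules: list[ContextRule]) -> list[ConceptMention]:
    """Full per-note pipeline: sentences -> matches -> context flags."""
    out = []
    for s_idx, sentence in enumerate(split_sentences(text)):
        tokens = sentence_tokens(sentence)
        mentions = match_concepts(tokens, lexicon, s_idx)
        apply_context(tokens, mentions, rules)
        out.extend(mentions)
    return out


def mentions_table(note_id, mentions: list[ConceptMention]) -> pd.DataFrame:
    """Mentions as an exportable annotation table."""
    return pd.DataFrame(
        {
            "note_id": note_id,
            "sentence_index": [m.sentence_index for m in mentions],
            "start": [m.start for m in mentions],
            "end": [m.end for m in mentions],
            "concept_id": [m.concept_id for m in mentions],
            "negated": [m.negated for m in mentions],
            "hypothetical": [m.hypothetical for m in mentions],
            "historical": [m.historical for m in mentions],
            "experiencer_other": [m.experiencer_other for m in mentions],
        }
    )


# ---------------------------------------------------------------------------
# Tcon features
# ---------------------------------------------------------------------------


def concept_features(cohort: list[CohortObservation], notes: pd.DataFrame,
                     lexicon: Lexicon, rules: list[ContextRule],
                     window_days: int = 365,
                     drop_flags: tuple[str, ...] = DEFAULT_DROP_FLAGS,
                     vocabulary: list[str] | None = None) -> FeatureMatrix:
    """Binary concept-presence matrix (set Tcon).

    A concept column is 1 for an observation iff at least one mention in a
    note dated [index - window_days, index - 1] carries none of
    ``drop_flags``. With ``vocabulary`` given (a concept_id list from a
    fitted training run), columns follow exactly that feature space;
    otherwise columns are the concepts observed here (all-zero columns do
    not arise by construction).
    """
    by_person: dict[int, list[tuple[pd.Timestamp, str]]] = {}
    for pid, date, text in zip(notes["person_id"], notes["note_date"],
                               notes["text"]):
        by_person.setdefault(pid, []).append((date, text))

    mention_cache: dict[str, list[ConceptMention]] = {}

    def concepts_in(text: str) -> set[str]:
        if text not in mention_cache:
            mention_cache[text] = extract_mentions(text, lexicon, rules)
        return {
            m.concept_id
            for m in mention_cache[text]
            if not any(m.flag(c) for c in drop_flags)
        }

    present: list[set[str]] = []
    for obs in cohort:
        lo = obs.index_date - pd.Timedelta(days=window_days)
        hi = obs.index_date - pd.Timedelta(days=1)
        found: set[str] = set()
        for date, text in by_person.get(obs.person_id, []):
            if lo <= date <= hi:
                found |= concepts_in(text)
        present.append(found)

    if vocabulary is None:
        vocabulary = sorted(set().union(*present)) if present else []
    col = {c: j for j, c in enumerate(vocabulary)}
    rows_idx, cols_idx = [], []
    for i, found in enumerate(present):
        for c in found:
            if c in col:
                rows_idx.append(i)
                cols_idx.append(col[c])
    values = sp.csr_matrix(
        (np.ones(len(rows_idx)), (rows_idx, cols_idx)),
        shape=(len(cohort), len(vocabulary)),
    )
    names = {e.concept_id: e.preferred_name for e in lexicon.entries}
    descriptors = [
        FeatureDescriptor(f"Tcon:{c}", "Tcon", f"{window_days}d",
                          f"concept {names.get(c, c)}")
        for c in vocabulary
    ]
    return FeatureMatrix(cohort, descriptors, values)
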