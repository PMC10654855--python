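"""Concept matching and contextual-modifier detection against independent
brute-force oracles."""

import numpy as np
import pandas as pd

import textpred as tp
from textpred.concept_context import (
    CATEGORIES,
    SCOPE_WINDOW,
    Lexicon,
    LexiconEntry,
    sentence_tokens,
)
from textpred.omop_io import CohortObservation

from conftest import make_manual_dataset


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def oracle_matches(tokens, lexicon):
    """All-substring candidate scan with leftmost-longest greedy selection."""
    candidates = []
    for i in range(len(tokens)):
        for j in range(i + 1, len(tokens) + 1):
            entry = lexicon.lookup(tuple(tokens[i:j]))
            if entry is not None:
                candidates.append((i, j, entry.concept_id))
    chosen, pos = [], 0
    while True:
        viable = [c for c in candidates if c[0] >= pos]
        if not viable:
            return chosen
        first = min(c[0] for c in viable)
        best = max((c for c in viable if c[0] == first), key=lambda c: c[1])
        chosen.append(best)
        pos = best[1]


def oracle_flags(tokens, spans, rules):
    """Reference scope interpreter over explicit token-index sets."""

    def find(phrase):
        k = len(phrase)
        return [(i, i + k) for i in range(len(tokens) - k + 1)
                if tuple(tokens[i:i + k]) == phrase]

    def clear(s):
        return all(s[1] <= a or b <= s[0] for a, b in spans)

    terminators = sorted(
        s for r in rules if r.terminator for s in find(r.tokens) if clear(s)
    )
    flags = [set() for _ in spans]
    for rule in rules:
        if rule.terminator:
            continue
        for ts, te in find(rule.tokens):
            if not clear((ts, te)):
                continue
            region = set()
            if rule.direction in ("forward", "bidirectional"):
                fwd = set(range(te, min(len(tokens), te + SCOPE_WINDOW)))
                inside = [t for t in terminators if t[0] in fwd]
                if inside:
                    cut = min(t[0] for t in inside)
                    fwd = {i for i in fwd if i < cut}
                region |= fwd
            if rule.direction in ("backward", "bidirectional"):
                bwd = set(range(max(0, ts - SCOPE_WINDOW), ts))
                inside = [t for t in terminators if t[0] in bwd]
                if inside:
                    t = max(inside)
                    bwd = {i for i in bwd if i >= t[1]}
                region |= bwd
            for m, (a, b) in enumerate(spans):
                if region & set(range(a, b)):
                    flags[m].add(rule.category)
    return flags


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------


class TestSplitSentences:
    def test_terminal_punctuation(self):
        assert tp.split_sentences("Koorts. Geen hoest.") == \
            ["Koorts.", "Geen hoest."]

    def test_no_terminator_single_sentence(self):
        assert tp.split_sentences("al jaren bekend met astma zonder klachten") \
            == ["al jaren bekend met astma zonder klachten"]

    def test_newline_delimited_shorthand(self):
        text = "hoest sinds 3d\ngeen koorts\nzo nodig paracetamol"
        assert tp.split_sentences(text) == \
            ["hoest sinds 3d", "geen koorts", "zo nodig paracetamol"]

    def test_digits_preserved(self):
        assert sentence_tokens("rr 140/90 pols 72") == \
            ["rr", "140", "90", "pols", "72"]

    def test_covers_all_nonwhitespace(self):
        text = "Eerste zin. Tweede!\nDerde regel"
        joined = "".join(tp.split_sentences(text))
        for ch in text:
            if not ch.isspace():
                assert ch in joined


# ---------------------------------------------------------------------------
# Concept matching
# ---------------------------------------------------------------------------


class TestMatchConcepts:
    def test_longest_match_wins(self, lexicon):
        tokens = sentence_tokens("diabetes mellitus type")
        mentions = tp.match_concepts(tokens, lexicon)
        assert [(m.concept_id, m.start, m.end) for m in mentions] == \
            [("C0011", 0, 2)]

    def test_case_insensitive(self, lexicon):
        mentions = tp.match_concepts(sentence_tokens("KANKER"), lexicon)
        assert [m.concept_id for m in mentions] == ["C0001"]

    def test_no_terms_empty(self, lexicon):
        assert tp.match_concepts(sentence_tokens("geen bijzonderheden"),
                                 lexicon) == []

    def test_matches_equal_substring_scan_oracle(self, lexicon):
        rng = np.random.default_rng(42)
        pool = ["diabetes", "mellitus", "pijn", "op", "de", "borst", "kanker",
                "en", "zonder", "klachten", "copd", "status", "na", "wat",
                "hartfalen", "decompensatio", "cordis", "vaag"]
        for _ in range(300):
            tokens = list(rng.choice(pool, size=rng.integers(1, 12)))
            got = [(m.start, m.end, m.concept_id)
                   for m in tp.match_concepts(tokens, lexicon)]
            assert got == oracle_matches(tokens, lexicon)

    def test_lexicon_growth_keeps_nonoverlapped_matches(self, lexicon):
        rng = np.random.default_rng(9)
        pool = ["kanker", "hoest", "koorts", "vaag", "iets", "nieuwterm"]
        bigger = lexicon.add("nieuwterm", "C9999", "nieuw")
        for _ in range(100):
            tokens = list(rng.choice(pool, size=rng.integers(1, 10)))
            before = tp.match_concepts(tokens, lexicon)
            after = tp.match_concepts(tokens, bigger)
            new_spans = [(m.start, m.end) for m in after
                         if m.concept_id == "C9999"]
            for m in before:
                if not any(m.start < e and s < m.end for s, e in new_spans):
                    assert any(
                        (a.concept_id, a.start, a.end)
                        == (m.concept_id, m.start, m.end)
                        for a in after
                    )


# ---------------------------------------------------------------------------
# Context detection
# ---------------------------------------------------------------------------


class TestApplyContext:
    def _flags(self, text, lexicon, rules):
        mentions = tp.extract_mentions(text, lexicon, rules)
        return {
            m.concept_id: {c for c in CATEGORIES if m.flag(c)}
            for m in mentions
        }

    def test_forward_negation(self, lexicon, context_rules):
        flags = self._flags("geen aanwijzing voor pneumonie", lexicon,
                            context_rules)
        assert "negated" in flags["C0005"]

    def test_concept_before_forward_trigger_unflagged(self, lexicon,
                                                      context_rules):
        flags = self._flags("pneumonie geen", lexicon, context_rules)
        assert flags["C0005"] == set()

    def test_backward_trigger(self, lexicon, context_rules):
        flags = self._flags("pneumonie uitgesloten", lexicon, context_rules)
        assert "negated" in flags["C0005"]

    def test_terminator_truncates_scope(self, lexicon, context_rules):
        flags = self._flags("geen koorts maar hoest", lexicon, context_rules)
        assert "negated" in flags["C0007"]
        assert "negated" not in flags["C0006"]

    def test_scope_window_limit(self, lexicon, context_rules):
        filler = " ".join(["vaag"] * SCOPE_WINDOW)
        flags = self._flags(f"geen {filler} hoest", lexicon, context_rules)
        assert "negated" not in flags["C0006"]

    def test_categories_accumulate(self, lexicon, context_rules):
        flags = self._flags("moeder indien kanker", lexicon, context_rules)
        assert {"experiencer_other", "hypothetical"} <= flags["C0001"]

    def test_concept_wins_span_overlap(self, context_rules):
        lex = Lexicon([LexiconEntry("geen eetlust", "C9000", "anorexie")])
        mentions = tp.extract_mentions("geen eetlust", lex, context_rules)
        assert len(mentions) == 1
        assert not mentions[0].negated  # trigger inside concept is ignored

    def test_sentence_boundary_blocks_scope(self, lexicon, context_rules):
        flags = self._flags("geen klachten.\nhoest", lexicon, context_rules)
        assert flags["C0006"] == set()

    def test_empty_rule_table_leaves_flags_false(self, lexicon):
        mentions = tp.extract_mentions("geen kanker en geen hoest", lexicon, [])
        assert mentions and all(
            not any(m.flag(c) for c in CATEGORIES) for m in mentions
        )

    def test_matches_reference_scope_interpreter(self, lexicon, context_rules):
        rng = np.random.default_rng(7)
        pool = ["geen", "niet", "indien", "moeder", "maar", "echter",
                "uitgesloten", "eerder", "kanker", "hoest", "koorts",
                "pneumonie", "diabetes", "mellitus", "vaag", "iets", "en",
                "aanwijzing", "voor", "status", "na"]
        checked = 0
        for _ in range(250):
            tokens = list(rng.choice(pool, size=rng.integers(2, 14)))
            mentions = tp.match_concepts(tokens, lexicon)
            tp.apply_context(tokens, mentions, context_rules)
            spans = [(m.start, m.end) for m in mentions]
            expected = oracle_flags(tokens, spans, context_rules)
            for m, exp in zip(mentions, expected):
                assert {c for c in CATEGORIES if m.flag(c)} == exp
            checked += len(mentions)
        assert checked >= 200


# ---------------------------------------------------------------------------
# Tcon features
# ---------------------------------------------------------------------------


class TestConceptFeatures:
    def _dataset(self, notes):
        return make_manual_dataset([
            (1, 1950, "M", "2015-01-01", "2019-01-01", [],
             [(d, t) for d, t in notes]),
        ])

    def _obs(self):
        return [CohortObservation(1, pd.Timestamp("2018-01-01"), 0, "A")]

    def test_negated_only_concept_absent(self, lexicon, context_rules):
        ds = self._dataset([("2017-06-01", "geen kanker")])
        T = tp.concept_features(self._obs(), ds.notes, lexicon, context_rules)
        assert "Tcon:C0001" not in T.feature_ids

    def test_repeated_concept_binary(self, lexicon, context_rules):
        ds = self._dataset([("2017-06-01", "kanker"), ("2017-07-01", "kanker"),
                            ("2017-08-01", "kanker")])
        T = tp.concept_features(self._obs(), ds.notes, lexicon, context_rules)
        j = T.feature_ids.index("Tcon:C0001")
        assert np.asarray(T.values.todense())[0, j] == 1.0

    def test_historical_kept_by_default(self, lexicon, context_rules):
        ds = self._dataset([("2017-06-01", "eerder kanker")])
        T = tp.concept_features(self._obs(), ds.notes, lexicon, context_rules)
        assert "Tcon:C0001" in T.feature_ids

    def test_out_of_window_note_ignored(self, lexicon, context_rules):
        ds = self._dataset([("2016-06-01", "kanker")])  # >365d before index
        T = tp.concept_features(self._obs(), ds.notes, lexicon, context_rules)
        assert T.shape[1] == 0

    def test_empty_rules_equal_unfiltered_presence(self, lexicon,
                                                   context_rules, small_dataset,
                                                   small_cohort):
        none = tp.concept_features(small_cohort, small_dataset.notes, lexicon, [])
        keep_all = tp.concept_features(small_cohort, small_dataset.notes,
                                       lexicon, context_rules, drop_flags=())
        assert none.feature_ids == keep_all.feature_ids
        assert (none.values != keep_all.values).nnz == 0

    def test_matches_mention_then_filter_oracle(self, lexicon, context_rules,
                                                small_dataset, small_cohort):
        cohort = small_cohort[:40]
        T = tp.concept_features(cohort, small_dataset.notes, lexicon,
                                context_rules)
        vals = np.asarray(T.values.todense())
        for i, obs in enumerate(cohort):
            expected = set()
            lo = obs.index_date - pd.Timedelta(days=365)
            hi = obs.index_date - pd.Timedelta(days=1)
            sub = small_dataset.notes
            sub = sub[(sub["person_id"] == obs.person_id)
                      & (sub["note_date"] >= lo) & (sub["note_date"] <= hi)]
            for text in sub["text"]:
                for m in tp.extract_mentions(text, lexicon, context_rules):
                    if not (m.negated or m.hypothetical or m.experiencer_other):
                        expected.add(m.concept_id)
            got = {fid.split(":")[1] for j, fid in enumerate(T.feature_ids)
                   if vals[i, j] == 1.0}
            assert got == expected

    def test_determinism(self, lexicon, context_rules, small_dataset,
                         small_cohort):
        a = tp.concept_features(small_cohort, small_dataset.notes, lexicon,
                                context_rules)
        b = tp.concept_features(small_cohort, small_dataset.notes, lexicon,
                                context_rules)
        assert a.feature_ids == b.feature_ids
        assert (a.values != b.values).nnz == 0
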