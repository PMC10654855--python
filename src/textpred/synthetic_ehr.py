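"""Seeded synthetic GP EHR datasets with planted outcome signals.

The generator emulates the note and event statistics of Dutch GP
populations recorded under different EHR systems: tens of short,
line-oriented notes and a few hundred words per 365-day observation
window, sparse coded events across four clinical domains, and outcome
prevalences in the 0.04-0.46 range. Notes are bags of tokens drawn from a
Zipfian background vocabulary of Dutch-like tokens (no grammar), which is
sufficient to exercise bag-of-words, TF-IDF, and dictionary-based concept
pipelines. Outcome labels come from a logistic model over planted
structured (event-code) and textual (token) exposures, so every
downstream stage has a recoverable ground truth.

Distribution shift between two "EHR systems" is modelled as (a) different
profile medians (note counts, note lengths, event densities) and (b)
renaming a fraction of the background vocabulary (spelling-variant
surrogate). Planted signal terms are never renamed, mirroring clinically
salient words that survive across systems.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .omop_io import EHRDataset, EVENT_DOMAINS, TaskSpec

BACKGROUND_VOCAB_SIZE = 2000
_VOCAB_SEED = 715_001  # fixed: the token inventory is part of the world, not the draw
_ZIPF_EXPONENT = 1.1

_DEFAULT_EVENTS = {"condition": 13, "drug": 6, "measurement": 9, "procedure": 1}

# tokens woven into background text so context detection has work to do
_CONTEXT_FILLER = ["geen", "niet", "indien", "moeder", "vader", "eerder"]


@functools.lru_cache(maxsize=1)
def _clinical_terms() -> tuple[str, ...]:
    """Surface terms of the bundled lexicon, woven into background text so
    concept extraction yields tens of mentions per observation (as real GP
    notes do). Multi-word terms appear as contiguous word runs."""
    from .concept_context import load_lexicon

    return tuple(sorted({e.term.lower() for e in load_lexicon().entries}))


@dataclass
class SystemProfile:
    """Marginal statistics of one synthetic EHR system population."""

    system_id: str
    n_patients: int
    notes_per_obs_median: int = 30
    words_per_note_median: int = 12
    events_per_obs_median: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_EVENTS)
    )
    vocab_shift: float = 0.0
    frac_short_prior: float = 0.10
    frac_lost_followup: float = 0.10
    communication_note_frac: float = 0.10

    def validate(self) -> "SystemProfile":
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if self.notes_per_obs_median <= 0 or self.words_per_note_median <= 0:
            raise ConfigurationError("note/word medians must be positive")
        for dom, m in self.events_per_obs_median.items():
            if dom not in EVENT_DOMAINS:
                raise ConfigurationError(f"unknown event domain {dom!r}")
            if m < 0:
                raise ConfigurationError("event medians must be non-negative")
        if not 0.0 <= self.vocab_shift <= 1.0:
            raise ConfigurationError("vocab_shift must be in [0, 1]")
        return self


@dataclass
class SignalSpec:
    """Planted outcome signals feeding the logistic label model.

    Each (token, weight) / (code, weight) pair contributes ``weight`` to
    the outcome log-odds when the person is exposed (exposure is Bernoulli
    with ``exposure_prob`` per signal, independent across signals). Exposed
    text terms are written into notes inside the covariate window; exposed
    event codes become condition events inside the window.
    """

    text_signal_terms: list[tuple[str, float]] = field(default_factory=list)
    event_signal_codes: list[tuple[str, float]] = field(default_factory=list)
    baseline_log_odds: float = 0.0
    noise_sd: float = 0.0
    exposure_prob: float = 0.3

    def validate(self) -> "SignalSpec":
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 < self.exposure_prob <= 1.0:
            raise ConfigurationError("exposure_prob must be in (0, 1]")
        return self

    def signal_tokens(self) -> set[str]:
        return {t for t, _ in self.text_signal_terms}


@functools.lru_cache(maxsize=4)
def background_vocabulary(size: int = BACKGROUND_VOCAB_SIZE) -> tuple[str, ...]:
    """Deterministic inventory of Dutch-looking syllabic tokens.

    The inventory is fixed (independent of the dataset seed): two systems
    drawn with different seeds share a vocabulary unless ``vocab_shift``
    renames part of it.
    """
    rng = np.random.default_rng(_VOCAB_SEED)
    onsets = ["b", "d", "g", "h", "k", "l", "m", "n", "p", "r", "s", "t", "v",
              "w", "z", "st", "sch", "br", "kl", "dr", "gr", "zw", "vr", "sp"]
    nuclei = ["a", "e", "i", "o", "u", "aa", "ee", "oo", "ij", "ei", "oe",
              "ui", "au"]
    codas = ["", "", "k", "l", "m", "n", "p", "r", "s", "t", "g", "nd", "rt",
             "ng", "cht"]
    clinical = _clinical_terms()
    n_special = len(_CONTEXT_FILLER) + len(clinical)
    vocab: list[str] = []
    seen = set(_CONTEXT_FILLER) | set(clinical)
    while len(vocab) < size - n_special:
        n_syll = int(rng.integers(1, 4))
        word = "".join(
            onsets[rng.integers(len(onsets))]
            + nuclei[rng.integers(len(nuclei))]
            + (codas[rng.integers(len(codas))] if s == n_syll - 1 else "")
            for s in range(n_syll)
        )
        if word not in seen and len(word) >= 2:
            seen.add(word)
            vocab.append(word)
    # context fillers and clinical terms get mid-rank slots so they occur
    # regularly in background text
    for i, tok in enumerate(_CONTEXT_FILLER):
        vocab.insert(20 + 5 * i, tok)
    for i, term in enumerate(clinical):
        vocab.insert(60 + 11 * i, term)
    return tuple(vocab)


def _zipf_probs(size: int) -> np.ndarray:
    ranks = np.arange(1, size + 1, dtype=float)
    p = ranks ** (-_ZIPF_EXPONENT)
    return p / p.sum()


def _shifted_vocabulary(vocab: tuple[str, ...], shift: float,
                        protected: set[str]) -> list[str]:
    """Rename a ``shift`` fraction of tokens (spelling-variant surrogate).

    The renamed subset depends only on the shift fraction, so two systems
    generated with any seeds see the same renaming. Protected (signal)
    tokens and context fillers are never renamed.
    """
    if shift <= 0:
        return list(vocab)
    rng = np.random.default_rng((987_654_321, int(round(shift * 1_000_000))))
    keep = protected | set(_CONTEXT_FILLER) | set(_clinical_terms())
    eligible = [i for i, t in enumerate(vocab) if t not in keep]
    n_rename = int(round(shift * len(vocab)))
    chosen = rng.choice(len(eligible), size=min(n_rename, len(eligible)),
                        replace=False)
    out = list(vocab)
    existing = set(vocab)
    for j in chosen:
        i = eligible[j]
        variant = out[i] + "je"  # diminutive-style respelling
        while variant in existing:
            variant += "s"
        existing.add(variant)
        out[i] = variant
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_dataset(profile: SystemProfile, signal: SignalSpec, task: TaskSpec,
                     seed: int | np.random.SeedSequence) -> EHRDataset:
    """Draw one synthetic EHR system population.

    Every person receives a target event (the task's index event) inside an
    observation period constructed so that controlled fractions of the
    population violate the 365-day prior-observation rule or leave the
    database inside the time-at-risk window. Outcome events are planted in
    the TAR for persons whose logistic draw is positive; a small fraction
    of decoy outcome events falls outside the TAR to exercise window logic.

    Identical seeds give byte-identical tables.
    """
    profile.validate()
    signal.validate()
    rng = np.random.default_rng(seed)

    vocab = _shifted_vocabulary(
        background_vocabulary(), profile.vocab_shift, signal.signal_tokens()
    )
    vprobs = _zipf_probs(len(vocab))

    n = profile.n_patients
    base = pd.Timestamp("2018-01-01")
    text_terms = list(signal.text_signal_terms)
    event_codes = list(signal.event_signal_codes)

    persons_rows = []
    events_rows = []
    notes_rows = []
    periods_rows = []
    note_id = 0

    domain_codes = {
        dom: [f"{dom[:4]}{i:03d}" for i in range(120)] for dom in EVENT_DOMAINS
    }
    dprobs = _zipf_probs(120)

    for pid in range(1, n + 1):
        index = base + pd.Timedelta(days=int(rng.integers(0, 365)))
        age = int(rng.integers(20, 91))
        yob = index.year - age
        sex = "M" if rng.random() < 0.5 else "F"
        persons_rows.append((pid, yob, sex))

        if rng.random() < profile.frac_short_prior:
            prior = int(rng.integers(30, task.observation_days))
        else:
            prior = int(rng.integers(task.observation_days, 1500))
        if rng.random() < profile.frac_lost_followup:
            follow = int(rng.integers(0, task.tar_end_days))
        else:
            follow = int(rng.integers(task.tar_end_days, task.tar_end_days + 400))
        start = index - pd.Timedelta(days=prior)
        end = index + pd.Timedelta(days=follow)
        periods_rows.append((pid, start, end))

        events_rows.append((pid, "procedure", task.target_code, index))
        # readmission-style tasks: some persons get a second index event
        if task.multiple_obs_per_patient and follow > 40 and rng.random() < 0.15:
            delta = int(rng.integers(35, min(120, follow) + 1))
            events_rows.append((pid, "procedure", task.target_code,
                                index + pd.Timedelta(days=delta)))

        # covariate window available to this person
        win_lo = max(1, min(prior, task.observation_days))

        # background events per domain
        for dom in EVENT_DOMAINS:
            med = profile.events_per_obs_median.get(dom, 0)
            k = int(rng.poisson(med))
            for _ in range(k):
                offset = int(rng.integers(-prior, follow + 1))
                code = domain_codes[dom][rng.choice(120, p=dprobs)]
                events_rows.append((pid, dom, code,
                                    index + pd.Timedelta(days=offset)))

        # signal exposures
        text_exp = rng.random(len(text_terms)) < signal.exposure_prob
        event_exp = rng.random(len(event_codes)) < signal.exposure_prob
        logit = signal.baseline_log_odds
        for exposed, (_, w) in zip(text_exp, text_terms):
            if exposed:
                logit += w
        for exposed, (_, w) in zip(event_exp, event_codes):
            if exposed:
                logit += w
        if signal.noise_sd > 0:
            logit += signal.noise_sd * rng.standard_normal()
        label = int(rng.random() < _sigmoid(np.asarray(logit)))

        for exposed, (code, _) in zip(event_exp, event_codes):
            if exposed:
                offset = int(rng.integers(1, win_lo + 1))
                events_rows.append((pid, "condition", code,
                                    index - pd.Timedelta(days=offset)))

        # outcome event inside TAR when the label fired and follow-up allows
        if label and follow >= task.tar_start_days:
            hi = min(task.tar_end_days, follow)
            off = int(rng.integers(task.tar_start_days, hi + 1))
            events_rows.append((pid, "condition", task.outcome_code,
                                index + pd.Timedelta(days=off)))
        elif rng.random() < 0.05 and prior > 40:
            # decoy outcome outside the TAR (before the index)
            off = int(rng.integers(5, min(prior, 400)))
            events_rows.append((pid, "condition", task.outcome_code,
                                index - pd.Timedelta(days=off)))

        # notes: mostly inside the covariate window, some outside
        n_notes = max(1, int(rng.poisson(profile.notes_per_obs_median)))
        in_window_notes = []
        for _ in range(n_notes):
            if rng.random() < 0.85:
                offset = -int(rng.integers(1, win_lo + 1))
            else:
                offset = int(rng.integers(-prior, follow + 1))
            ndate = index + pd.Timedelta(days=offset)
            n_words = max(1, int(rng.poisson(profile.words_per_note_median)))
            toks = [vocab[j] for j in rng.choice(len(vocab), size=n_words, p=vprobs)]
            text = _format_note(toks, rng)
            klass = ("communication"
                     if rng.random() < profile.communication_note_frac else "gp")
            note_id += 1
            notes_rows.append((note_id, pid, ndate, klass, text))
            if -win_lo <= offset <= -1:
                in_window_notes.append(len(notes_rows) - 1)

        # write exposed signal terms into in-window notes as their own lines
        exposed_terms = [t for e, (t, _) in zip(text_exp, text_terms) if e]
        if exposed_terms and not in_window_notes:
            offset = -int(rng.integers(1, win_lo + 1))
            note_id += 1
            notes_rows.append((note_id, pid, index + pd.Timedelta(days=offset),
                               "gp", ""))
            in_window_notes.append(len(notes_rows) - 1)
        for term in exposed_terms:
            n_mentions = 1 + int(rng.poisson(1.0))
            for _ in range(n_mentions):
                i = in_window_notes[rng.integers(len(in_window_notes))]
                nid, p, d, k, text = notes_rows[i]
                line = term + ("." if rng.random() < 0.5 else "")
                notes_rows[i] = (nid, p, d, k,
                                 (text + "\n" + line) if text else line)

    persons = pd.DataFrame(persons_rows,
                           columns=["person_id", "year_of_birth", "sex"])
    events = pd.DataFrame(events_rows,
                          columns=["person_id", "domain", "concept_code",
                                   "event_date"])
    notes = pd.DataFrame(notes_rows,
                         columns=["note_id", "person_id", "note_date",
                                  "note_class", "text"])
    periods = pd.DataFrame(periods_rows,
                           columns=["person_id", "start_date", "end_date"])
    events = events.sort_values(
        ["person_id", "event_date", "domain", "concept_code"]
    ).reset_index(drop=True)
    dataset = EHRDataset(persons=persons, events=events, notes=notes,
                         observation_periods=periods,
                         system_id=profile.system_id)
    return dataset.validate()


def _format_note(tokens: list[str], rng: np.random.Generator) -> str:
    """Arrange tokens as short GP-style shorthand lines (~5 words each),
    sprinkling digits and punctuation so preprocessing has work to do."""
    lines = []
    i = 0
    while i < len(tokens):
        n = int(rng.integers(3, 8))
        line_toks = tokens[i:i + n]
        i += n
        if rng.random() < 0.15:
            line_toks.insert(int(rng.integers(0, len(line_toks) + 1)),
                             str(rng.integers(1, 200)))
        line = " ".join(line_toks)
        if rng.random() < 0.3:
            line += "."
        elif rng.random() < 0.1:
            line = line.replace(" ", ", ", 1)
        lines.append(line)
    return "\n".join(lines)


def make_system_pair(profile_a: SystemProfile, profile_b: SystemProfile,
                     signal: SignalSpec, task: TaskSpec,
                     seed: int) -> tuple[EHRDataset, EHRDataset]:
    """Two populations sharing the planted signal but differing in surface
    distribution (profile medians, vocabulary spelling)."""
    ss_a, ss_b = np.random.SeedSequence(seed).spawn(2)
    return (
        generate_dataset(profile_a, signal, task, ss_a),
        generate_dataset(profile_b, signal, task, ss_b),
    )
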