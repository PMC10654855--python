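"""Bag-of-words featurization of clinical notes with a serializable
pipeline configuration.

The pipeline concatenates all of an observation's notes from the 365-day
covariate window into one document, replaces digits, newlines, and
underscores with spaces, lowercases and splits at spaces/punctuation,
prunes the vocabulary by document frequency (terms in more than 80% or
fewer than 0.1% of training documents are dropped; both boundaries are
kept), and emits either binary term-occurrence vectors (Tterm) or
TF-IDF vectors (Ttfidf) with tfidf(t, d) = tf(t, d) * ln(N / df(t)) —
raw counts, natural-log idf, no smoothing, no length normalization.

The fitted vocabulary and idf table are frozen at fit time and applied
unchanged to held-out or external documents: unseen terms are ignored, so
a config fitted on one EHR system produces exactly the training feature
space on any other corpus. Configs round-trip through JSON together with
a vocabulary checksum; a checksum mismatch on load raises an integrity
warning but still loads (the user may have edited the vocabulary on
purpose).
"""

from __future__ import annotations

import hashlib
import json
import math
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import FitError
from .omop_io import CohortObservation, FeatureDescriptor, FeatureMatrix

_STRIP_RE = re.compile(r"[\d_\r\n]")
_TOKEN_RE = re.compile(r"[\W_]+", re.UNICODE)

DEFAULT_MAX_DF = 0.8
DEFAULT_MIN_DF = 0.001
# relative slack so df == max_df * N survives float rounding
_DF_EPS = 1e-9


class IntegrityWarning(UserWarning):
    """Persisted pipeline artifacts failed a checksum comparison."""


def preprocess(text: str) -> str:
    """Replace every digit, newline (\\n or \\r), and underscore with one
    space; all other characters pass through untouched."""
    return _STRIP_RE.sub(" ", text)


def tokenize(text: str) -> list[str]:
    """Lowercase and split at spaces and punctuation; drop empty tokens."""
    return [t for t in _TOKEN_RE.split(text.lower()) if t]


@dataclass(frozen=True)
class ObservationDocument:
    """All in-window note text of one observation, concatenated."""

    observation: CohortObservation
    text: str
    note_count: int


def build_documents(cohort: list[CohortObservation], notes: pd.DataFrame,
                    window_days: int = 365) -> list[ObservationDocument]:
    """One document per observation from notes dated in
    [index - window_days, index - 1]; observations without in-window notes
    yield an empty document (kept, not dropped)."""
    by_person: dict[int, list[tuple[pd.Timestamp, str]]] = {}
    for pid, date, text in zip(notes["person_id"], notes["note_date"],
                               notes["text"]):
        by_person.setdefault(pid, []).append((date, text))
    docs = []
    for obs in cohort:
        lo = obs.index_date - pd.Timedelta(days=window_days)
        hi = obs.index_date - pd.Timedelta(days=1)
        in_window = [
            (d, t) for d, t in by_person.get(obs.person_id, []) if lo <= d <= hi
        ]
        in_window.sort(key=lambda pair: pair[0])
        docs.append(
            ObservationDocument(
                observation=obs,
                text="\n".join(t for _, t in in_window),
                note_count=len(in_window),
            )
        )
    return docs


@dataclass
class PipelineConfig:
    """Frozen state of a fitted text pipeline.

    Stores the pruning thresholds, the fitted vocabulary with its document
    frequencies and idf values, the fitting-corpus size, and a fingerprint
    (free-form dict, e.g. seed and dataset hash) so processed results can
    be shared and reproduced exactly.
    """

    representation: str = "binary"  # binary | tfidf | concept
    lowercase: bool = True
    max_df: float = DEFAULT_MAX_DF
    min_df: float = DEFAULT_MIN_DF
    window_days: int = 365
    n_fit: int = 0
    vocabulary: list[str] = field(default_factory=list)
    df_table: dict[str, int] = field(default_factory=dict)
    idf_table: dict[str, float] = field(default_factory=dict)
    fingerprint: dict = field(default_factory=dict)

    def vocab_checksum(self) -> str:
        payload = json.dumps([self.vocabulary, self.df_table], sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _document_counts(doc: ObservationDocument) -> Counter:
    return Counter(tokenize(preprocess(doc.text)))


def corpus_statistics(documents: list[ObservationDocument]
                      ) -> tuple[list[Counter], Counter, int]:
    """Per-document term counts tf(t, d), document frequencies df(t), and
    corpus size N. df(t) counts documents with tf(t, d) > 0."""
    counts = [_document_counts(d) for d in documents]
    df = Counter()
    for c in counts:
        df.update(c.keys())
    return counts, df, len(documents)


def fit_vocabulary(documents: list[ObservationDocument],
                   max_df: float = DEFAULT_MAX_DF,
                   min_df: float = DEFAULT_MIN_DF,
                   representation: str = "binary",
                   window_days: int = 365,
                   fingerprint: dict | None = None) -> PipelineConfig:
    """Fit the vocabulary and idf table on a training corpus.

    A term is kept iff min_df * N <= df(t) <= max_df * N (boundaries
    inclusive). Raises :class:`FitError` on an empty corpus or a corpus of
    only empty documents.
    """
    counts, df, n = corpus_statistics(documents)
    if n == 0 or not df:
        raise FitError("cannot fit a vocabulary on an empty corpus")
    hi = max_df * n * (1 + _DF_EPS)
    lo = min_df * n * (1 - _DF_EPS)
    vocab = sorted(t for t, c in df.items() if lo <= c <= hi)
    idf = {t: math.log(n / df[t]) for t in vocab}
    return PipelineConfig(
        representation=representation,
        max_df=max_df,
        min_df=min_df,
        window_days=window_days,
        n_fit=n,
        vocabulary=vocab,
        df_table={t: int(df[t]) for t in vocab},
        idf_table=idf,
        fingerprint=dict(fingerprint or {}),
    )


def _vectorize(documents: list[ObservationDocument], config: PipelineConfig,
               binary: bool) -> FeatureMatrix:
    if not config.vocabulary:
        raise FitError("config has an empty vocabulary; fit it first")
    col = {t: j for j, t in enumerate(config.vocabulary)}
    rows, cols, vals = [], [], []
    for i, doc in enumerate(documents):
        for term, tf in _document_counts(doc).items():
            j = col.get(term)
            if j is None:
                continue  # out-of-vocabulary (incl. unseen external terms)
            v = 1.0 if binary else tf * config.idf_table[term]
            if v != 0.0:
                rows.append(i)
                cols.append(j)
                vals.append(v)
    values = sp.csr_matrix(
        (np.array(vals), (rows, cols)),
        shape=(len(documents), len(config.vocabulary)),
    )
    set_name = "Tterm" if binary else "Ttfidf"
    tag = f"{config.window_days}d"
    descriptors = [
        FeatureDescriptor(f"{set_name}:{t}", set_name, tag, f"term '{t}'")
        for t in config.vocabulary
    ]
    return FeatureMatrix([d.observation for d in documents], descriptors, values)


def vectorize_binary(documents: list[ObservationDocument],
                     config: PipelineConfig) -> FeatureMatrix:
    """Binary term occurrence over the fitted vocabulary (set Tterm)."""
    return _vectorize(documents, config, binary=True)


def vectorize_tfidf(documents: list[ObservationDocument],
                    config: PipelineConfig) -> FeatureMatrix:
    """tf(t, d) * ln(N_fit / df_fit(t)) over the fitted vocabulary
    (set Ttfidf); fitting-corpus statistics are applied unchanged to
    held-out documents."""
    return _vectorize(documents, config, binary=False)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Serialize a fitted pipeline to JSON with a vocabulary checksum."""
    payload = {
        "representation": config.representation,
        "lowercase": config.lowercase,
        "max_df": config.max_df,
        "min_df": config.min_df,
        "window_days": config.window_days,
        "n_fit": config.n_fit,
        "vocabulary": config.vocabulary,
        "df_table": config.df_table,
        "idf_table": config.idf_table,
        "fingerprint": config.fingerprint,
        "vocab_checksum": config.vocab_checksum(),
    }
    Path(path).write_text(json.dumps(payload))


def load_config(path: str | Path) -> PipelineConfig:
    """Inverse of :func:`save_config`; warns if the checksum mismatches."""
    payload = json.loads(Path(path).read_text())
    stored = payload.pop("vocab_checksum", None)
    config = PipelineConfig(**payload)
    if stored is not None and stored != config.vocab_checksum():
        warnings.warn(
            f"vocabulary checksum mismatch in {path}: the stored pipeline "
            "state was modified after saving",
            IntegrityWarning,
            stacklevel=2,
        )
    return config
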