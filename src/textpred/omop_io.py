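"""Simplified OMOP-CDM-style relational tables, cohort construction, and
sparse feature-matrix persistence.

The schema keeps only the columns that patient-level prediction on GP data
actually consumes: a person table, a long event table covering the four
clinical domains (condition, drug, measurement, procedure), a note table,
and observation periods. Concept codes are opaque strings; dates are
calendar dates. Covariate windows are closed intervals in whole days and
"365 days prior to the index" means [index-365, index-1] — the index date
itself never contributes covariates, which prevents outcome leakage at the
index. The time-at-risk (TAR) window is [index + tar_start_days,
index + tar_end_days], closed on both ends.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .exceptions import IntegrityError, SchemaError

EVENT_DOMAINS = ("condition", "drug", "measurement", "procedure")
NOTE_CLASSES = ("gp", "communication")

_PERSON_COLS = ["person_id", "year_of_birth", "sex"]
_EVENT_COLS = ["person_id", "domain", "concept_code", "event_date"]
_NOTE_COLS = ["note_id", "person_id", "note_date", "note_class", "text"]
_OBS_COLS = ["person_id", "start_date", "end_date"]

_TABLE_FILES = {
    "persons": "persons.csv",
    "events": "events.csv",
    "notes": "notes.csv",
    "observation_periods": "observation_periods.csv",
}


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


@dataclass
class EHRDataset:
    """Container of person/event/note/observation-period tables for one EHR
    system.

    Invariants (checked by :meth:`validate`): every ``person_id`` in a child
    table exists in ``persons``; every event and note date falls inside some
    observation period of that person.
    """

    persons: pd.DataFrame
    events: pd.DataFrame
    notes: pd.DataFrame
    observation_periods: pd.DataFrame
    system_id: str = "A"

    def validate(self) -> "EHRDataset":
        for name, df, cols in (
            ("persons", self.persons, _PERSON_COLS),
            ("events", self.events, _EVENT_COLS),
            ("notes", self.notes, _NOTE_COLS),
            ("observation_periods", self.observation_periods, _OBS_COLS),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"table {name!r} is missing columns {missing}")
        known = set(self.persons["person_id"])
        for name, df in (
            ("events", self.events),
            ("notes", self.notes),
            ("observation_periods", self.observation_periods),
        ):
            orphan = ~df["person_id"].isin(known)
            if orphan.any():
                row = int(np.flatnonzero(orphan.to_numpy())[0])
                pid = df["person_id"].iloc[row]
                raise SchemaError(
                    f"table {name!r} row {row}: person_id {pid!r} not in persons"
                )
        self._check_dates_in_periods("events", self.events, "event_date")
        self._check_dates_in_periods("notes", self.notes, "note_date")
        return self

    def _check_dates_in_periods(self, name: str, df: pd.DataFrame, col: str) -> None:
        if df.empty:
            return
        rows = df[["person_id", col]].reset_index(names="_row")
        merged = rows.merge(self.observation_periods, on="person_id", how="left")
        inside = (merged[col] >= merged["start_date"]) & (
            merged[col] <= merged["end_date"]
        )
        # a row passes if ANY of its person's periods covers the date
        covered = inside.groupby(merged["_row"]).any()
        if not covered.all():
            row = int(covered.index[~covered][0])
            pid = df.loc[row, "person_id"]
            date = df.loc[row, col]
            raise SchemaError(
                f"table {name!r} row {row}: {col} {date.date()} of person "
                f"{pid!r} outside all observation periods"
            )

    def persons_set(self) -> set:
        return set(self.persons["person_id"])


def write_dataset(dataset: EHRDataset, out_dir: str | Path) -> None:
    """Write the four tables as RFC-4180 CSVs (ISO-8601 dates)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in _TABLE_FILES.items():
        df = getattr(dataset, attr).copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%d")
        df.to_csv(out / fname, index=False)
    (out / "system.json").write_text(json.dumps({"system_id": dataset.system_id}))


def read_dataset(path_map: dict[str, str | Path] | str | Path) -> EHRDataset:
    """Read and validate a dataset.

    ``path_map`` maps table names (persons, events, notes,
    observation_periods) to CSV paths; a single directory written by
    :func:`write_dataset` is also accepted.
    """
    if isinstance(path_map, (str, Path)):
        base = Path(path_map)
        path_map = {k: base / v for k, v in _TABLE_FILES.items()}
        system_file = base / "system.json"
        system_id = (
            json.loads(system_file.read_text())["system_id"]
            if system_file.exists()
            else "A"
        )
    else:
        system_id = "A"
    missing = [k for k in _TABLE_FILES if k not in path_map]
    if missing:
        raise SchemaError(f"path_map is missing tables {missing}")
    date_cols = {
        "persons": [],
        "events": ["event_date"],
        "notes": ["note_date"],
        "observation_periods": ["start_date", "end_date"],
    }
    tables = {}
    for name in _TABLE_FILES:
        df = pd.read_csv(path_map[name], dtype={"concept_code": str}, keep_default_na=False, na_values=[])
        for col in date_cols[name]:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        if name == "notes" and "text" in df.columns:
            df["text"] = df["text"].astype(str)
        tables[name] = df
    return EHRDataset(system_id=system_id, **tables).validate()


# ---------------------------------------------------------------------------
# Task specification and cohort construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskSpec:
    """One prediction problem: a target-event rule defining index dates, an
    outcome rule, and the time-at-risk window.

    ``target_code`` events (optionally age-restricted at the index date)
    define candidate index dates; the label is 1 iff an ``outcome_code``
    event occurs within [index + tar_start_days, index + tar_end_days].
    ``observation_days`` of continuous observation before the index are
    required. Only readmission-style tasks allow several observations per
    person; all others keep the earliest qualifying index date.
    """

    task_id: str
    target_code: str
    outcome_code: str
    tar_start_days: int
    tar_end_days: int
    observation_days: int = 365
    min_age: int | None = None
    multiple_obs_per_patient: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.tar_start_days <= self.tar_end_days):
            raise SchemaError(
                f"task {self.task_id!r}: need 0 < tar_start_days <= tar_end_days, "
                f"got {self.tar_start_days}..{self.tar_end_days}"
            )
        if self.observation_days <= 0:
            raise SchemaError("observation_days must be positive")


@dataclass(frozen=True)
class CohortObservation:
    """One qualifying (person, index date) row with its outcome label."""

    person_id: int
    index_date: pd.Timestamp
    label: int
    system_id: str


def build_cohort(dataset: EHRDataset, task: TaskSpec) -> list[CohortObservation]:
    """Apply the task definition to a dataset.

    A candidate (person, index date) qualifies iff a single observation
    period of that person covers [index - observation_days, index +
    tar_end_days]: the person has the full prior observation window and is
    not lost to follow-up inside the TAR.
    """
    events = dataset.events
    cand = events.loc[events["concept_code"] == task.target_code,
                      ["person_id", "event_date"]].drop_duplicates()
    cand = cand.merge(dataset.persons[["person_id", "year_of_birth"]], on="person_id")
    if task.min_age is not None:
        age = cand["event_date"].dt.year - cand["year_of_birth"]
        cand = cand[age >= task.min_age]

    periods = dataset.observation_periods
    merged = cand.merge(periods, on="person_id", how="left")
    lo = merged["event_date"] - pd.Timedelta(days=task.observation_days)
    hi = merged["event_date"] + pd.Timedelta(days=task.tar_end_days)
    covers = (merged["start_date"] <= lo) & (merged["end_date"] >= hi)
    merged = merged[covers]
    qual = merged[["person_id", "event_date"]].drop_duplicates()

    if not task.multiple_obs_per_patient:
        qual = qual.sort_values(["person_id", "event_date"]).groupby(
            "person_id", as_index=False
        ).first()

    outcomes = events.loc[
        events["concept_code"] == task.outcome_code, ["person_id", "event_date"]
    ].rename(columns={"event_date": "outcome_date"})
    joined = qual.merge(outcomes, on="person_id", how="left")
    start = joined["event_date"] + pd.Timedelta(days=task.tar_start_days)
    end = joined["event_date"] + pd.Timedelta(days=task.tar_end_days)
    hit = (joined["outcome_date"] >= start) & (joined["outcome_date"] <= end)
    labels = (
        hit.groupby([joined["person_id"], joined["event_date"]]).any().astype(int)
    )

    qual = qual.sort_values(["person_id", "event_date"])
    cohort = [
        CohortObservation(
            person_id=int(pid),
            index_date=pd.Timestamp(idx),
            label=int(labels.loc[(pid, idx)]),
            system_id=dataset.system_id,
        )
        for pid, idx in zip(qual["person_id"], qual["event_date"])
    ]
    if not cohort:
        warnings.warn(
            f"task {task.task_id!r}: no qualifying observations in system "
            f"{dataset.system_id!r}", stacklevel=2,
        )
    return cohort


def cohort_frame(cohort: list[CohortObservation]) -> pd.DataFrame:
    """Cohort as a DataFrame (person_id, index_date, label, system_id)."""
    return pd.DataFrame(
        {
            "person_id": [o.person_id for o in cohort],
            "index_date": [o.index_date for o in cohort],
            "label": [o.label for o in cohort],
            "system_id": [o.system_id for o in cohort],
        }
    )


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------

SOURCE_SETS = ("D", "E", "Tterm", "Ttfidf", "Tcon")
WINDOW_TAGS = ("365d", "30d", "NA")


@dataclass(frozen=True)
class FeatureDescriptor:
    """Provenance metadata for one feature column."""

    feature_id: str
    source_set: str
    window_tag: str
    name: str


@dataclass
class FeatureMatrix:
    """Sparse observations x features matrix with per-column provenance.

    Rows follow the order of ``observations`` (a cohort list); columns are
    described by ``descriptors``. Alignment across matrices is by
    ``feature_id``, never by column position.
    """

    observations: list[CohortObservation]
    descriptors: list[FeatureDescriptor]
    values: sp.csr_matrix

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        if self.values.shape != (len(self.observations), len(self.descriptors)):
            raise IntegrityError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.observations)} observations x "
                f"{len(self.descriptors)} descriptors"
            )
        ids = [d.feature_id for d in self.descriptors]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate feature ids: {dupes[:5]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def feature_ids(self) -> list[str]:
        return [d.feature_id for d in self.descriptors]

    def labels(self) -> np.ndarray:
        return np.array([o.label for o in self.observations], dtype=int)

    def drop_zero_columns(self) -> "FeatureMatrix":
        """Remove all-zero columns (used by event/text feature builders)."""
        col_nnz = np.asarray((self.values != 0).sum(axis=0)).ravel()
        keep = np.flatnonzero(col_nnz > 0)
        return FeatureMatrix(
            self.observations,
            [self.descriptors[i] for i in keep],
            self.values[:, keep],
        )

    def hstack(self, *others: "FeatureMatrix") -> "FeatureMatrix":
        """Column-wise concatenation; all matrices must share the row index."""
        for other in others:
            if other.observations != self.observations:
                raise IntegrityError("cannot hstack matrices over different rows")
        descriptors = list(self.descriptors)
        blocks = [self.values]
        for other in others:
            descriptors.extend(other.descriptors)
            blocks.append(other.values)
        return FeatureMatrix(self.observations, descriptors, sp.hstack(blocks).tocsr())

    def subset_rows(self, idx: np.ndarray | list[int]) -> "FeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return FeatureMatrix(
            [self.observations[i] for i in idx], self.descriptors, self.values[idx]
        )

    def project_onto(self, feature_ids: list[str],
                     descriptors: list[FeatureDescriptor] | None = None
                     ) -> "FeatureMatrix":
        """Project onto a reference feature space (for external validation).

        Columns absent here are zero-filled; columns not in ``feature_ids``
        are dropped. Output column order follows ``feature_ids``.
        """
        pos = {fid: j for j, fid in enumerate(self.feature_ids)}
        n = len(self.observations)
        cols = []
        out_desc = []
        ref_desc = {d.feature_id: d for d in (descriptors or self.descriptors)}
        for fid in feature_ids:
            if fid in pos:
                cols.append(self.values[:, pos[fid]])
                out_desc.append(self.descriptors[pos[fid]])
            else:
                cols.append(sp.csr_matrix((n, 1)))
                out_desc.append(ref_desc[fid])
        values = sp.hstack(cols).tocsr() if cols else sp.csr_matrix((n, 0))
        return FeatureMatrix(self.observations, out_desc, values)


def save_features(matrix: FeatureMatrix, path: str | Path) -> None:
    """Persist as MatrixMarket values + a JSON descriptor/row sidecar.

    ``path`` is a stem: writes ``<path>.mtx`` and ``<path>.json``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path.with_suffix(".mtx")), matrix.values)
    sidecar = {
        "observations": [
            [o.person_id, o.index_date.strftime("%Y-%m-%d"), o.label, o.system_id]
            for o in matrix.observations
        ],
        "descriptors": [
            [d.feature_id, d.source_set, d.window_tag, d.name]
            for d in matrix.descriptors
        ],
        "shape": list(matrix.values.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_features(path: str | Path) -> FeatureMatrix:
    """Inverse of :func:`save_features`; lossless for values and metadata."""
    path = Path(path)
    mtx_path = path.with_suffix(".mtx")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise IntegrityError(f"missing descriptor sidecar {sidecar_path}")
    if not mtx_path.exists():
        raise IntegrityError(f"missing value file {mtx_path}")
    sidecar = json.loads(sidecar_path.read_text())
    values = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    expected = tuple(sidecar["shape"])
    if values.shape != expected:
        raise IntegrityError(
            f"value shape {values.shape} does not match sidecar shape {expected}"
        )
    observations = [
        CohortObservation(int(p), pd.Timestamp(d), int(lbl), sys)
        for p, d, lbl, sys in sidecar["observations"]
    ]
    descriptors = [FeatureDescriptor(*row) for row in sidecar["descriptors"]]
    if values.shape[1] != len(descriptors):
        raise IntegrityError("descriptor/value dimension mismatch")
    return FeatureMatrix(observations, descriptors, values)
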