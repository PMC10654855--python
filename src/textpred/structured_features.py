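"""Demographic (D) and clinical-event (E) covariates per cohort observation.

D is two dense columns: age in completed calendar years at the index date
and a binary sex indicator (1 = male). E is one binary column per
(domain, concept code, window) triple, 1 iff at least one event with that
code falls inside the window before the index. Windows are closed day
intervals excluding the index date: the w-day window is
[index - w, index - 1]. Event features are occurrence indicators, not
counts; all-zero columns are dropped after construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import SchemaError
from .omop_io import (
    CohortObservation,
    FeatureDescriptor,
    FeatureMatrix,
)


def extract_demographics(cohort: list[CohortObservation],
                         persons: pd.DataFrame) -> FeatureMatrix:
    """Age and sex columns (source set D)."""
    info = persons.set_index("person_id")
    missing = [o.person_id for o in cohort if o.person_id not in info.index]
    if missing:
        raise SchemaError(f"cohort persons missing from person table: {missing[:5]}")
    age = np.array(
        [o.index_date.year - int(info.at[o.person_id, "year_of_birth"])
         for o in cohort], dtype=float,
    )
    sex = np.array(
        [1.0 if info.at[o.person_id, "sex"] == "M" else 0.0 for o in cohort]
    )
    values = sp.csr_matrix(np.column_stack([age, sex]))
    descriptors = [
        FeatureDescriptor("D:age", "D", "NA", "age in years at index"),
        FeatureDescriptor("D:sex_male", "D", "NA", "sex is male"),
    ]
    return FeatureMatrix(cohort, descriptors, values)


def extract_event_features(cohort: list[CohortObservation],
                           events: pd.DataFrame,
                           windows: tuple[int, ...] = (365, 30)) -> FeatureMatrix:
    """Binary event-occurrence columns (source set E).

    One column per (domain, concept_code, window); windows must be given in
    descending order (the default 365/30 pair gives nested lookbacks).
    """
    if not windows:
        raise SchemaError("windows must be non-empty")
    if list(windows) != sorted(windows, reverse=True):
        raise SchemaError("windows must be in descending order")

    n = len(cohort)
    obs_pos: dict[int, list[int]] = {}
    for i, o in enumerate(cohort):
        obs_pos.setdefault(o.person_id, []).append(i)

    cols: dict[tuple[str, str, int], set[int]] = {}
    ev = events[events["person_id"].isin(obs_pos)]
    for pid, dom, code, date in zip(
        ev["person_id"], ev["domain"], ev["concept_code"], ev["event_date"]
    ):
        for i in obs_pos[pid]:
            index = cohort[i].index_date
            delta = (index - date).days
            for w in windows:
                if 1 <= delta <= w:
                    cols.setdefault((dom, code, w), set()).add(i)

    keys = sorted(cols, key=lambda k: (k[0], k[1], -k[2]))
    rows_idx: list[int] = []
    cols_idx: list[int] = []
    for j, key in enumerate(keys):
        for i in sorted(cols[key]):
            rows_idx.append(i)
            cols_idx.append(j)
    values = sp.csr_matrix(
        (np.ones(len(rows_idx)), (rows_idx, cols_idx)), shape=(n, len(keys))
    )
    descriptors = [
        FeatureDescriptor(
            f"E:{dom}:{code}:{w}d", "E", f"{w}d",
            f"{dom} {code} in {w}d before index",
        )
        for dom, code, w in keys
    ]
    return FeatureMatrix(cohort, descriptors, values)
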