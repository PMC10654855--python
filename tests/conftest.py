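import pandas as pd
import pytest

import textpred as tp


@pytest.fixture(scope="session")
def simple_task():
    return tp.TaskSpec("toy", target_code="target", outcome_code="outcome",
                       tar_start_days=2, tar_end_days=30)


@pytest.fixture(scope="session")
def small_dataset(simple_task):
    """120-person single-system dataset with one planted text signal."""
    profile = tp.SystemProfile("A", 120, notes_per_obs_median=10,
                               words_per_note_median=10)
    signal = tp.SignalSpec(text_signal_terms=[("kanker", 1.5)],
                           event_signal_codes=[("sigcode", 1.0)],
                           baseline_log_odds=-0.5)
    return tp.generate_dataset(profile, signal, simple_task, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_dataset, simple_task):
    return tp.build_cohort(small_dataset, simple_task)


@pytest.fixture(scope="session")
def lexicon():
    return tp.load_lexicon()


@pytest.fixture(scope="session")
def context_rules():
    return tp.load_context_rules()


def make_manual_dataset(rows):
    """Build a tiny dataset from explicit per-person tuples:
    (person_id, yob, sex, period_start, period_end, events, notes) where
    events is a list of (domain, code, date) and notes of (date, text)."""
    persons, events, notes, periods = [], [], [], []
    note_id = 0
    for pid, yob, sex, start, end, evs, nts in rows:
        persons.append((pid, yob, sex))
        periods.append((pid, pd.Timestamp(start), pd.Timestamp(end)))
        for dom, code, date in evs:
            events.append((pid, dom, code, pd.Timestamp(date)))
        for date, text in nts:
            note_id += 1
            notes.append((note_id, pid, pd.Timestamp(date), "gp", text))
    return tp.EHRDataset(
        persons=pd.DataFrame(persons, columns=["person_id", "year_of_birth", "sex"]),
        events=pd.DataFrame(events, columns=["person_id", "domain",
                                             "concept_code", "event_date"]),
        notes=pd.DataFrame(notes, columns=["note_id", "person_id", "note_date",
                                           "note_class", "text"]),
        observation_periods=pd.DataFrame(
            periods, columns=["person_id", "start_date", "end_date"]),
        system_id="A",
    )
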