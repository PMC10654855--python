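"""Benchmark orchestration: feature-set combinations, subject-level
splitting, hyperparameter tuning, and the internal + external validation
grid.

Seven feature-set combinations are evaluated per task: structured
(S = D+E), three text sets (T = D+Tterm, D+Ttfidf, D+Tcon), and three
combined sets (S+T = D+E+Tterm, D+E+Ttfidf, D+E+Tcon). Demographics (D)
join every combination because they are always available. With three
learners — L1-regularized logistic regression (LR), gradient-boosted
trees (XGB), and random forests (RF) — that is 21 models per task, each
validated internally (25% held-out subjects of the larger EHR system) and
externally (all observations of the smaller system).

Vocabulary, idf, and concept feature spaces are fitted on the training
partition only and frozen; internal-test and external-system matrices are
projected onto the training feature space (novel features dropped, absent
ones zero-filled). Hyperparameters are chosen by mean subject-level
3-fold cross-validated AUROC, with ties broken toward the more
regularized / smaller model (grids are ordered accordingly). One seed
governs the split, fold assignment, and learner randomness.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MaxAbsScaler
from xgboost import XGBClassifier

from . import concept_context, evaluation, structured_features, text_features
from .exceptions import (
    ConfigurationError,
    MetricError,
    SplitError,
    TrainingError,
)
from .omop_io import (
    CohortObservation,
    EHRDataset,
    FeatureMatrix,
    TaskSpec,
    build_cohort,
)
from .synthetic_ehr import SignalSpec, SystemProfile, make_system_pair

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Feature-set combinations
# ---------------------------------------------------------------------------

COMBO_MEMBERS: dict[str, tuple[str, ...]] = {
    "S": ("D", "E"),
    "T_term": ("D", "Tterm"),
    "T_tfidf": ("D", "Ttfidf"),
    "T_con": ("D", "Tcon"),
    "ST_term": ("D", "E", "Tterm"),
    "ST_tfidf": ("D", "E", "Ttfidf"),
    "ST_con": ("D", "E", "Tcon"),
}

COMBO_FAMILY = {
    "S": "S",
    "T_term": "T", "T_tfidf": "T", "T_con": "T",
    "ST_term": "S+T", "ST_tfidf": "S+T", "ST_con": "S+T",
}

COMBO_REPRESENTATION = {
    "S": "none",
    "T_term": "term", "T_tfidf": "tfidf", "T_con": "concept",
    "ST_term": "term", "ST_tfidf": "tfidf", "ST_con": "concept",
}

ALGORITHMS = ("lr", "xgb", "rf")


def build_combos(D: FeatureMatrix, E: FeatureMatrix, Tterm: FeatureMatrix,
                 Ttfidf: FeatureMatrix, Tcon: FeatureMatrix
                 ) -> dict[str, FeatureMatrix]:
    """Column-wise concatenation of the member sets into the 7 combos."""
    members = {"D": D, "E": E, "Tterm": Tterm, "Ttfidf": Ttfidf, "Tcon": Tcon}
    return {
        combo_id: members[parts[0]].hstack(*(members[p] for p in parts[1:]))
        for combo_id, parts in COMBO_MEMBERS.items()
    }


# ---------------------------------------------------------------------------
# Subject-level splitting
# ---------------------------------------------------------------------------


def split_subject_level(observations: list[CohortObservation],
                        test_fraction: float = 0.25,
                        seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Partition observation indices so every person lands entirely in one
    side; the test side gets round(test_fraction * n_persons) persons."""
    if not 0 < test_fraction < 1:
        raise ConfigurationError("test_fraction must be in (0, 1)")
    persons = sorted({o.person_id for o in observations})
    if len(persons) < 2:
        raise SplitError("cannot split a cohort with fewer than 2 persons")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(persons))
    n_test = int(round(test_fraction * len(persons)))
    n_test = min(max(n_test, 1), len(persons) - 1)
    test_persons = {persons[i] for i in order[:n_test]}
    train_idx = np.array(
        [i for i, o in enumerate(observations) if o.person_id not in test_persons],
        dtype=int,
    )
    test_idx = np.array(
        [i for i, o in enumerate(observations) if o.person_id in test_persons],
        dtype=int,
    )
    return train_idx, test_idx


# ---------------------------------------------------------------------------
# Model specification and tuning
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """One learner with its hyperparameter grid.

    The grid is an ordered list of parameter dicts, most-regularized /
    smallest model first, which is also the tie-break order for equal
    cross-validated AUROC.
    """

    algorithm: str
    grid: list[dict] = field(default_factory=list)
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}")
        if not self.grid:
            self.grid = default_grid(self.algorithm)
        if self.cv_folds != 3:
            raise ConfigurationError("cv_folds is fixed at 3")


def default_grid(algorithm: str) -> list[dict]:
    if algorithm == "lr":
        return [{"C": c} for c in (0.001, 0.01, 0.1, 1.0, 10.0)]
    if algorithm == "xgb":
        return [
            {"max_depth": d, "n_estimators": n, "learning_rate": lr}
            for d in (2, 4, 6) for n in (50, 200) for lr in (0.05, 0.2)
        ]
    if algorithm == "rf":
        return [{"n_estimators": 200, "max_features": mf}
                for mf in ("sqrt", 0.3)]
    raise ConfigurationError(f"unknown algorithm {algorithm!r}")


def default_model_specs(seed: int = 0,
                        algorithms: tuple[str, ...] = ALGORITHMS,
                        grids: dict[str, list[dict]] | None = None
                        ) -> list[ModelSpec]:
    grids = grids or {}
    return [ModelSpec(a, grid=list(grids.get(a, [])), seed=seed)
            for a in algorithms]


def _make_estimator(spec: ModelSpec, params: dict):
    if spec.algorithm == "lr":
        return Pipeline([
            ("scale", MaxAbsScaler()),
            ("clf", LogisticRegression(
                l1_ratio=1.0, solver="liblinear", max_iter=2000,
                random_state=spec.seed, **params)),
        ])
    if spec.algorithm == "xgb":
        return XGBClassifier(
            objective="binary:logistic", tree_method="hist", n_jobs=1,
            random_state=spec.seed, eval_metric="logloss", verbosity=0,
            **params)
    return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **params)


@dataclass
class TrainedModel:
    """A fitted learner plus everything needed to score new data."""

    spec: ModelSpec
    estimator: object
    best_params: dict
    cv_scores: list[float]
    feature_ids: list[str]
    descriptors: list
    task_id: str = ""
    combo_id: str = ""

    @property
    def algorithm(self) -> str:
        return self.spec.algorithm

    def predict(self, matrix: FeatureMatrix) -> np.ndarray:
        """Probabilities for a matrix aligned by feature_id (novel columns
        dropped, missing ones zero-filled)."""
        aligned = matrix.project_onto(self.feature_ids, self.descriptors)
        return self.estimator.predict_proba(aligned.values)[:, 1]


def tune_and_train(matrix: FeatureMatrix, labels: np.ndarray,
                   spec: ModelSpec) -> TrainedModel:
    """Grid search by mean subject-level 3-fold cross-validated AUROC,
    then refit the winner on all training data."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise TrainingError("training labels contain a single class")
    groups = np.array([o.person_id for o in matrix.observations])
    X = matrix.values
    n_splits = min(spec.cv_folds, len(np.unique(groups)))
    folds = list(GroupKFold(n_splits=n_splits).split(X, labels, groups))

    mean_scores = []
    for params in spec.grid:
        fold_scores = []
        for tr, va in folds:
            if len(np.unique(labels[tr])) < 2 or len(np.unique(labels[va])) < 2:
                fold_scores.append(np.nan)
                continue
            est = _make_estimator(spec, params)
            est.fit(X[tr], labels[tr])
            p = est.predict_proba(X[va])[:, 1]
            fold_scores.append(evaluation.auroc(labels[va], p))
        with np.errstate(invalid="ignore"):
            mean_scores.append(float(np.nanmean(fold_scores))
                               if not all(np.isnan(fold_scores)) else np.nan)

    scores = np.array(mean_scores)
    if np.all(np.isnan(scores)):
        best = 0  # degenerate folds: fall back to the most regularized model
    else:
        best = int(np.nanargmax(np.where(np.isnan(scores), -np.inf, scores)))
    best_params = spec.grid[best]
    estimator = _make_estimator(spec, best_params)
    estimator.fit(X, labels)
    return TrainedModel(
        spec=spec,
        estimator=estimator,
        best_params=dict(best_params),
        cv_scores=[float(s) for s in scores],
        feature_ids=matrix.feature_ids,
        descriptors=list(matrix.descriptors),
    )


# ---------------------------------------------------------------------------
# Per-task feature assembly with train-only fitting
# ---------------------------------------------------------------------------


@dataclass
class TaskData:
    """Inputs for one task: the task spec and its two system datasets."""

    task: TaskSpec
    dataset_a: EHRDataset
    dataset_b: EHRDataset


def _assemble_features(cohort, dataset, lexicon, rules, config=None,
                       e_space=None, tcon_vocab=None):
    """Build the five member matrices for one cohort partition.

    With ``config``/``e_space``/``tcon_vocab`` given, matrices are
    projected onto that fitted training feature space instead of refit.
    """
    D = structured_features.extract_demographics(cohort, dataset.persons)
    E = structured_features.extract_event_features(cohort, dataset.events)
    docs = text_features.build_documents(cohort, dataset.notes)
    if config is None:
        config = text_features.fit_vocabulary(docs)
    if e_space is not None:
        E = E.project_onto([d.feature_id for d in e_space], e_space)
    Tterm = text_features.vectorize_binary(docs, config)
    Ttfidf = text_features.vectorize_tfidf(docs, config)
    Tcon = concept_context.concept_features(
        cohort, dataset.notes, lexicon, rules, vocabulary=tcon_vocab
    )
    return {"D": D, "E": E, "Tterm": Tterm, "Ttfidf": Ttfidf, "Tcon": Tcon,
            "config": config}


def run_task(task_data: TaskData, seed: int,
             algorithms: tuple[str, ...] = ALGORITHMS,
             grids: dict[str, list[dict]] | None = None,
             test_fraction: float = 0.25,
             lexicon=None, rules=None):
    """Train and validate all combo x algorithm cells for one task.

    The system with more qualifying observations provides the train /
    internal-test split; the other system is used entirely for external
    validation. Returns (records DataFrame, predictions DataFrame, models).
    """
    lexicon = lexicon or concept_context.load_lexicon()
    rules = rules if rules is not None else concept_context.load_context_rules()
    task = task_data.task
    t0 = time.perf_counter()

    cohort_a = build_cohort(task_data.dataset_a, task)
    cohort_b = build_cohort(task_data.dataset_b, task)
    if len(cohort_a) >= len(cohort_b):
        ds_int, cohort_int = task_data.dataset_a, cohort_a
        ds_ext, cohort_ext = task_data.dataset_b, cohort_b
    else:
        ds_int, cohort_int = task_data.dataset_b, cohort_b
        ds_ext, cohort_ext = task_data.dataset_a, cohort_a

    train_idx, test_idx = split_subject_level(cohort_int, test_fraction, seed)
    cohort_train = [cohort_int[i] for i in train_idx]
    cohort_test = [cohort_int[i] for i in test_idx]

    train_sets = _assemble_features(cohort_train, ds_int, lexicon, rules)
    config = train_sets.pop("config")
    config.fingerprint = {"seed": seed, "task": task.task_id,
                          "train_system": ds_int.system_id,
                          "n_documents": config.n_fit}
    tcon_vocab = [d.feature_id.split(":", 1)[1]
                  for d in train_sets["Tcon"].descriptors]
    e_space = train_sets["E"].descriptors
    test_sets = _assemble_features(cohort_test, ds_int, lexicon, rules,
                                   config=config, e_space=e_space,
                                   tcon_vocab=tcon_vocab)
    test_sets.pop("config")
    ext_sets = _assemble_features(cohort_ext, ds_ext, lexicon, rules,
                                  config=config, e_space=e_space,
                                  tcon_vocab=tcon_vocab)
    ext_sets.pop("config")

    combos_train = build_combos(**train_sets)
    combos_test = build_combos(**test_sets)
    combos_ext = build_combos(**ext_sets)

    y_train = np.array([o.label for o in cohort_train])
    specs = default_model_specs(seed=seed, algorithms=algorithms, grids=grids)
    log.info("task %s: features built in %.1fs (train=%d test=%d external=%d)",
             task.task_id, time.perf_counter() - t0,
             len(cohort_train), len(cohort_test), len(cohort_ext))

    records, predictions, models = [], [], {}
    for combo_id, X_train in combos_train.items():
        for spec in specs:
            t1 = time.perf_counter()
            model = tune_and_train(X_train, y_train, spec)
            model.task_id = task.task_id
            model.combo_id = combo_id
            models[(task.task_id, combo_id, spec.algorithm)] = model
            log.debug("task %s %s/%s tuned in %.1fs (best %s)",
                      task.task_id, combo_id, spec.algorithm,
                      time.perf_counter() - t1, model.best_params)
            for vtype, cohort_v, X_v in (
                ("internal", cohort_test, combos_test[combo_id]),
                ("external", cohort_ext, combos_ext[combo_id]),
            ):
                y_v = np.array([o.label for o in cohort_v])
                p_v = model.predict(X_v)
                try:
                    rec = evaluation.compute_metrics(y_v, p_v)
                except MetricError:
                    log.warning(
                        "task %s %s/%s %s: single-class validation labels, "
                        "metrics undefined", task.task_id, combo_id,
                        spec.algorithm, vtype)
                    rec = {k: float("nan") for k in
                           ("auroc", "auprc", "brier", "precision",
                            "recall", "f1", "threshold")}
                records.append({
                    "task": task.task_id, "combo": combo_id,
                    "family": COMBO_FAMILY[combo_id],
                    "representation": COMBO_REPRESENTATION[combo_id],
                    "algorithm": spec.algorithm, "validation_type": vtype,
                    "seed": seed, "n": len(y_v),
                    "n_outcomes": int(y_v.sum()), **rec,
                })
                for obs, y, p in zip(cohort_v, y_v, p_v):
                    predictions.append({
                        "task": task.task_id, "combo": combo_id,
                        "family": COMBO_FAMILY[combo_id],
                        "representation": COMBO_REPRESENTATION[combo_id],
                        "algorithm": spec.algorithm,
                        "validation_type": vtype,
                        "person_id": obs.person_id,
                        "index_date": obs.index_date.strftime("%Y-%m-%d"),
                        "system_id": obs.system_id, "seed": seed,
                        "label": int(y), "probability": float(p),
                    })
    return pd.DataFrame(records), pd.DataFrame(predictions), models


def run_grid(task_datas: list[TaskData], seed: int,
             algorithms: tuple[str, ...] = ALGORITHMS,
             grids: dict[str, list[dict]] | None = None,
             lexicon=None, rules=None):
    """The full benchmark over all tasks (21 models per task with the
    default three algorithms; 84 for four tasks)."""
    all_records, all_preds, all_models = [], [], {}
    for td in task_datas:
        rec, pred, models = run_task(
            td, seed=seed, algorithms=algorithms, grids=grids,
            lexicon=lexicon, rules=rules,
        )
        all_records.append(rec)
        all_preds.append(pred)
        all_models.update(models)
    return (
        pd.concat(all_records, ignore_index=True),
        pd.concat(all_preds, ignore_index=True),
        all_models,
    )


# ---------------------------------------------------------------------------
# Default synthetic benchmark conditions
# ---------------------------------------------------------------------------

# Outcome prevalences and note/event scales follow the published GP-cohort
# ranges (outcome-to-observation ratios 0.04-0.46; tens of notes and a few
# hundred words per 365-day observation). Planted signal terms are lexicon
# concepts so every text representation can recover them.


def default_task_setups(n_patients_a: int = 400, n_patients_b: int = 250
                        ) -> list[dict]:
    """The four benchmark prediction problems with their planted signals."""
    shared = dict(notes_per_obs_median=28, words_per_note_median=12)
    shifted = dict(notes_per_obs_median=36, words_per_note_median=14,
                   vocab_shift=0.3)
    setups = [
        dict(
            task=TaskSpec("readmission", target_code="discharge",
                          outcome_code="readmit", tar_start_days=2,
                          tar_end_days=30, min_age=18,
                          multiple_obs_per_patient=True),
            signal=SignalSpec(
                text_signal_terms=[("tumor", 1.2), ("benauwd", 1.0)],
                event_signal_codes=[("cond_sig_readm", 1.2)],
                baseline_log_odds=-3.2, noise_sd=0.5),
            n_scale=1.0,
        ),
        dict(
            task=TaskSpec("end_of_life", target_code="gp_visit",
                          outcome_code="eol_conversation", tar_start_days=1,
                          tar_end_days=365, min_age=60),
            signal=SignalSpec(
                text_signal_terms=[("kanker", 1.5), ("palliatief", 1.5)],
                event_signal_codes=[("cond_sig_eol", 1.2)],
                baseline_log_odds=-3.9, noise_sd=0.5),
            n_scale=2.0,  # the 60+ age rule halves the qualifying population
        ),
        dict(
            task=TaskSpec("asthma_exacerbation", target_code="asthma_rx",
                          outcome_code="exacerbation", tar_start_days=1,
                          tar_end_days=730, min_age=18),
            signal=SignalSpec(
                text_signal_terms=[("prednison", 1.2), ("hoest", 0.8)],
                event_signal_codes=[("cond_sig_asthma", 1.0)],
                baseline_log_odds=-1.4, noise_sd=0.5),
            n_scale=1.0,
        ),
        dict(
            task=TaskSpec("copd_mortality", target_code="copd_dx",
                          outcome_code="death", tar_start_days=1,
                          tar_end_days=730, min_age=40),
            signal=SignalSpec(
                text_signal_terms=[("gemetastaseerd", 1.5), ("moeheid", 0.8)],
                event_signal_codes=[("cond_sig_copd", 1.2)],
                baseline_log_odds=-3.0, noise_sd=0.5),
            n_scale=1.0,
        ),
    ]
    for s in setups:
        scale = s.pop("n_scale")
        s["profile_a"] = SystemProfile(
            "A", max(2, int(round(scale * n_patients_a))), **shared)
        s["profile_b"] = SystemProfile(
            "B", max(2, int(round(scale * n_patients_b))), **shifted)
    return setups


def signal_recovery_study(base_seed: int = 0, n_seeds: int = 10,
                          text_only: bool = True, n_patients_a: int = 300,
                          n_patients_b: int = 180,
                          algorithms: tuple[str, ...] = ("lr",),
                          grids: dict | None = None):
    """Repeated-seed study of planted-signal recovery.

    With ``text_only`` the outcome depends on planted note terms alone, so
    text models should beat structured models; otherwise both structured
    and text signals are planted, and the combined models should match or
    beat the best single-source family. Returns (records over all seeds,
    fraction of seeds where the strongest planted term ranks in the LR
    top-5 features of the binary bag-of-words model).
    """
    planted = [("kanker", 2.0), ("benauwd", 1.5), ("palliatief", 1.5)]
    task = TaskSpec("signal_recovery", target_code="visit",
                    outcome_code="outcome", tar_start_days=1,
                    tar_end_days=180)
    signal = SignalSpec(
        text_signal_terms=planted,
        event_signal_codes=[] if text_only else
        [("cond_sig_a", 2.0), ("cond_sig_b", 1.5)],
        baseline_log_odds=-1.8, noise_sd=0.3,
    )
    if grids is None:
        grids = {"lr": [{"C": 0.1}, {"C": 1.0}]}
    profile_a = SystemProfile("A", n_patients_a, notes_per_obs_median=15,
                              words_per_note_median=10)
    profile_b = SystemProfile("B", n_patients_b, notes_per_obs_median=15,
                              words_per_note_median=10, vocab_shift=0.3)

    all_records = []
    top5_hits = 0
    for k in range(n_seeds):
        seed = base_seed + k
        ds_a, ds_b = make_system_pair(profile_a, profile_b, signal, task,
                                      seed=seed)
        records, _, models = run_task(
            TaskData(task, ds_a, ds_b), seed=seed, algorithms=algorithms,
            grids=grids,
        )
        records["study_seed"] = seed
        all_records.append(records)
        lr_term = models[(task.task_id, "T_term", "lr")]
        top5 = evaluation.feature_importance(lr_term, k=5)
        if "Tterm:kanker" in set(top5["feature_id"]):
            top5_hits += 1
    return pd.concat(all_records, ignore_index=True), top5_hits / n_seeds


def generate_benchmark(seed: int, n_patients_a: int = 400,
                       n_patients_b: int = 250) -> list[TaskData]:
    """Generate the two-system datasets for all four default tasks."""
    out = []
    for k, setup in enumerate(default_task_setups(n_patients_a, n_patients_b)):
        ds_a, ds_b = make_system_pair(
            setup["profile_a"], setup["profile_b"], setup["signal"],
            setup["task"], seed + 1000 * (k + 1),
        )
        out.append(TaskData(setup["task"], ds_a, ds_b))
    return out
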