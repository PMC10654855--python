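# Methods

## Problem setting

`textpred` studies prognostic patient-level prediction on GP EHR data:
given a target cohort of (person, index date) observations, predict from
covariates measured in a 365-day observation window before the index
whether the outcome occurs in a time-at-risk (TAR) window after it. The
question of interest is comparative — how models built from structured
codes, from free-text notes, and from both together differ in
discrimination, calibration, transportability across EHR systems, and in
which patients they flag.

## Data model and cohort logic

Tables follow a simplified OMOP-CDM shape: persons (year of birth, sex),
a long event table over four domains (condition, drug, measurement,
procedure) with opaque string codes, a note table (date, class, text),
and observation periods. All windows are closed intervals in whole days.
"365 days prior to the index" means `[index-365, index-1]`: the index
date itself never contributes covariates, so same-day outcome recording
cannot leak into the features. The TAR is
`[index + tar_start, index + tar_end]`, also closed.

An observation qualifies iff a single observation period covers
`[index-365, index+tar_end]` — this enforces both the prior-observation
requirement and no loss to follow-up within the TAR. Tasks keep one
(the earliest) observation per person unless they are readmission-style
(`multiple_obs_per_patient`), in which case every qualifying index event
is an observation. The label is 1 iff an outcome-coded event falls in the
TAR. Cohort construction is vectorized but contract-tested against an
exhaustive (person, date) enumeration.

## Feature sets

- **D**: age in completed calendar years (single numeric column, not
  binned — a config-free minimal encoding; binning can be emulated
  upstream) and a male indicator. D joins every feature combination
  because demographics are always recorded.
- **E**: one binary column per (domain, code, window) for windows of 365
  and 30 days; occurrence, not counts. All-zero columns never arise
  (columns exist only where events do). 30-day columns are logically
  nested in their 365-day counterparts.
- **Tterm / Ttfidf**: all notes of the 365-day window are concatenated
  into one document per observation. Preprocessing replaces every digit,
  newline, and underscore with a space; tokenization lowercases and
  splits at spaces and punctuation. Terms appearing in more than 80% or
  fewer than 0.1% of training documents are pruned; both boundaries read
  strictly, so df = 0.8N is kept. TF-IDF is the textbook
  `tf · ln(N/df)` with raw counts, natural log, no smoothing and no
  length normalization; the form is recorded in the serialized pipeline
  config so variants remain switchable. Text features use the 365-day
  window only; a 30-day text window can be enabled via the
  `window_days` argument but is off by default, since note text is
  cumulative narrative rather than dated point events.
- **Tcon**: dictionary-based concept extraction over raw note text
  (digits preserved). Sentences split at newlines — GP notes are
  line-oriented shorthand with median sentence length around five words —
  and at terminal punctuation. Lexicon terms match case-insensitively as
  contiguous token sequences, leftmost-longest, non-overlapping (the
  standard dictionary-NER convention). Contextual modifiers follow the
  classic ConText design: trigger phrases carry a category (negated,
  hypothetical, historical, experiencer_other) and a direction; the scope
  runs from the trigger toward the sentence boundary, truncated at the
  first scope terminator and at 10 tokens; a mention whose span
  intersects the scope is flagged, and categories accumulate. Trigger or
  terminator occurrences overlapping a concept span are ignored (the
  concept wins). The bundled Dutch lexicon (49 surface terms, 38
  concepts) and trigger table (44 rules across 4 categories plus
  terminators) are small, user-replaceable stand-ins for licensed
  clinical vocabularies. Tcon keeps a concept iff some mention is not
  negated, not hypothetical, and not about another person; historical
  mentions count as present, because a history of a condition is
  prognostically informative. The dropped categories are configurable
  (`drop_flags`), as the right semantics are debatable.

Vocabulary, idf, document frequencies, and the concept feature space are
fitted on the training partition only and frozen. Internal-test and
external-system data are projected onto the training feature space:
novel features are dropped, absent ones zero-filled, alignment is by
feature id, never by column position. This defines external-validation
transfer and prevents information leakage from evaluation data into the
representation.

## Experimental design

Per task, the two system datasets are ranked by qualifying-observation
count; the larger provides a 75/25 subject-level train/test split (all
observations of a person land on one side), the smaller is used entirely
for external validation. Seven combinations (S = D+E; T = D+Tterm,
D+Ttfidf, D+Tcon; S+T = D+E+Tterm, D+E+Ttfidf, D+E+Tcon) × three
learners = 21 models per task, 84 over the four default tasks, each
yielding one internal and one external evaluation record.

Learners and default grids (conventional desk-scale grids, fully
config-overridable):

| learner | grid |
|---|---|
| L1 logistic regression (liblinear, max-abs feature scaling) | C ∈ {0.001, 0.01, 0.1, 1, 10} |
| gradient-boosted trees | depth {2, 4, 6} × trees {50, 200} × learning rate {0.05, 0.2} |
| random forest | 200 trees × max features {sqrt, 0.3} |

Hyperparameters are selected by mean 3-fold cross-validated AUROC with
subject-level folds (consistent with the outer split); ties break toward
the more regularized / smaller model, implemented by grid order. One
seed governs the split, the folds, and learner randomness. Folds whose
training or validation part is single-class score NaN and are skipped in
the mean; if every grid point is NaN the most regularized model is used.

## Evaluation

AUROC is the rank (Mann–Whitney) statistic with tie correction; AUPRC is
the area under the precision-recall step function (average precision,
not trapezoidal); Brier is the mean squared probability error.
Precision, recall, and F1 are reported at the threshold maximizing F1
over an exhaustive scan of the unique predicted probabilities (rule:
positive iff p ≥ threshold; among ties the smallest threshold).

Family comparisons (S vs T vs S+T per task and validation type) use
two-sided unpaired Wilcoxon rank-sum tests: exact enumeration when both
groups have ≤ 10 tie-free values, otherwise the normal approximation
with tie correction. The Bonferroni family is the set of family pairs
tested within one (task, validation type, metric) analysis — three
pairs, so the adjustment factor is 3. Median-centering subtracts the
per-(task, validation type, family) median so representation and
algorithm effects are comparable across groups.

Predictive multiplicity between two model families is the Pearson
correlation of predicted probabilities over the shared observation set,
computed per representation × algorithm cell and averaged within each
(task, pair, validation type); the qualitative bands are r > .8 very
strong, .6–.8 strong, .4–.6 moderate. Feature importance is signed
coefficients for the logistic model (exact zeros dropped), mean decrease
in impurity for random forests, and average split gain for boosting,
always carrying the source-set provenance of each feature.

## Synthetic data generator

The generator emulates the marginal statistics of Dutch GP populations
recorded under different EHR systems — tens of short notes and a few
hundred words per 365-day observation, a handful of coded events per
domain, outcome-to-observation ratios between 0.04 and 0.46 — without
claiming linguistic realism. Notes are bags of tokens drawn from a fixed
Zipfian background vocabulary of 2000 Dutch-like syllabic tokens
(exponent 1.1), arranged into ~5-word shorthand lines with occasional
digits and punctuation so that preprocessing and sentence splitting have
real work. The bundled lexicon terms and a handful of context-trigger
words are woven into the background vocabulary at mid ranks, so concept
extraction yields tens of mentions per observation and negation/context
detection fires on natural collocations.

Outcomes follow a logistic model: per signal (a note term or an event
code) each person is independently exposed with probability 0.3; the
log-odds are the baseline plus the exposed weights plus optional
Gaussian noise. Exposed terms are written into covariate-window notes as
their own lines; exposed codes become condition events in the window.
Positive labels plant an outcome event inside the TAR (when follow-up
allows); 5% of the remaining persons get a decoy outcome event outside
the TAR. Observation periods are constructed so that ~10% of persons
violate the 365-day prior-observation rule and ~10% leave mid-TAR,
keeping the exclusion logic permanently exercised. Every person carries
a target event at the index date; readmission-style tasks give 15% of
persons a second index event 35–120 days later.

Cross-system shift has two components: different profile medians (note
count, note length, event density) and renaming a fraction
(`vocab_shift`) of background tokens to spelling variants. Planted
signal terms, lexicon terms, and trigger words are exempt from renaming
— mirroring clinically salient words that are spelled consistently
across systems — so external validation degrades through the background
vocabulary, not by destroying the signal or the concept dictionary.

What the generator does **not** emulate: grammar and word order (so
nothing can be concluded about parsing-dependent NLP), longitudinal
disease trajectories, correlated code/term co-occurrence structure,
typos and abbreviation noise, or realistic calibration drift between
systems. Passing tests therefore demonstrate the correctness and
leakage-freedom of the machinery and the recoverability of planted
signals, not clinical performance on real data.

## Default benchmark conditions and problem sizes

The four default tasks mirror common GP prediction problems: hospital
readmission (TAR 2–30 days, multiple observations per person),
end-of-life conversation (TAR 1–365 days, age ≥ 60; double population
size since the age rule halves the qualifying fraction), asthma
exacerbation and COPD mortality (TAR 1–730 days). Baseline log-odds are
set so outcome prevalences land near the 0.04–0.46 range spanned by the
real tasks; each task plants two note terms and one condition code with
log-odds weights 0.8–1.5.

Populations default to 400 persons in system A and 250 in system B
(scaled for desk-scale runs; the grid over all four tasks completes in a
few minutes on one CPU). At this scale the per-cell AUROC estimates are
deliberately noisy — internal test sets hold only a few dozen positives
— so conclusions should be drawn from family medians and repeated-seed
studies, as the signal-recovery analysis does (10 seeds, medians over
families). The 10-seed studies use 300/180-person systems, 15 notes ×
10 words per observation, and planted text weights of 1.5–2.0.

## Numerical conventions and edge cases

- Document-frequency boundaries use a relative tolerance of 1e-9 so
  df = max_df·N survives floating-point rounding.
- Empty documents are kept (all-zero rows); an empty corpus or a
  vocabulary-less config raises a fit error.
- Single-class label vectors make metrics undefined: `compute_metrics`
  raises, while the grid runner records NaN metrics with a warning (tiny
  external cohorts can be single-class by chance).
- Pearson r is NaN for constant prediction vectors; such cells are
  dropped from multiplicity averages.
- Serialized pipeline configs carry a SHA-256 checksum of the vocabulary
  and df table; a mismatch on load warns but does not fail, since users
  may edit vocabularies deliberately.
- Determinism: generation, splitting, fold assignment, and learners are
  driven by explicit seeds; identical seeds give byte-identical CSV/MTX
  outputs and identical predictions (single-threaded learners).

## Known limitations

- The bundled lexicon and trigger table are deliberately tiny; absolute
  Tcon coverage is far below what licensed vocabularies would give.
- Sentence splitting is rule-based (newlines + terminal punctuation);
  abbreviations with periods can over-split.
- TF-IDF has no sublinear tf or length normalization by design; long
  documents weigh more.
- The generator's independence assumptions (independent exposures,
  conditionally independent tokens) make planted signals easier to
  recover than correlated real-world predictors.
- External validation shares the code space for structured events across
  systems; real cross-system coding practice differs more radically.
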