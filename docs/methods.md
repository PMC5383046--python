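# Methods

This note documents the models and procedures implemented in `triagenlp`,
the choices made where the design was genuinely open, and what the bundled
synthetic cohort does and does not establish.

## Outcome and cohort

One record is one ED visit: demographics (age, gender), triage vitals
(temperature, heart rate, respiratory rate, oxygen saturation, systolic and
diastolic blood pressure, pain score), a 5-level acuity (ESI, 1 = most
urgent), two free-text fields (chief complaint; nursing assessment), and
optionally a list of ICD-9-CM discharge codes and/or a binary infection
label. When only codes are present, the label is derived by membership in
a user-supplied abstraction list (`label_infection`): entries are exact
codes or `*`-suffixed prefixes, compared after removing dots. The
abstraction list itself is an input, not part of the package.

Visits are partitioned once into fixed train (64%), validate (20%), and
test (16%) sets by a seeded uniform draw with largest-remainder rounding,
so the subset sizes are exactly the rounded fractions and the partition is
exhaustive for any n.

## Text processing

1. **Tokenization.** Case-folded (configurable); whitespace-delimited;
   leading and trailing punctuation characters become separate tokens;
   interior punctuation is preserved so clinical shorthand (`s/p`, `h/a`,
   `n&v`) survives intact. Total function — any string tokenizes.
2. **Collocations.** Adjacent word pairs with corpus count ≥ 5 and
   pointwise mutual information ≥ 3.0 bits (both configurable) are joined
   into a single token by an underscore. A fixed user-supplied pair list is
   also accepted. Joining scans left to right and consumes greedily, so of
   two overlapping listed pairs the leftmost wins.
3. **Negation.** Trigger words (`no`, `not`, `denies`, `denied`,
   `without`, `neg`, `w/o`) open a scope; every in-scope token — including
   punctuation tokens such as a comma — receives the `_neg` suffix until a
   terminator word (`but`, `however`, `except`, `although`), a
   sentence-ending `.`/`;`/`:`, or 6 tokens, whichever comes first. The
   trigger itself is dropped from the output. The operation is idempotent
   (no `_neg_neg`), and negation runs after collocation joining so a joined
   term is negated as one token (`no chest pain` → `chest-pain_neg` with a
   hyphen joiner configured).

The 6-token scope cap is the conventional NegEx bound and prevents runaway
scopes in unpunctuated notes; the lexicons above are deliberately small
defaults and are expected to be extended per site.

## Vitals block

Each continuous field has a physiologic range and a normal value
(configurable via a YAML table):

| field | range | normal |
|---|---|---|
| age (years) | 0–120 | 60 (defensive only; age is essentially never missing) |
| temperature (°F) | 80–110 | 98.0 |
| heart rate (bpm) | 20–400 | 80 |
| respiratory rate (bpm) | 4–80 | 16 |
| SpO₂ (%) | 50–100 | 99 |
| systolic BP (mm Hg) | 40–300 | 120 |
| diastolic BP (mm Hg) | 20–200 | 70 |
| pain (0–10) | 0–10 | 0 |

Parsing takes the leading decimal number of the raw string ("101.9
rectally" → 101.9); anything missing, unparseable, or out of range is
replaced by the normal value with **no** imputation indicator; the result
is min–max scaled onto [0,1] over the physiologic range. Gender is a 0/1
indicator (male = 1, an arbitrary documented coding) and acuity becomes
five indicator columns — the most general encoding of a 5-level ordinal
for a linear model — with missing or unparseable acuity assigned the modal
level 3. The composite map is total: every record yields a vector, and no
record is ever dropped.

## Text features

The vocabulary keeps every token with corpus count ≥ 5, ordered
lexicographically. By default it is fitted on the training split only;
`paper_faithful=True` fits on the whole dataset, which reproduces the
original protocol but leaks evaluation-split counts into the feature
definition (`check_no_leakage` verifies the default). Term frequencies are
raw counts. For the `bow` and `topics` models the two text fields are
concatenated per visit; for `cc` only the chief complaint is counted.

Topics come from LDA fitted by collapsed Gibbs sampling (token-level
resampling of topic assignments from the exact conditional). The class
defaults are symmetric priors α = 50/K, β = 0.01 and 1000 sweeps; held-out
documents are folded in with topic–word counts frozen, and the
document–topic distribution is averaged over post-burn-in sweeps.
Proportions below 0.001 are zeroed and **not** renormalized. The pipeline
runs K = 24 topics, 150 fitting sweeps, 200 inference sweeps (100
burn-in), and a sharper α = 0.5: triage notes are 15–30 tokens, and with
α = 50/K the prior mass (≈ 2 pseudo-tokens per topic) would swamp the
~25 observed tokens and flatten every document's θ toward uniform. K and
all priors are configurable; the K = 500 regime the method was designed
around is reachable by config on a correspondingly larger corpus.

The sampler's inner loops are numba-compiled and use a seeded generator
inside the kernel, so all topic-model outputs are exactly reproducible.

## Classifier

The primary learner minimizes the pairwise hinge bound on 1 − AUC:

J(w) = ½‖w‖² + (C/|P||N|) · Σ_{i∈P, j∈N} max(0, 1 − (w·x_i − w·x_j)).

No intercept is fitted (AUC is shift-invariant). The optimizer is Adam on
subsampled-pair subgradients: 200,000 positive×negative pairs are drawn
per epoch (all pairs, deterministically, when there are fewer), for 150
epochs with step size decaying as 1/√epoch and a Polyak average over the
final quarter of the epochs. Because the optimum's norm grows with C —
weakly separated data needs large weights to push pair margins past 1 —
the base step is scaled by √C; without this the optimizer cannot reach the
optimum at large C within the epoch budget. In full-batch mode the exact
objective is tracked per epoch and the best iterate is returned, which
makes the procedure a plain batch subgradient method whose final objective
is checked in the tests against an independent exact solver (an ordinary
hinge SVM over pairwise difference vectors — the two problems are
algebraically identical after rescaling C).

C is selected on the validation split from the grid 10⁻³…10³ (decade
steps); ties break toward the smaller C (stronger regularization).
Baselines: L2 logistic regression with classes reweighted inversely to
prevalence, Bernoulli naïve Bayes, and random forests (grid over minimum
samples per leaf), all via scikit-learn.

**Calibration.** Platt scaling — a one-feature logistic regression with
bias on the decision value — is fitted on the validation split and applied
to test scores, avoiding training-score optimism. The regularization is
effectively disabled (C = 10⁸) so the fit matches an unpenalized IRLS
solution.

## Evaluation

* **AUC** in Mann–Whitney form (ties ½), identical to trapezoidal ROC
  integration; **95% CI** by the DeLong placement-value variance with a
  normal interval truncated to [0,1] (a stratified bootstrap serves as
  cross-check in the tests).
* **Operating point**: the threshold over all distinct scores maximizing
  Youden's J with "predict positive at score ≥ t"; ties resolve to the
  lowest threshold (favoring sensitivity). By default the threshold is
  chosen on the validation split and applied to train/test reports;
  `paper_faithful` re-optimizes per split.
* **Calibration**: deciles [0,0.1), …, [0.9,1.0] of predicted
  probability; per bin the observed infected fraction with a 95% Wilson
  interval (chosen over normal approximation for small-bin behavior);
  empty bins report count 0 and undefined fraction.
* **Subgroups**: sensitivity restricted to labeled positives of each mask
  (admitted / not admitted / ICU from the synthetic flags, or arbitrary
  user masks); subgroups with no positives report NaN rather than error.
* **Introspection**: `top_weights` lists the k most positive and most
  negative features of a linear model; topic features can be rendered by
  their most frequent words.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
with defaults frozen as the package's study conditions:

* prevalence 0.14; per-field missingness: acuity 2.7%, SBP 4.9%, DBP 5.2%,
  HR 4.6%, pain 6.6%, RR 6.5%, SpO₂ 5.6%, temperature 6.7%, nursing note
  2.9% (empty);
* vitals Gaussian per outcome group, truncated to plausible support, with
  group means matching the emulated cohort (e.g. temperature 97.7 vs
  98.1 °F, heart rate 84.3 vs 88.4 bpm); the standard deviations are not
  published and are field-realistic choices. The resulting vitals-only
  separation is weak by construction (optimal AUC ≈ 0.70);
* notes of 15–30 tokens (chief complaints 2–5) drawn from weighted
  infection-indicative and background vocabularies. A nursing-note token
  is infection-lexicon with probability 0.12 for infected visits vs 0.04
  for uninfected; chief complaints are denser (0.35 vs 0.03), reflecting
  that the chief complaint distils the visit reason — this is what makes
  even the short `cc` model a large gain over vitals while `bow` adds
  more;
* negated infection phrases (`no fever`, `denies chills`) inserted in 15%
  of notes, misspelling variants (`abcess`, `pnemonia`) substituted for
  10% of eligible words, typo-style out-of-range vitals at 1% and
  alphanumeric suffixes ("… rectally") at 0.5% per field;
* optional ICD-9-CM code lists consistent with the label, and
  admitted/ICU flags with infected visits admitted more often (50.9% vs
  30.0%).

Identical config and seed give byte-identical output.

**What passing tests do and do not show.** The generator's notes are bags
of weighted words with inserted negation phrases; they have no grammar,
no co-reference, no section structure, and a vocabulary of dozens rather
than the >15,000 words of a real corpus. Tests on this cohort establish
that the pipeline's machinery is correct (preprocessing rules, counting,
optimization, metric computation, leakage hygiene) and that the
qualitative conclusion — free text dominates vitals for this outcome — is
recovered when the data has that structure. They do not establish
real-world discrimination levels, calibration transportability, or
robustness to documentation practices, none of which can be learned from
synthetic text.

## Numerical choices and degenerate inputs

* Split fractions must sum to 1 within 1e-9; visit ids must be unique.
* AUC/Youden/CI raise on single-class inputs; subgroup sensitivity
  reports NaN instead (a subgroup legitimately may contain no positives).
* Topic-word rows sum to 1 within 1e-8; K = 1 degenerates to the smoothed
  corpus unigram distribution; an empty document gets the uniform prior
  proportions before thresholding.
* All stochastic stages (generation, split, pair subsampling, Gibbs
  sampling) draw from per-stage seeds derived from one global seed by
  fixed offsets, so any stage can be replayed in isolation and a rerun
  with the same config reproduces every artifact.
* Pipeline problem sizes (20,000 visits, K = 24, 150/200 sweeps, 150 SVM
  epochs) are the package's default study scale, chosen so a full
  four-model run completes in well under a minute on one CPU while every
  estimate above is stable to the third decimal across seeds.

## Known limitations

* The negation detector has no pre-scope triggers ("pain denied") and no
  uncertainty handling ("possible uti").
* Spelling normalization and synonym mapping are deliberately absent: the
  learner is expected to pick up the predictive value of variants itself,
  and the weight tables confirm it does on the synthetic cohort.
* The pairwise-hinge optimizer is first-order; at extreme C (≫10³) or with
  unscaled features its epoch budget may leave the objective short of the
  optimum. The validation-AUC model selection makes this harmless in the
  pipeline, but the objective-vs-oracle guarantee in the tests is stated
  only at small n where all pairs are enumerated.
* DeLong intervals are normal-theory; with very few positives the
  stratified bootstrap in the test suite is the safer reference.
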