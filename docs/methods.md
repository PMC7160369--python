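# Methods

This note documents the scientific and numerical choices behind the
package: what is modelled, which knobs matter, what the synthetic data do
and do not emulate, and where the design was genuinely open.

## Segmentation model

A response is segmented by a greedy left-to-right scan over adjacent word
pairs: token *i* joins the current cluster iff the same-cluster predicate
holds for (*W*<sub>i−1</sub>, *W*<sub>i</sub>), otherwise a switch is
recorded at *i*. Only the adjacent pair is consulted — no look-ahead, no
chain rules over shared subcategories. This is exactly the rule supported
by an adjacent-similarity sequence *d*(*W*<sub>i−1</sub>, *W*<sub>i</sub>)
and keeps the two modes (embedding threshold, category-table
intersection) interchangeable behind one predicate.

Conventions worth pinning down:

* **Similarity, not distance.** Throughout, higher cosine = more related;
  a *switch* occurs when similarity falls **below** the threshold. A tie
  (similarity == threshold) joins the cluster, because the switch
  condition is "lower than".
* **Adaptive threshold.** The response's adjacent similarities are
  min–max normalized to [0, 1]; the threshold is `fraction × mean` of the
  normalized values (default fraction 0.75), and the comparison happens
  on the same normalized scale. The normalization basis is the adjacent
  pairs of the response (an all-pairs basis is available via
  `SemanticThresholdConfig.pair_scope`). If all similarities are equal
  the threshold is undefined and the pipeline falls back to a single
  cluster with a warning.
* **Repetitions** (perseverations) are segmented like any other token;
  uniqueness is applied only in the unique-word counts.
* In category-table mode, names absent from the table are treated as
  non-animal and dropped before segmentation. The drop happens *after*
  timeline trimming, when word durations are no longer available, so no
  second interval collapse is applied — the inter-word gap absorbs the
  dropped token. Responses dominated by out-of-table names therefore
  lose timing resolution in table mode; embedding mode does not have
  this problem.

## Timeline trimming

"Renormalizing timestamps to the shortened audio" is implemented as
**interval collapse**: each removed (non-animal) token's duration is
subtracted from every later onset, so
`removed + shortened == original` exactly and gaps between animal words
with no interruption between them are preserved to the second. The
alternative reading — dividing collapsed onsets by the shortened
duration — is available as `time_norm: fraction` for sensitivity
analysis; collapse is the default because it preserves the raw
second-scale gap values of the worked example (0.7 s, 0.9 s).

## Timing features

Per switch, SD is the onset gap across the cluster boundary and ICRT the
onset gap of the first two words of the entered cluster; both require
the segmentation and the collapsed timeline. ICRT (and hence
OSR = |SD − ICRT|) is undefined when the entered cluster is a singleton;
undefined entries are NaN and excluded from the per-subject aggregates
(mean, median, population variance, min, max). A subject with no
switches gets all-NaN timing aggregates, which downstream model fitting
imputes with the training-fold median. Variance and standard deviations
are population (divide by *n*) everywhere — these are descriptors of the
response, not estimators of a super-population moment.

## Count features

Fifteen features per response (see `count_features.COUNT_FEATURES`).
"Unique animal words" and "unique words" coincide after normalization,
so one `af_score` column carries both. Word frequency enters as the
natural log; tokens without a positive frequency entry are excluded from
that feature's moments (a warning counts them) rather than contributing
−∞. Lexical moments average over *tokens*, so repeated words count
twice. `mesa` (mean adjacent similarity) and `maesa` (mean over all
C(n, 2) token pairs) need an embedding store and are NaN without one or
for single-word responses.

## Name normalization

Tokens are matched longest-phrase-first against the lexicon (multi-word
names such as "great white shark" merge into one token spanning the
constituent words), then through an irregular-plural map ("oxen",
"hippopotami"), then by conservative suffix stemming (-s, -es, -ies)
accepted only when the stemmed form is itself a lexicon entry — "moose"
is never truncated. Everything else is non-animal. All resources are
local files; nothing is looked up online.

## Scaling, selection, classification

* **Quantile scaling** follows `f(x) = (x − Q1)/(Q3 − Q1)` per feature —
  note the centering on Q1 (so Q1 ↦ 0, Q3 ↦ 1), not on the median as in
  the conventional robust scaler; `scaler_center: median` exposes the
  conventional variant. Quantiles are linear-interpolation order
  statistics, fitted on training rows only and reused for test rows. A
  training-constant feature is scaled to 0.
* **RFECV** drops the smallest-|coefficient| feature one at a time,
  scoring each subset by inner stratified k-fold AUC (default 5 folds)
  and returning the best subset. By default selection runs **once on the
  full matrix** before the repeated CV — mirroring the reporting of a
  single final feature set — with `per_repeat` available for strict
  nesting at ~n_repeats× the cost.
* **Linear SVM** via liblinear with squared hinge loss (the L1-penalized
  primal supports only squared hinge, so both penalties use it for
  comparability), default C = 10, L1 penalty, and an optional inner-CV
  grid search over C ∈ {1e−10, 0.1, 1, 10} × {L1, L2}. At large C the L1
  coordinate-descent solver cycles near the optimum without meeting
  tol = 1e−4, so the iteration cap (2000) is the effective stopping
  rule; coefficients are stable well before it. `random_state` is pinned
  — liblinear is internally randomized.
* **Leave-one-pair-out CV**: per repeat, MCI and CI subjects are
  shuffled and paired (uniformly at random — no pairing rule beyond
  class membership is imposed); each fold trains on the remaining
  subjects subsampled without replacement to the smaller class's size
  (27 + 27 for 28/42) and scores the held-out pair with the decision
  function. Fold scores pool into one AUC per repeat; sensitivity and
  specificity use the sign of the decision function with MCI positive.
  Reported metrics are means over repeats, in percent. Everything is
  driven by one `numpy` generator, so a given seed is bit-reproducible.

A property worth knowing when interpreting null experiments: on a single
finite cohort with *no* group signal, the LOPO-SVM estimate is
high-variance and pessimistically biased (training folds anti-correlate
with their held-out pair), so individual null cohorts can score well
below or above 50 %. The expectation over independent null cohorts is
close to 50, and the label-independent chance scorer is unbiased at 50
on any cohort; the test suite asserts both at those levels.

## Statistical screening

Feature screening uses the two-sample Kolmogorov–Smirnov statistic
(exact sup-difference of the ECDFs) with the two-sided asymptotic
p-value — appropriate for group sizes of a few dozen, and
distribution-free across features whose scales differ wildly. NaNs are
dropped per feature; a feature needs ≥ 2 present values per group.

## Synthetic cohorts

The generator emulates a 60-second session per subject: a first word at
0.8–1.6 s, then clusters drawn as subcategory patches from the fixture
category table, geometric cluster sizes, log-normal intra-cluster gaps,
and log-normal switch gaps, emitted until the clock runs out. Group
parameters (defaults):

| parameter | CI | MCI | meaning |
|---|---|---|---|
| `mean_words` | 17.3 | 13.3 | target mean unique names per 60 s |
| `subject_sigma` | 0.29 | 0.31 | between-subject log-pace spread |
| `switch_ratio` | 1.5 | 2.5 | mean switch gap / mean intra gap |
| `switch_sigma` | 0.3 | 0.7 | log-scale spread of switch gaps |
| `mean_cluster_size` | 2.5 | 2.2 | geometric mean patch size |

The productivity targets are published animal-fluency means for matched
MCI / intact groups of advanced age, and the subject sigmas are their
coefficients of variation; the remaining shapes were chosen once as
field-realistic (positive support and right skew for retrieval
intervals; geometric patch sizes). The gap *scale* is never tuned: it is
derived in closed form from the target count via renewal theory
(`E[N(t)] = t/μ + (c² − 1)/2`, plus corrections for the perseveration
rate and the Jensen term of the pace multiplier). The MCI
parameterization produces fewer words and a larger, more variable
|SD − ICRT| — the "poor patch-leaving" hypothesis the timing features
target.

Interruptions ("you still have ten seconds left") and fillers ("um")
are inserted *into* gaps with real durations, shifting later tokens by
exactly the inserted time, so trimming recovers the clean timeline and
conservation is testable. Surface forms exercise normalization: plural
(regular and irregular) with probability 0.15, multi-word names split
into their constituent tokens.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: acoustic/ASR alignment error in the
timestamps, within-cluster semantic drift (words are exchangeable within
a patch), age/education covariates, out-of-vocabulary animal names, and
the real Troyer-style instrument (the fixture table is a synthetic
stand-in with real animal names but invented subcategory structure).
Classifier performance on synthetic cohorts reflects the injected effect
sizes, not clinically expected effect sizes.

Fixture embeddings place each subcategory at a near-orthogonal centroid
(QR-orthonormalized when the dimension allows) and each word at the mean
of its centroids plus Gaussian noise (0.25/√d), giving high
within-subcategory and low between-subcategory cosine similarity. The
worked-example embeddings are built by a chained construction that makes
each adjacent cosine *exactly* the printed value.

## Degenerate inputs and edge policies

* Empty responses, or responses with no animal words, are skipped with a
  warning at extraction (never silently imputed).
* Single-word responses segment as one cluster; all pairwise features
  are NaN.
* A zero embedding vector, a missing embedding, and a name missing from
  the category table are hard errors naming the offending word.
* CTM parse errors name the file and line number.

## Known limitations

* Switching is strictly pairwise; the multi-category chain conventions
  of manual Troyer scoring are out of scope.
* The adaptive threshold is undefined for responses whose adjacent
  similarities are all equal (single-cluster fallback).
* Word-frequency, syllable and typicality tables are user-supplied; the
  shipped generators produce synthetic values, not psycholinguistic
  norms.
* The category-table mode drops out-of-table names, which biases timing
  features for subjects with many unlisted animals.
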