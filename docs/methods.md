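# Methods

## The surveillance problem

A manufacturer that sells far more product than the materials it records
buying is either omitting purchase invoices or using inputs it should not.
The pipeline turns that intuition into two testable stages: (1) restrict the
invoice stream to the commodity under surveillance (edible oil) by
classifying free-text item names, and (2) flag manufacturer-months whose
smoothed sales-to-purchase turnover is irrational on the log scale.

## Stage 1: the item-name sieve

Item names are short, noisy product titles. The funnel is:

1. **Keyword prefilter** — keep names containing "oil" (case-folded
   substring). This over-selects by design: soy sauce with "oil" in the name,
   motor oil, cosmetics.
2. **Tokenization** — case-fold, treat punctuation as whitespace, drop tokens
   containing digits (pack sizes, lot numbers). The tokenizer is a pluggable
   callable; for scripts without word boundaries a character-n-gram tokenizer
   can be substituted without touching anything downstream.
3. **Term filtering** — drop tokens below a document-frequency floor or on a
   stoplist.
4. **Featurization** — either *topics*: TF-IDF weighting of the filtered
   vocabulary reduced to `m` components by truncated SVD (the proprietary
   topic tool this emulates is unpublished; latent-semantic indexing is the
   closest widely understood analogue, and the singular-vector sign
   indeterminacy is fixed by making each component's largest-magnitude weight
   positive); or an *expert keyword* indicator vector (60 default terms).
   Optional feature selection ranks keywords by the chi-square statistic of
   their 2×2 occurrence-by-label table (ties break on feature index;
   constant features score 0).
5. **Classification** — k-NN (k ∈ {3,5,7}), linear SVM, logistic regression,
   a small feedforward net, or random forest, each behind a standard-scaler
   pipeline with a small fixed grid, selected by seeded stratified 5-fold CV
   on the 80% training split and reported on the held-out 20%.

Published work on this problem reports both an 80/20 split and 5-fold CV
without stating their interaction; this package adopts CV-for-selection
inside the 80% and metrics on the 20%, which is the only composition that
uses both without leaking the test split.

## Stage 2: the transaction alarm

Monthly totals per manufacturer: `Pur_i` sums amounts where the manufacturer
is the vendee (downstream), `Sale_i` where it is the vendor (upstream).
Missing months are zero-filled before smoothing — the absence of invoices is
informative, not missing data. The 3-month moving averages `D_i`, `U_i`
deliberately blur the artificial month boundary (purchases on the 1st are not
materially different from the 31st of the previous month) and damp
single-month noise. Features `X1 = ln(U_i/D_i)` and `X2 = ln(U_i/D_{i-1})`
use the natural log; the threshold 6 corresponds to a sales-to-purchase fold
ratio of e⁶ ≈ 403, i.e. > 400.

Numerical decisions:

- **Warm-up.** Features are emitted only for full 3-month windows: a series
  of M contiguous months yields M−2 X1 values and M−3 X2 values. X2 is absent
  for the first emitted month; the naïve rule labels such partial records
  benchmark.
- **Zero denominators.** `D = 0` with `U > 0` is conceptually +∞ (maximally
  suspicious); it is clamped to a configurable cap (default 20, far above the
  rule threshold) and flagged, preserving the semantics without non-finite
  arithmetic. The mirror case clamps to −20. Both window sums zero marks the
  record invalid and excludes it.
- **Rule boundary.** Strict inequalities: a point at exactly (6, 6) is
  benchmark.
- **Clamped records** participate in the naïve rule but are excluded from
  classifier training by default — they are distributional outliers by
  construction.

The five backends can be trained on (X1, X2). Because month records per class
are few, evaluation uses seeded stratified k-fold cross-validation (k = 5,
reduced to the smallest class size when necessary) with metrics pooled over
out-of-fold predictions; the in-sample report after the final refit is kept
alongside, since published alarm tables rarely state which variant they
print. Prediction ellipses fit a bivariate normal to the benchmark cloud
(sample mean and covariance); the level-p boundary is the Mahalanobis shell
at the chi-square(df = 2) quantile, `-2 ln(1-p)` in closed form. Ellipses are
descriptive aids and an optional outlier screen; they do not feed the
classifiers. Screening aggregates month labels to manufacturers by a
configurable minimum count of suspicious months (default 1); the aggregation
rule is this package's decision, since source material reports manufacturer
counts without stating one.

### Auditing a published performance table

`implied_error_rate(se, sp, n_pos, n_neg)` recovers the error counts implied
by a printed sensitivity/specificity pair as nearest integers and returns the
implied total error rate. With class sizes 27 suspicious / 425 benchmark
month records, the printed error-rate cells of five of six classifiers in the
alarm-performance table this package's evaluation surface mirrors are
reproduced exactly (SVM 5.97%, random forest 0.44%, k-NN 2.21%, logistic
2.65%, neural net 2.43%); the one-rule-tree row prints 3.97% where its own
se/sp imply (8 + 2)/452 = 2.21%. The package computes error rates from the
confusion matrix and documents the discrepancy rather than matching the
printed cell. Percentages render half-up to two decimals, the only reading
under which those five rows are self-consistent.

## The synthetic world

The generator's defaults state one fixed world: 21 benchmark (A), 6
problematic (B), 568 unspecified (C) manufacturers over 46 months from
January 2014; a 1,000-name catalog in three strata (350 edible-oil / 250
oil-keyword confounder / 400 unrelated — unique names composed from
per-stratum word pools whose token vocabularies are disjoint except for
"oil", shared with confounders by design); benchmark months draw
`log(Sale/Pur) ~ N(0, 0.5)`; suspicious months keep sales and scale recorded
purchases by e⁻⁸ (suppression, mirroring off-the-books material purchases,
rather than sales inflation — it keeps sales magnitudes comparable across
classes); half of a B manufacturer's months are suppressed (i.i.d.
Bernoulli); C months mix the regimes at 2%. Monthly totals split into a
Poisson number of lines (mean 6/side) by a Dirichlet weight vector, dated
uniformly within the month, at a 10⁵ currency-unit scale with lognormal
(sd 0.3) month-to-month variation; non-edible distractor lines (mean 3 per
month) make the sieve load-bearing. No distributional description of real
amounts is available, so these scale parameters are stand-ins chosen once
for plausibility, not calibrated.

One integer seed drives everything; per-manufacturer streams derive from a
stable 32-bit hash of the manufacturer id, making output byte-identical
across runs and platforms for equal (config, seed).

**Ground truth and smoothing.** The generator records raw per-month
suppression flags. For evaluating the alarm, truth is defined at the
feature-record level: a smoothed month is suspicious iff all four raw months
feeding `D_i` and `D_{i-1}` were suppressed (`feature_truth_labels`). This is
deliberate: 3-month smoothing dilutes an isolated suppressed month below any
threshold — that is what the fuzzification is for — and the lag feature looks
across a two-month span, so only sustained suppression is detectable or, on
the alarm's own terms, alarming. A consequence worth knowing: with the
default 2% i.i.d. C-month mixture, a four-month suppressed run almost never
occurs (p ≈ 1.6·10⁻⁷ per window), so screening the C class flags
essentially nothing; C screening becomes informative when suspicious months
arrive in runs, e.g. by raising `p_c_suspicious`.

**What a green test establishes — and does not.** The synthetic strata are
separable and the regimes well-separated (shift 8 vs noise 0.5), so perfect
sieve metrics and near-perfect rule recovery verify the *machinery* —
aggregation, smoothing, feature arithmetic, rule semantics, training
plumbing — not real-world performance. The generator does not emulate real
item-name text (no Chinese NLP, no brand noise shared across strata), price
levels or seasonality, invoice voiding or credit notes, tax semantics, or
manufacturers entering/leaving the panel; real sensitivities and
specificities will be materially lower.

## Known limitations

- The m-topic features of the proprietary text-mining tool cannot be
  reconstructed exactly; topic-feature results are analogues, not replicas.
- `amount` is treated as a unitless positive total; currency and tax
  semantics are out of scope, and quantity (optional in the data model) is
  unused.
- The clamp cap for zero-denominator records is an artifact decision; how
  such months were handled in the original analysis is unstated.
- A flag means "worth inspecting", not guilt; no causal reading is
  supported.
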