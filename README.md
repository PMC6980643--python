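# oilwatch

A two-stage early-alert pipeline for food-safety surveillance over
business-to-business e-invoices, aimed at regulators and data scientists who
monitor edible-oil supply chains for fraud (for example, manufacturers selling
product made from materials they never properly purchased).

**Stage 1 — sieving.** Invoice streams mix edible-oil lines with lookalike
confounders ("motor oil", "oil paint") and unrelated goods. Item names are
keyword-prefiltered on "oil", tokenized, and classified as edible-oil-related
or not, using either latent-semantic *topic* features (TF-IDF reduced to *m*
components by truncated SVD, *m* ∈ {30, …, 180}) or an expert keyword
indicator vector, under any of five backends (k-NN, linear SVM, logistic
regression, feedforward net, random forest). Model selection is stratified
5-fold CV inside a stratified 80/20 split; sensitivity, specificity and error
rate are reported on the held-out 20%.

**Stage 2 — the alarm.** For each manufacturer, monthly purchase (downstream,
D) and sales (upstream, U) totals over the sieved lines are smoothed with a
3-month moving average,

    D_i = (Pur_{i-2} + Pur_{i-1} + Pur_i) / 3,    U_i likewise over Sale,

and two log-turnover features are formed:

    X1 = ln(U_i / D_i),        X2 = ln(U_i / D_{i-1}).

The naïve one-node decision rule flags a manufacturer-month as suspicious iff
**X1 > 6 and X2 > 6** — sales exceeding e⁶ (> 400) times purchases over a
two-month span. The same five classifier backends can be trained on (X1, X2),
and 95%/99% bivariate-normal prediction ellipses over the benchmark cloud
provide the visual/outlier companion. Screening labels every unlabeled
manufacturer-month and flags manufacturers by a configurable month count.

Because real e-invoice corpora are access-restricted, the package ships a
synthetic generator (`oilwatch.synthetic`) that emulates the assumed
statistical structure — three item-name strata, benchmark months with
log(sales/purchases) ~ N(0, σ), suspicious months with recorded purchases
suppressed by e⁻⁸ — so the full pipeline is testable end to end with known
ground truth.

## Worked example

```python
import numpy as np
from oilwatch import (GeneratorConfig, generate_corpus, SieveModel, TopicModel,
                      sieve_invoices, feature_table, DecisionRule, screen_unlabeled,
                      fit_ellipse, feature_truth_labels)
from oilwatch.evaluation import report_from_predictions

config = GeneratorConfig(seed=7, n_A=21, n_B=6, n_C=40)
catalog, invoices, truth = generate_corpus(config)

sieve = SieveModel.from_labeled_items(
    catalog, method="random_forest", featurizer=TopicModel(m=60, seed=7)
).fit(split_seed=7)
print(sieve.summary())

related, unrelated = sieve_invoices(invoices, sieve)
features = feature_table(related, sorted(truth.classes))
labeled = features[features.manufacturer_id.str[0].isin(["A", "B"])]
labeled = labeled.sort_values(["manufacturer_id", "month"]).reset_index(drop=True)
y_true = np.concatenate([
    feature_truth_labels(truth, mid, grp["month"].astype(str).tolist())
    for mid, grp in labeled.groupby("manufacturer_id")
])
rule = DecisionRule()  # suspicious iff X1 > 6 and X2 > 6
pred = (rule.apply(labeled) == "suspicious").to_numpy()
print(report_from_predictions(y_true, pred, positive=True, method="naive rule").summary())
```

prints (machine-verified output):

```
Invoice sieve — random_forest on topics features (60 components)
method:      random_forest
n:           200 (70 positive / 130 negative)
sensitivity: 100.00%  (tp=70, fn=0)
specificity: 100.00%  (tn=130, fp=0)
error rate:  0.00%
method:      naive rule
n:           1188 (15 positive / 1173 negative)
sensitivity: 100.00%  (tp=15, fn=0)
specificity: 100.00%  (tn=1173, fp=0)
error rate:  0.00%
```

The sieve's held-out metrics say the 200 test item names were all partitioned
correctly (the synthetic catalog's strata are separable by construction). The
alarm block says all 15 manufacturer-months whose full two-month lag window
was purchase-suppressed were caught by the threshold rule, with no false
alarms among 1,173 benchmark months. On real data neither number would be
100% — the generator states an idealized world; see `docs/methods.md` for
what these greens do and do not establish.

A thin CLI wraps the same flow: `oilwatch generate`, `oilwatch sieve
train/apply`, `oilwatch features`, `oilwatch alarm fit/screen`, and `oilwatch
implied-error` (the published-table consistency calculator). Run any
subcommand with `--help`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default-scale synthetic corpus (595 manufacturers, 46 months,
~400k invoices), trains the sieve, partitions the stream, builds the smoothed
turnover features, evaluates the naïve rule and a trained alarm classifier
against the generator's ground truth, fits the 95%/99% benchmark ellipses,
and screens the unspecified manufacturers, logging each stage's metrics to
stderr. All randomness derives from `--seed`. Runtime is roughly 1–2 minutes.
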