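"""Stage 1: tokenization, keyword filtering, topic/keyword featurization,
feature selection, and sieve training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oilwatch.evaluation import stratified_split
from oilwatch.io import LabeledItem
from oilwatch.sieve import (
    DEFAULT_OIL_KEYWORDS,
    KeywordFeaturizer,
    SieveModel,
    TopicModel,
    build_topics,
    chi_square_scores,
    featurize_keywords,
    filter_terms,
    keyword_filter,
    normalize_and_tokenize,
    select_features,
    sieve_invoices,
    train_sieve,
)


class TestTokenizer:
    @pytest.mark.parametrize(
        "name,tokens",
        [
            ("Refined Soybean Oil 18L", ["refined", "soybean", "oil"]),
            ("", []),
            ("  olive-oil,  extra!virgin ", ["olive", "oil", "extra", "virgin"]),
            ("motor oil 10W40", ["motor", "oil"]),
        ],
    )
    def test_examples(self, name, tokens):
        assert normalize_and_tokenize(name) == tokens

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(max_size=40))
    def test_idempotent(self, text):
        toks = normalize_and_tokenize(text)
        assert normalize_and_tokenize(" ".join(toks)) == toks


class TestKeywordFilter:
    def test_substring_semantics(self):
        items = ["olive oil", "motor oil", "rice vinegar"]
        assert keyword_filter(items, "oil") == ["olive oil", "motor oil"]

    def test_case_folded(self):
        assert keyword_filter(["Olive OIL"], "oil") == ["Olive OIL"]

    def test_empty_input(self):
        assert keyword_filter([], "oil") == []

    def test_empty_keyword_rejected(self):
        with pytest.raises(ValueError):
            keyword_filter(["x"], "  ")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["olive oil", "oily rag", "tea", "soy sauce", "OIL can"]), max_size=20))
    def test_projection(self, items):
        once = keyword_filter(items, "oil")
        assert keyword_filter(once, "oil") == once


class TestFilterTerms:
    def test_doc_frequency_threshold(self):
        docs = [["oil", "olive"], ["oil", "motor"], ["tea"]]
        assert filter_terms(docs, min_doc_freq=2) == ["oil"]

    def test_stoplist_wins_over_frequency(self):
        docs = [["oil"], ["oil"], ["oil"]]
        assert filter_terms(docs, min_doc_freq=1, stoplist=["oil"]) == []

    def test_identity_case(self):
        docs = [["a", "b"], ["b", "c"]]
        assert filter_terms(docs) == ["a", "b", "c"]


class TestTopicModel:
    def test_dimension_contract(self, catalog_1000):
        names = [it.item_name for it in catalog_1000]
        tm = build_topics(names, m=60, seed=0)
        assert tm.transform(names[:7]).shape == (7, 60)
        assert tm.components.shape[0] == 60

    def test_deterministic_basis(self, catalog_1000):
        names = [it.item_name for it in catalog_1000[:200]]
        a = build_topics(names, m=10, seed=4)
        b = build_topics(names, m=10, seed=4)
        np.testing.assert_allclose(a.components, b.components)
        # sign convention: each topic's largest-magnitude weight is positive
        comp = a.components
        assert (comp[np.arange(10), np.abs(comp).argmax(axis=1)] > 0).all()

    def test_m_too_large_instructs_smaller_m(self):
        names = ["olive oil", "motor oil", "rice tea", "soy sauce", "palm oil"] * 4
        with pytest.raises(ValueError, match="smaller m"):
            build_topics(names, m=50)

    def test_two_stratum_separability(self, catalog_1000):
        """Disjoint-vocabulary strata: a logistic classifier on 10 topic
        components separates edible-oil from unrelated names with < 5% error."""
        items = [it for it in catalog_1000 if it.label == 1][:200] + [
            it for it in catalog_1000 if it.label == 0
        ][-200:]
        names = [it.item_name for it in items]
        y = np.array([it.label for it in items])
        tm = build_topics(names, m=10, seed=0)
        tr, te = stratified_split(y, 0.2, seed=0)
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(max_iter=1000).fit(tm.transform([names[i] for i in tr]), y[tr])
        err = (clf.predict(tm.transform([names[i] for i in te])) != y[te]).mean()
        assert err < 0.05


class TestKeywordFeaturizer:
    def test_counts_present_keywords(self):
        kf = KeywordFeaturizer()
        v = featurize_keywords("premium soybean oil can", kf)
        assert v.sum() == 2  # "premium" and "soybean"; "oil" itself is not a keyword

    def test_zero_and_all_ones(self):
        kf = KeywordFeaturizer(["soybean", "olive", "palm"])
        assert featurize_keywords("motor oil", kf).sum() == 0
        assert featurize_keywords("soybean olive palm blend", kf).tolist() == [1, 1, 1]

    def test_purity(self):
        kf = KeywordFeaturizer()
        a = featurize_keywords("refined soybean oil", kf)
        b = featurize_keywords("refined soybean oil", kf)
        np.testing.assert_array_equal(a, b)

    def test_default_list_has_sixty_unique_keywords(self):
        assert len(DEFAULT_OIL_KEYWORDS) == 60
        assert KeywordFeaturizer().n_features == 60

    def test_duplicate_keywords_deduplicated(self):
        assert KeywordFeaturizer(["Olive", "olive", "palm"]).n_features == 2


class TestSelectFeatures:
    def test_sixty_to_thirtyone(self, catalog_1000):
        names = [it.item_name for it in catalog_1000]
        labels = [it.label for it in catalog_1000]
        kf = KeywordFeaturizer()
        reduced = select_features(kf, names, labels, target_count=31)
        assert reduced.n_features == 31

    def test_identity_when_target_equals_count(self, catalog_1000):
        names = [it.item_name for it in catalog_1000[:100]]
        labels = [it.label for it in catalog_1000[:100]]
        kf = KeywordFeaturizer(["soybean", "olive", "motor"])
        assert select_features(kf, names, labels, 3).keywords == kf.keywords

    def test_label_identical_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        X = rng.integers(0, 2, (200, 5)).astype(float)
        X[:, 3] = y  # perfect association
        scores = chi_square_scores(X, y)
        assert scores.argmax() == 3
        assert scores[3] == pytest.approx(200.0)  # chi-square of a perfect 2x2 table is n

    def test_constant_feature_scores_zero(self):
        y = np.array([0, 1] * 20)
        X = np.ones((40, 2))
        X[:, 1] = np.array([0, 1] * 20)
        scores = chi_square_scores(X, y)
        assert scores[0] == 0.0 and scores[1] > 0

    def test_target_above_count_rejected(self):
        kf = KeywordFeaturizer(["a", "b"])
        with pytest.raises(ValueError):
            select_features(kf, ["a"], [1], 5)


class TestTrainSieve:
    def test_deterministic_report(self, catalog_1000):
        items = catalog_1000[:150] + catalog_1000[-150:]
        r1 = train_sieve(items, method="logistic", featurizer=KeywordFeaturizer(), split_seed=5)[1]
        r2 = train_sieve(items, method="logistic", featurizer=KeywordFeaturizer(), split_seed=5)[1]
        assert r1 == r2

    def test_single_class_rejected(self):
        items = [LabeledItem(item_name=f"item {c}", label=0) for c in "abcdefghij"]
        with pytest.raises(ValueError, match="both labels"):
            SieveModel.from_labeled_items(items)

    def test_too_few_items_rejected(self):
        items = [LabeledItem(item_name=str(i), label=i % 2) for i in range(6)]
        with pytest.raises(ValueError, match="at least 10"):
            SieveModel.from_labeled_items(items)

    def test_shuffled_labels_hit_permutation_baseline(self, catalog_1000):
        """With labels shuffled, held-out error is near the baseline of always
        predicting the majority class."""
        rng = np.random.default_rng(1)
        names = [it.item_name for it in catalog_1000]
        y = np.array([it.label for it in catalog_1000])
        y_shuf = rng.permutation(y)
        model = SieveModel(names, y_shuf, method="logistic", featurizer=KeywordFeaturizer())
        report = model.fit(split_seed=1).report
        baseline = min(y_shuf.mean(), 1 - y_shuf.mean())
        assert abs(report.error_rate - baseline) < 0.12

    def test_increasing_topics_never_hurts_much(self, catalog_1000):
        """On the separable benchmark, growing m across {10, 30, 60} does not
        decrease held-out sensitivity beyond Monte-Carlo noise."""
        sens = []
        for m in (10, 30, 60):
            res = SieveModel.from_labeled_items(
                catalog_1000, method="logistic", featurizer=TopicModel(m=m, seed=2)
            ).fit(split_seed=2)
            sens.append(res.report.sensitivity)
        assert sens[1] >= sens[0] - 0.05
        assert sens[2] >= sens[1] - 0.05


class TestSieveInvoices:
    def test_partition_conserves_and_matches_truth(self, small_corpus):
        catalog, invoices, _ = small_corpus
        results = SieveModel.from_labeled_items(
            catalog, method="random_forest", featurizer=KeywordFeaturizer()
        ).fit(split_seed=0)
        related, unrelated = sieve_invoices(invoices, results)
        assert len(related) + len(unrelated) == len(invoices)
        # classifier is perfect on this separable catalog, so the partition
        # equals the ground-truth item labels
        oil = {it.item_name for it in catalog if it.label == 1}
        assert all(inv.item_name in oil for inv in related)
        assert all(inv.item_name not in oil for inv in unrelated)

    def test_empty_input(self, small_corpus):
        catalog, _, _ = small_corpus
        results = SieveModel.from_labeled_items(
            catalog, method="logistic", featurizer=KeywordFeaturizer()
        ).fit(split_seed=0)
        assert sieve_invoices([], results) == ([], [])
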