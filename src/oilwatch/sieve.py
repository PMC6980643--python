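"""Stage 1 — sieving edible-oil-related invoices by item-name classification.

The stage mirrors a text-mining funnel: a keyword pre-filter on "oil", light
normalization and tokenization, document-frequency term filtering, then one of
two featurizations — latent-semantic *topics* (TF-IDF weighting reduced to m
components by truncated SVD) or an expert keyword indicator vector — feeding a
supervised classifier chosen among five standard backends. Model selection
uses stratified 5-fold cross-validation inside a stratified 80/20 split; the
reported sensitivity (probability of identifying a related item), specificity
and error rate come from the held-out 20%.

The tokenizer is pluggable: every featurizer accepts a ``tokenizer`` callable,
so a character-n-gram tokenizer can replace the whitespace one for scripts
without word boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import TruncatedSVD
from sklearn.feature_extraction.text import TfidfVectorizer

from . import backends
from .evaluation import EvalReport, report_from_predictions, stratified_split
from .io import Invoice, LabeledItem

__all__ = [
    "normalize_and_tokenize",
    "keyword_filter",
    "filter_terms",
    "TopicModel",
    "build_topics",
    "KeywordFeaturizer",
    "featurize_keywords",
    "chi_square_scores",
    "select_features",
    "SieveModel",
    "SieveResults",
    "train_sieve",
    "sieve_invoices",
    "DEFAULT_OIL_KEYWORDS",
]

_TOKEN_SPLIT = re.compile(r"[^0-9a-z]+")
_HAS_DIGIT = re.compile(r"\d")


def normalize_and_tokenize(item_name: str) -> list[str]:
    """Case-fold and split an item name into alphabetic tokens.

    Punctuation is treated as whitespace; tokens containing digits (pack
    sizes, lot numbers) are dropped. Idempotent: tokenizing the joined tokens
    reproduces them.
    """
    parts = _TOKEN_SPLIT.split(item_name.casefold())
    return [t for t in parts if t and not _HAS_DIGIT.search(t)]


def _normalize(text: str) -> str:
    return " ".join(normalize_and_tokenize(text))


def keyword_filter(items: Sequence[str], keyword: str) -> list[str]:
    """Keep exactly the items whose normalized name contains the normalized
    keyword as a substring; order and duplicates preserved."""
    if not keyword or not keyword.strip():
        raise ValueError("keyword must be non-empty")
    key = _normalize(keyword)
    return [it for it in items if key in _normalize(it)]


def filter_terms(
    token_lists: Sequence[Sequence[str]],
    min_doc_freq: int = 1,
    stoplist: Iterable[str] = (),
) -> list[str]:
    """Vocabulary of tokens appearing in at least ``min_doc_freq`` documents
    and not on the stoplist, sorted for determinism."""
    if min_doc_freq < 1:
        raise ValueError("min_doc_freq must be >= 1")
    stop = set(stoplist)
    df: dict[str, int] = {}
    for toks in token_lists:
        for t in set(toks):
            df[t] = df.get(t, 0) + 1
    return sorted(t for t, n in df.items() if n >= min_doc_freq and t not in stop)


# 60 expert terms that distinguish edible-oil merchandise from "oil"-keyword
# confounders; used as the default keyword featurization.
DEFAULT_OIL_KEYWORDS = [
    "soybean", "olive", "peanut", "sesame", "canola", "sunflower", "palm",
    "ricebran", "grapeseed", "corn", "camellia", "lard", "cooking", "salad",
    "frying", "vegetable", "refined", "virgin", "organic", "pressed", "pure",
    "blended", "roasted", "filtered", "unrefined", "premium", "expeller",
    "firstpress", "extra", "cold", "edible", "culinary", "kitchen", "fryer",
    "shortening", "margarine", "tallow", "coconut", "avocado", "walnut",
    "almond", "flaxseed", "safflower", "cottonseed", "mustard", "rapeseed",
    "groundnut", "maize", "wok", "tempura", "stirfry", "drizzle", "dressing",
    "marinade", "sauce", "seasoned", "infused", "garlic", "chili", "truffle",
]


class KeywordFeaturizer:
    """Binary indicator featurization over an expert keyword list.

    Component j of the feature vector is 1 iff keyword j occurs as a token of
    the normalized item name (multi-word keywords match as token subsequences
    of the normalized text).
    """

    def __init__(
        self,
        keywords: Sequence[str] | None = None,
        tokenizer: Callable[[str], list[str]] = normalize_and_tokenize,
    ) -> None:
        raw = list(keywords) if keywords is not None else list(DEFAULT_OIL_KEYWORDS)
        self.tokenizer = tokenizer
        normed = [" ".join(tokenizer(k)) for k in raw]
        seen: dict[str, None] = {}
        for k in normed:
            if k:
                seen.setdefault(k, None)
        self.keywords: list[str] = list(seen)
        if not self.keywords:
            raise ValueError("keyword list is empty after normalization")

    @property
    def n_features(self) -> int:
        return len(self.keywords)

    def transform(self, names: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(names), self.n_features), dtype=float)
        for i, name in enumerate(names):
            text = " ".join(self.tokenizer(name))
            padded = f" {text} "
            for j, kw in enumerate(self.keywords):
                if f" {kw} " in padded:
                    out[i, j] = 1.0
        return out

    def subset(self, indices: Sequence[int]) -> "KeywordFeaturizer":
        kept = [self.keywords[i] for i in indices]
        return KeywordFeaturizer(kept, tokenizer=self.tokenizer)

    def describe(self) -> dict:
        return {"kind": "keywords", "n_features": self.n_features}


def featurize_keywords(item_name: str, featurizer: KeywordFeaturizer) -> np.ndarray:
    """Indicator vector of the featurizer's keywords present in one name."""
    return featurizer.transform([item_name])[0]


class TopicModel:
    """Latent-semantic topic featurization: TF-IDF weighting of the filtered
    vocabulary reduced to an m-dimensional basis by truncated SVD.

    The proprietary topic clustering the funnel emulates is unpublished;
    TF-IDF + truncated SVD is the closest widely-understood analogue. Singular
    vectors have an arbitrary sign, fixed here by making each basis vector's
    largest-magnitude component positive, so identical corpus and seed give an
    identical basis.
    """

    def __init__(
        self,
        m: int,
        seed: int = 0,
        min_doc_freq: int = 1,
        stoplist: Iterable[str] = (),
        tokenizer: Callable[[str], list[str]] = normalize_and_tokenize,
    ) -> None:
        if m < 1:
            raise ValueError("m must be >= 1")
        self.m = m
        self.seed = seed
        self.min_doc_freq = min_doc_freq
        self.stoplist = tuple(stoplist)
        self.tokenizer = tokenizer
        self._vectorizer: TfidfVectorizer | None = None
        self._svd: TruncatedSVD | None = None

    @property
    def n_features(self) -> int:
        return self.m

    @property
    def vocabulary(self) -> list[str]:
        if self._vectorizer is None:
            raise RuntimeError("TopicModel is not fitted")
        return list(self._vectorizer.get_feature_names_out())

    @property
    def components(self) -> np.ndarray:
        """The m × vocabulary topic basis."""
        if self._svd is None:
            raise RuntimeError("TopicModel is not fitted")
        return self._svd.components_

    def fit(self, names: Sequence[str]) -> "TopicModel":
        if len(names) < self.m:
            raise ValueError(
                f"corpus has {len(names)} documents < m={self.m}; choose a smaller m"
            )
        vocab = filter_terms(
            [self.tokenizer(n) for n in names], self.min_doc_freq, self.stoplist
        )
        if len(vocab) <= self.m:
            raise ValueError(
                f"m={self.m} is not below the vocabulary size {len(vocab)}; "
                "choose a smaller m"
            )
        self._vectorizer = TfidfVectorizer(
            analyzer=self.tokenizer, vocabulary=vocab, norm="l2"
        )
        X = self._vectorizer.fit_transform(names)
        self._svd = TruncatedSVD(n_components=self.m, random_state=self.seed)
        self._svd.fit(X)
        # fix the sign indeterminacy of singular vectors
        comp = self._svd.components_
        signs = np.sign(comp[np.arange(comp.shape[0]), np.abs(comp).argmax(axis=1)])
        signs[signs == 0] = 1.0
        self._svd.components_ = comp * signs[:, None]
        return self

    def transform(self, names: Sequence[str]) -> np.ndarray:
        if self._vectorizer is None or self._svd is None:
            raise RuntimeError("TopicModel is not fitted")
        return self._svd.transform(self._vectorizer.transform(names))

    def describe(self) -> dict:
        return {"kind": "topics", "m": self.m, "seed": self.seed}


def build_topics(names: Sequence[str], m: int, seed: int = 0, **kwargs) -> TopicModel:
    """Fit an m-topic featurization on a corpus of item names."""
    return TopicModel(m=m, seed=seed, **kwargs).fit(names)


def chi_square_scores(X: np.ndarray, y: Sequence[int]) -> np.ndarray:
    """Chi-square statistic of each binary feature's 2×2 table against the
    binary label; constant features score 0."""
    Xb = (np.asarray(X) > 0).astype(float)
    yb = np.asarray(y).astype(float)
    n = len(yb)
    if n == 0:
        raise ValueError("no observations")
    scores = np.zeros(Xb.shape[1])
    n1 = yb.sum()
    for j in range(Xb.shape[1]):
        f = Xb[:, j]
        a = float((f * yb).sum())          # feature & label
        b = float(f.sum() - a)             # feature & not label
        c = float(n1 - a)                  # not feature & label
        d = float(n - a - b - c)
        row1, row0 = a + b, c + d
        col1, col0 = a + c, b + d
        if row1 == 0 or row0 == 0 or col1 == 0 or col0 == 0:
            continue  # degenerate (constant feature or label): score 0
        num = n * (a * d - b * c) ** 2
        scores[j] = num / (row1 * row0 * col1 * col0)
    return scores


def select_features(
    featurizer: KeywordFeaturizer,
    names: Sequence[str],
    labels: Sequence[int],
    target_count: int,
) -> KeywordFeaturizer:
    """Keep the ``target_count`` keywords most associated with the label.

    Features are ranked by the chi-square statistic of their 2×2 occurrence
    table; ties break deterministically on feature index.
    """
    if target_count > featurizer.n_features:
        raise ValueError(
            f"target_count={target_count} exceeds feature count {featurizer.n_features}"
        )
    X = featurizer.transform(names)
    scores = chi_square_scores(X, labels)
    order = np.lexsort((np.arange(len(scores)), -scores))
    kept = np.sort(order[:target_count])
    return featurizer.subset(kept)


@dataclass
class SieveResults:
    """Fitted sieve: the trained backend, its featurization, and held-out
    performance. Produced by :meth:`SieveModel.fit`."""

    method: str
    featurizer: TopicModel | KeywordFeaturizer
    classifier: object
    report: EvalReport
    best_params: dict = field(default_factory=dict)
    split_seed: int = 0

    def predict(self, names: Sequence[str]) -> np.ndarray:
        """Binary edible-oil-related predictions for item names."""
        return np.asarray(self.classifier.predict(self.featurizer.transform(names)), dtype=int)

    def summary(self) -> str:
        head = (
            f"Invoice sieve — {self.method} on "
            f"{self.featurizer.describe()['kind']} features "
            f"({self.featurizer.n_features} components)"
        )
        return head + "\n" + self.report.summary()

    def report_dict(self) -> dict:
        d = self.report.to_dict()
        d.update(self.featurizer.describe())
        d["split_seed"] = self.split_seed
        d["best_params"] = {k: v for k, v in self.best_params.items()}
        return d


class SieveModel:
    """Item-name classifier for the edible-oil sieve (model object).

    Parameters
    ----------
    item_names, labels
        The labeled catalog; both classes must be present.
    method
        One of ``knn``, ``linear_svm``, ``logistic``, ``neural_net``,
        ``random_forest``.
    featurizer
        A fitted-or-not :class:`TopicModel` or :class:`KeywordFeaturizer`; by
        default an ``m=60`` topic model fitted on the training split.
    """

    def __init__(
        self,
        item_names: Sequence[str],
        labels: Sequence[int],
        method: str = "random_forest",
        featurizer: TopicModel | KeywordFeaturizer | None = None,
    ) -> None:
        if len(item_names) != len(labels):
            raise ValueError("item_names and labels must have equal length")
        if len(item_names) < 10:
            raise ValueError("need at least 10 labeled items for an 80/20 split")
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("both labels must be present in the training data")
        if method not in backends.METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {backends.METHODS}")
        self.item_names = list(item_names)
        self.labels = y
        self.method = method
        self.featurizer = featurizer

    @classmethod
    def from_labeled_items(cls, items: Sequence[LabeledItem], **kwargs) -> "SieveModel":
        return cls([it.item_name for it in items], [it.label for it in items], **kwargs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "SieveModel":
        return cls(df["item_name"].tolist(), df["label"].tolist(), **kwargs)

    def fit(self, split_seed: int = 0, cv_seed: int | None = None) -> SieveResults:
        """Stratified 80/20 split, 5-fold CV model selection on the training
        portion, and held-out evaluation on the 20%."""
        cv_seed = split_seed if cv_seed is None else cv_seed
        train_idx, test_idx = stratified_split(self.labels, 0.2, split_seed)
        names = np.asarray(self.item_names, dtype=object)
        featurizer = self.featurizer
        if featurizer is None:
            featurizer = TopicModel(m=60, seed=cv_seed)
        if isinstance(featurizer, TopicModel) and featurizer._svd is None:
            featurizer.fit([str(n) for n in names[train_idx]])
        X_train = featurizer.transform([str(n) for n in names[train_idx]])
        X_test = featurizer.transform([str(n) for n in names[test_idx]])
        y_train, y_test = self.labels[train_idx], self.labels[test_idx]
        search = backends.grid_search(self.method, seed=cv_seed)
        search.fit(X_train, y_train)
        y_pred = search.best_estimator_.predict(X_test)
        report = report_from_predictions(
            y_test, y_pred, positive=1, method=self.method, seed=split_seed
        )
        report.extra["n_train"] = int(len(train_idx))
        report.extra["n_test"] = int(len(test_idx))
        return SieveResults(
            method=self.method,
            featurizer=featurizer,
            classifier=search.best_estimator_,
            report=report,
            best_params=dict(search.best_params_),
            split_seed=split_seed,
        )


def train_sieve(
    items: Sequence[LabeledItem],
    method: str = "random_forest",
    featurizer: TopicModel | KeywordFeaturizer | None = None,
    split_seed: int = 0,
) -> tuple[SieveResults, EvalReport]:
    """Functional wrapper over :class:`SieveModel`: returns the fitted sieve
    and its held-out evaluation report."""
    results = SieveModel.from_labeled_items(items, method=method, featurizer=featurizer).fit(
        split_seed=split_seed
    )
    return results, results.report


def sieve_invoices(
    invoices: Sequence[Invoice], results: SieveResults
) -> tuple[list[Invoice], list[Invoice]]:
    """Partition an invoice stream by predicted item-name label.

    Returns ``(related, unrelated)``; sizes always sum to the input size.
    Predictions are computed once per distinct item name.
    """
    if not invoices:
        return [], []
    names = sorted({inv.item_name for inv in invoices})
    pred = dict(zip(names, results.predict(names)))
    related = [inv for inv in invoices if pred[inv.item_name] == 1]
    unrelated = [inv for inv in invoices if pred[inv.item_name] == 0]
    return related, unrelated
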