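"""The five supervised backends both pipeline stages share, with their small
fixed hyperparameter grids, behind canonical method names."""

from __future__ import annotations

from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

METHODS = ("knn", "linear_svm", "logistic", "neural_net", "random_forest")

# Grids are deliberately small and fixed; k-NN defaults to voting over
# k in {3, 5, 7} with k = 5 the usual winner on well-separated data.
_GRIDS = {
    "knn": {"clf__n_neighbors": [3, 5, 7]},
    "linear_svm": {"clf__C": [0.1, 1.0]},
    "logistic": {"clf__C": [0.1, 1.0]},
    "neural_net": {"clf__alpha": [1e-4, 1e-2]},
    "random_forest": {"clf__max_features": ["sqrt", None]},
}


def make_classifier(method: str, seed: int = 0) -> Pipeline:
    """Fresh unfitted estimator pipeline for a canonical method name."""
    if method == "knn":
        clf = KNeighborsClassifier(n_neighbors=5)
    elif method == "linear_svm":
        clf = LinearSVC(C=1.0, random_state=seed)
    elif method == "logistic":
        clf = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    elif method == "neural_net":
        clf = MLPClassifier(
            hidden_layer_sizes=(16,), max_iter=1000, random_state=seed, solver="adam"
        )
    elif method == "random_forest":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def grid_search(method: str, seed: int = 0, n_folds: int = 5) -> GridSearchCV:
    """Estimator wrapped in seeded stratified k-fold grid search."""
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return GridSearchCV(
        make_classifier(method, seed), _GRIDS[method], cv=cv, scoring="accuracy", n_jobs=1
    )
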