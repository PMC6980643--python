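"""Stage 2 detection: the naïve threshold rule, elliptic prediction regions,
classifier backends on (X1, X2), and screening of unlabeled manufacturers.

The naïve rule is a one-node decision tree: a manufacturer-month is
*suspicious* iff X1 > 6 and X2 > 6 (strict inequalities; a point on the
boundary is benchmark). The threshold 6 means the smoothed sales amount
exceeds e^6 (> 400) times the smoothed purchases over a two-month span.
Prediction ellipses at 95%/99% coverage are descriptive aids fitted to the
benchmark cloud: a bivariate normal whose Mahalanobis boundary radius² is the
chi-square(df = 2) quantile at the coverage level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import backends
from .evaluation import EvalReport, report_from_predictions

__all__ = [
    "DecisionRule",
    "naive_rule_classify",
    "PredictionEllipse",
    "fit_ellipse",
    "AlarmModel",
    "AlarmResults",
    "train_alarm_classifier",
    "AlarmReport",
    "screen_unlabeled",
    "plot_features",
]

SUSPICIOUS = "suspicious"
BENCHMARK = "benchmark"


@dataclass(frozen=True)
class DecisionRule:
    """Two-threshold rule on the log-turnover features (strict inequalities)."""

    t1: float = 6.0
    t2: float = 6.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t1) and np.isfinite(self.t2)):
            raise ValueError("thresholds must be finite")

    def classify(self, x1: float, x2: float) -> str:
        """Label one record; a missing X2 (first emitted month) is benchmark
        by convention."""
        if x2 is None or (isinstance(x2, float) and np.isnan(x2)):
            return BENCHMARK
        return SUSPICIOUS if (x1 > self.t1 and x2 > self.t2) else BENCHMARK

    def apply(self, features: pd.DataFrame) -> pd.Series:
        """Vectorized labels over a feature table with X1, X2 columns."""
        x1 = features["X1"].to_numpy(dtype=float)
        x2 = features["X2"].to_numpy(dtype=float)
        hit = (x1 > self.t1) & (x2 > self.t2) & ~np.isnan(x2) & ~np.isnan(x1)
        return pd.Series(np.where(hit, SUSPICIOUS, BENCHMARK), index=features.index)


def naive_rule_classify(x1: float, x2: float, rule: DecisionRule | None = None) -> str:
    """Label a single (X1, X2) point with the naïve threshold rule."""
    return (rule or DecisionRule()).classify(x1, x2)


class PredictionEllipse:
    """Elliptic prediction region of a bivariate normal fitted to benchmark
    months. A point p is inside iff its squared Mahalanobis distance from the
    sample mean is at most the chi-square(df=2) quantile at ``level``."""

    def __init__(self, center: np.ndarray, cov: np.ndarray, level: float = 0.95) -> None:
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        center = np.asarray(center, dtype=float)
        cov = np.asarray(cov, dtype=float)
        if center.shape != (2,) or cov.shape != (2, 2):
            raise ValueError("expected a 2-vector center and 2x2 covariance")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() <= 0:
            raise ValueError(
                "covariance is singular; add jitter or more benchmark records"
            )
        self.center = center
        self.cov = cov
        self.level = level
        self._prec = np.linalg.inv(cov)

    @property
    def radius2(self) -> float:
        """Squared Mahalanobis boundary radius: chi2.ppf(level, df=2)."""
        return float(stats.chi2.ppf(self.level, df=2))

    def mahalanobis2(self, points: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        return np.einsum("ij,jk,ik->i", d, self._prec, d)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: inside-or-on-boundary."""
        return self.mahalanobis2(points) <= self.radius2

    def boundary(self, n: int = 200) -> np.ndarray:
        """n points tracing the ellipse boundary (for plotting)."""
        theta = np.linspace(0, 2 * np.pi, n)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        L = np.linalg.cholesky(self.cov)
        return (self.center[:, None] + np.sqrt(self.radius2) * (L @ circle)).T

    def sample(self, n: int, seed: int = 0) -> np.ndarray:
        """Fresh draws from the fitted bivariate normal."""
        rng = np.random.default_rng(seed)
        return rng.multivariate_normal(self.center, self.cov, size=n)


def fit_ellipse(points: Sequence[Sequence[float]], level: float = 0.95) -> PredictionEllipse:
    """Fit a prediction ellipse to benchmark (X1, X2) records.

    Center is the sample mean, shape the sample covariance; at least three
    non-degenerate records are required.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) array of (X1, X2) points")
    if len(pts) < 3:
        raise ValueError("need at least 3 records to fit an ellipse")
    return PredictionEllipse(pts.mean(axis=0), np.cov(pts.T), level=level)


@dataclass
class AlarmResults:
    """Fitted transaction-alarm classifier with its held-out evaluation."""

    method: str
    classifier: object
    report: EvalReport
    seed: int = 0
    cv_report: EvalReport | None = None
    insample_report: EvalReport | None = None
    best_params: dict = field(default_factory=dict)

    def predict(self, features: pd.DataFrame) -> pd.Series:
        X = features[["X1", "X2"]].to_numpy(dtype=float)
        y = self.classifier.predict(X)
        return pd.Series(
            np.where(np.asarray(y) == 1, SUSPICIOUS, BENCHMARK), index=features.index
        )

    def summary(self) -> str:
        lines = [f"Transaction alarm — {self.method} on (X1, X2)", self.report.summary()]
        if self.cv_report is not None:
            lines.append("cross-validation (pooled over folds):")
            lines.append(self.cv_report.summary())
        return "\n".join(lines)


class AlarmModel:
    """Classifier on the month-level features (X1, X2) (model object).

    Trains one of the five supervised backends to separate suspicious (B)
    month records from benchmark (A) ones. Records with a missing X2 are
    dropped; clamped records are excluded from training by default because
    they are distributional outliers by construction, but are still scored at
    screening time.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: Sequence[object],
        method: str = "random_forest",
        include_clamped: bool = False,
    ) -> None:
        if method not in backends.METHODS:
            raise ValueError(f"unknown method {method!r}; expected one of {backends.METHODS}")
        feats = features.reset_index(drop=True)
        y = np.asarray(
            [1 if lab in (1, True, SUSPICIOUS, "B") else 0 for lab in labels], dtype=int
        )
        if len(feats) != len(y):
            raise ValueError("features and labels must have equal length")
        keep = ~feats["X1"].isna() & ~feats["X2"].isna()
        if "valid" in feats.columns:
            keep &= feats["valid"].astype(bool)
        if not include_clamped and "clamped" in feats.columns:
            keep &= ~feats["clamped"].astype(bool)
        self.features = feats.loc[keep]
        self.labels = y[keep.to_numpy()]
        if len(np.unique(self.labels)) < 2:
            raise ValueError(
                "both suspicious and benchmark month records are required for training"
            )
        self.method = method

    def fit(self, seed: int = 0) -> AlarmResults:
        """Seeded stratified 5-fold CV for model selection, with held-out
        metrics from pooled out-of-fold predictions and a final refit on all
        records. Both the pooled-CV and the refit in-sample reports are kept
        because published alarm tables rarely say which they print."""
        X = self.features[["X1", "X2"]].to_numpy(dtype=float)
        y = self.labels
        n_folds = min(5, int(np.bincount(y).min()))
        if n_folds < 2:
            raise ValueError("smallest class has fewer than 2 records; cannot cross-validate")
        from sklearn.model_selection import StratifiedKFold, cross_val_predict

        search = backends.grid_search(self.method, seed=seed, n_folds=n_folds)
        search.fit(X, y)
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        y_oof = cross_val_predict(search.best_estimator_, X, y, cv=cv)
        cv_report = report_from_predictions(y, y_oof, positive=1, method=self.method, seed=seed)
        y_in = search.best_estimator_.predict(X)
        insample = report_from_predictions(y, y_in, positive=1, method=self.method, seed=seed)
        return AlarmResults(
            method=self.method,
            classifier=search.best_estimator_,
            report=cv_report,
            cv_report=cv_report,
            insample_report=insample,
            seed=seed,
            best_params=dict(search.best_params_),
        )


def train_alarm_classifier(
    features: pd.DataFrame,
    labels: Sequence[object],
    method: str = "random_forest",
    seed: int = 0,
) -> tuple[AlarmResults, EvalReport]:
    """Functional wrapper over :class:`AlarmModel`."""
    results = AlarmModel(features, labels, method=method).fit(seed=seed)
    return results, results.report


@dataclass
class AlarmReport:
    """Screening outcome over unlabeled manufacturers."""

    month_labels: pd.DataFrame  # manufacturer_id, month, label, partial
    flagged_manufacturers: list[str]
    flagged_fraction: float  # fraction of scored months labeled suspicious
    provenance: str
    min_suspicious_months: int = 1

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "min_suspicious_months": self.min_suspicious_months,
            "n_months_scored": int(len(self.month_labels)),
            "flagged_fraction": self.flagged_fraction,
            "n_flagged_manufacturers": len(self.flagged_manufacturers),
            "flagged_manufacturers": list(self.flagged_manufacturers),
        }


def screen_unlabeled(
    features: pd.DataFrame,
    model: AlarmResults | DecisionRule,
    min_suspicious_months: int = 1,
) -> AlarmReport:
    """Score every unlabeled manufacturer-month and aggregate to manufacturers.

    A manufacturer is flagged iff at least ``min_suspicious_months`` of its
    months are labeled suspicious. Invalid records (no money flow at all) are
    excluded from scoring; records with missing X2 are labeled benchmark and
    marked ``partial``.
    """
    if features.empty:
        return AlarmReport(
            month_labels=pd.DataFrame(columns=["manufacturer_id", "month", "label", "partial"]),
            flagged_manufacturers=[],
            flagged_fraction=0.0,
            provenance=_provenance(model),
            min_suspicious_months=min_suspicious_months,
        )
    feats = features.reset_index(drop=True)
    if "valid" in feats.columns:
        feats = feats.loc[feats["valid"].astype(bool)].reset_index(drop=True)
    partial = feats["X2"].isna().to_numpy()
    if isinstance(model, DecisionRule):
        labels = model.apply(feats)
    else:
        labels = pd.Series(BENCHMARK, index=feats.index)
        scored = ~partial & ~feats["X1"].isna().to_numpy()
        if scored.any():
            labels.loc[scored] = model.predict(feats.loc[scored]).to_numpy()
    out = pd.DataFrame(
        {
            "manufacturer_id": feats["manufacturer_id"],
            "month": feats["month"].astype(str),
            "label": labels.to_numpy(),
            "partial": partial,
        }
    )
    counts = out[out["label"] == SUSPICIOUS].groupby("manufacturer_id").size()
    flagged = sorted(counts[counts >= min_suspicious_months].index)
    frac = float((out["label"] == SUSPICIOUS).mean()) if len(out) else 0.0
    return AlarmReport(
        month_labels=out,
        flagged_manufacturers=flagged,
        flagged_fraction=frac,
        provenance=_provenance(model),
        min_suspicious_months=min_suspicious_months,
    )


def _provenance(model) -> str:
    if isinstance(model, DecisionRule):
        return f"rule(t1={model.t1}, t2={model.t2})"
    return f"classifier({model.method}, seed={model.seed})"


def plot_features(
    features_by_class: dict[str, pd.DataFrame],
    levels: Sequence[float] = (0.95, 0.99),
    benchmark_class: str = "A",
    path: str | None = None,
):
    """Scatter of (X1, X2) by manufacturer class with prediction ellipses
    fitted to the benchmark class. Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    markers = {"A": "o", "B": "s", "C": "^"}
    for cls, df in features_by_class.items():
        d = df.dropna(subset=["X1", "X2"])
        ax.scatter(d["X1"], d["X2"], s=14, alpha=0.6, label=cls, marker=markers.get(cls, "x"))
    bench = features_by_class.get(benchmark_class)
    if bench is not None:
        pts = bench.dropna(subset=["X1", "X2"])[["X1", "X2"]].to_numpy()
        if "clamped" in bench.columns:
            pts = bench.dropna(subset=["X1", "X2"]).loc[
                ~bench.dropna(subset=["X1", "X2"])["clamped"].astype(bool), ["X1", "X2"]
            ].to_numpy()
        if len(pts) >= 3:
            for lev in levels:
                b = fit_ellipse(pts, level=lev).boundary()
                ax.plot(b[:, 0], b[:, 1], lw=1, label=f"{int(lev * 100)}% region")
    ax.set_xlabel("X1 = ln(U_i / D_i)")
    ax.set_ylabel("X2 = ln(U_i / D_{i-1})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
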