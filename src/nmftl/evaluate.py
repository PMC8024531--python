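"""Metrics, the two evaluation protocols, and multi-method rank tests.

Scenario 1 evaluates a pipeline under matched distributions with stratified
k-fold cross-validation.  Scenario 2 evaluates transfer between two
differently-distributed domains: per round a classifier is fitted
source-to-target and another on the swapped pair, the two directions are
averaged, and the round is repeated with fresh seeded resamples.

Method comparison across datasets uses the Friedman rank test

    chi2_F = 12 N / (k (k+1)) * sum_j (Rbar_j - (k+1)/2)^2

(k methods, N datasets, Rbar_j the mean rank of method j; rank 1 = best,
ties get average ranks) followed by the Nemenyi post-hoc: two methods
differ significantly when their mean ranks differ by more than the
critical difference CD = q_alpha(k) * sqrt(k (k+1) / (6 N)).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skm
from sklearn.model_selection import StratifiedKFold

from .io import FeatureMatrix

__all__ = [
    "MetricSet",
    "ComparisonReport",
    "classification_metrics",
    "run_scenario1",
    "run_scenario2",
    "friedman_statistic",
    "nemenyi_cd",
    "compare_methods",
]


@dataclass
class MetricSet:
    """Accuracy plus positive-class precision/recall/F1.

    For multiclass problems the headline precision/recall/F1 are
    macro-averaged over one-vs-rest treatments and ``per_class`` carries
    the per-label breakdown.  Precision is 0 when nothing is predicted
    positive (hence F1 = 0), by convention.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


def classification_metrics(
    y_true, y_pred, positive_class=None
) -> MetricSet:
    """Accuracy and positive-class (or macro) precision/recall/F1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    accuracy = float(_skm.accuracy_score(y_true, y_pred))
    per_class = {}
    for lab in labels:
        p, r, f, _ = _skm.precision_recall_fscore_support(
            y_true == lab, y_pred == lab, average="binary", zero_division=0
        )
        per_class[str(lab)] = {
            "precision": float(p),
            "recall": float(r),
            "f1": float(f),
        }
    if len(labels) == 2:
        if positive_class is None:
            positive_class = labels[1]
        elif positive_class not in labels:
            raise ValueError(f"positive_class {positive_class!r} not in labels")
        stats_ = per_class[str(positive_class)]
        return MetricSet(
            accuracy=accuracy,
            precision=stats_["precision"],
            recall=stats_["recall"],
            f1=stats_["f1"],
            per_class=per_class,
        )
    macro = {
        key: float(np.mean([per_class[str(l)][key] for l in labels]))
        for key in ("precision", "recall", "f1")
    }
    return MetricSet(
        accuracy=accuracy,
        precision=macro["precision"],
        recall=macro["recall"],
        f1=macro["f1"],
        per_class=per_class,
    )


def _mean_metrics(parts: list[MetricSet]) -> MetricSet:
    return MetricSet(
        accuracy=float(np.mean([m.accuracy for m in parts])),
        precision=float(np.mean([m.precision for m in parts])),
        recall=float(np.mean([m.recall for m in parts])),
        f1=float(np.mean([m.f1 for m in parts])),
    )


def _fit(estimator, X, y, X_target):
    """Fit an estimator, passing the target matrix when supported."""
    try:
        estimator.fit(X, y, X_target=X_target)
    except TypeError:
        estimator.fit(X, y)
    return estimator


def run_scenario1(
    data: FeatureMatrix,
    pipeline_factory,
    folds: int = 10,
    seed: int = 0,
    positive_class=None,
) -> MetricSet:
    """Matched-distribution protocol: stratified k-fold cross-validation.

    Per fold a fresh pipeline from ``pipeline_factory()`` is fitted on the
    training fold (the held-out fold's features are exposed as the target
    domain for transductive subspace learning) and scored on the held-out
    fold; metrics are averaged over folds.
    """
    if data.labels is None:
        raise ValueError("scenario 1 requires labeled data")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = data.labels
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"every class needs >= {folds} members for {folds}-fold CV"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = []
    for train_idx, test_idx in skf.split(data.values, y):
        est = pipeline_factory()
        _fit(est, data.values[train_idx], y[train_idx], data.values[test_idx])
        y_pred = est.predict(data.values[test_idx])
        per_fold.append(
            classification_metrics(y[test_idx], y_pred, positive_class)
        )
    return _mean_metrics(per_fold)


def _stratified_subsample(
    rng: np.random.Generator, y: np.ndarray, fraction: float
) -> np.ndarray:
    idx = []
    for lab in np.unique(y):
        members = np.flatnonzero(y == lab)
        take = max(1, int(round(fraction * members.size)))
        idx.append(rng.choice(members, size=take, replace=False))
    return np.sort(np.concatenate(idx))


def run_scenario2(
    source: FeatureMatrix,
    target: FeatureMatrix,
    pipeline_factory,
    rounds: int = 10,
    seed: int = 0,
    train_fraction: float = 0.75,
    test_fraction: float = 0.25,
    positive_class=None,
) -> MetricSet:
    """Distribution-shift protocol: seeded swap rounds.

    Per round: a stratified ``train_fraction`` subsample of the source
    trains a pipeline scored on a stratified ``test_fraction`` subsample of
    the target; then the roles are swapped for a second fit; the round's
    metrics average both directions (two fits per round, so ``rounds=10``
    performs exactly 20 fits).  Final metrics average the rounds.
    """
    if source.labels is None or target.labels is None:
        raise ValueError("scenario 2 scores target predictions: both domains must be labeled")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    rng = np.random.default_rng(seed)
    per_round = []
    for _ in range(rounds):
        directions = []
        for dom_train, dom_test in ((source, target), (target, source)):
            tr = _stratified_subsample(rng, dom_train.labels, train_fraction)
            te = _stratified_subsample(rng, dom_test.labels, test_fraction)
            X_tr, y_tr = dom_train.values[tr], dom_train.labels[tr]
            X_te, y_te = dom_test.values[te], dom_test.labels[te]
            est = _fit(pipeline_factory(), X_tr, y_tr, X_te)
            directions.append(
                classification_metrics(y_te, est.predict(X_te), positive_class)
            )
        per_round.append(_mean_metrics(directions))
    return _mean_metrics(per_round)


def friedman_statistic(
    scores: np.ndarray,
) -> tuple[float, float, np.ndarray]:
    """Friedman rank test over a k-methods x N-datasets score matrix.

    Higher scores rank better (rank 1 = best); ties receive average ranks.
    Returns the chi-square statistic, its p-value (k-1 degrees of freedom),
    and the per-method mean ranks.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a 2-D methods x datasets matrix")
    k, N = scores.shape
    if k < 2 or N < 2:
        raise ValueError("need at least 2 methods and 2 datasets")
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores matrix has missing or non-finite cells")
    # rank within each dataset column; negate so the best score gets rank 1
    ranks = np.column_stack(
        [stats.rankdata(-scores[:, j]) for j in range(N)]
    )
    mean_ranks = ranks.mean(axis=1)
    stat = 12.0 * N / (k * (k + 1)) * float(
        np.sum((mean_ranks - (k + 1) / 2.0) ** 2)
    )
    p = float(stats.chi2.sf(stat, df=k - 1))
    return stat, p, mean_ranks


#: Critical values q_alpha(k) of the Nemenyi test (studentized range based,
#: infinite degrees of freedom, divided by sqrt(2)), k = 2..10.
_NEMENYI_Q = {
    0.05: [1.960, 2.343, 2.569, 2.728, 2.850, 2.949, 3.031, 3.102, 3.164],
    0.10: [1.645, 2.052, 2.291, 2.459, 2.589, 2.693, 2.780, 2.855, 2.920],
}


def nemenyi_cd(k: int, N: int, alpha: float = 0.05) -> float:
    """Nemenyi critical difference for k methods on N datasets.

    Two methods differ significantly at level ``alpha`` iff their mean
    ranks differ by more than ``CD = q_alpha(k) * sqrt(k (k+1) / (6 N))``.
    Only alpha in {0.05, 0.10} is tabulated, for k up to 10.
    """
    if alpha not in _NEMENYI_Q:
        raise ValueError("alpha must be 0.05 or 0.10 (tabulated values)")
    if not (2 <= k <= 10):
        raise ValueError("q values tabulated for 2 <= k <= 10")
    if N < 1:
        raise ValueError("N must be >= 1")
    q = _NEMENYI_Q[alpha][k - 2]
    return q * float(np.sqrt(k * (k + 1) / (6.0 * N)))


@dataclass
class ComparisonReport:
    """Per-method scores across datasets plus the Friedman/Nemenyi summary."""

    methods: list[str]
    datasets: list[str]
    scores: np.ndarray  # k x N
    mean_ranks: np.ndarray
    friedman_stat: float
    friedman_p: float
    nemenyi_cd: float
    alpha: float = 0.05

    def significant_pairs(self) -> list[tuple[str, str]]:
        """Method pairs whose mean-rank gap exceeds the critical difference."""
        pairs = []
        for i in range(len(self.methods)):
            for j in range(i + 1, len(self.methods)):
                if abs(self.mean_ranks[i] - self.mean_ranks[j]) > self.nemenyi_cd:
                    pairs.append((self.methods[i], self.methods[j]))
        return pairs

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.scores, index=self.methods, columns=self.datasets
        )
        frame["mean_rank"] = self.mean_ranks
        return frame

    def save(self, directory: str | Path) -> None:
        """Write scores + ranks as CSV and the statistics as JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "scores.csv")
        summary = {
            "friedman_stat": self.friedman_stat,
            "friedman_p": self.friedman_p,
            "nemenyi_cd": self.nemenyi_cd,
            "alpha": self.alpha,
            "mean_ranks": dict(
                zip(self.methods, map(float, self.mean_ranks))
            ),
            "significant_pairs": self.significant_pairs(),
        }
        (directory / "comparison.json").write_text(
            json.dumps(summary, indent=2)
        )


def compare_methods(
    scores: pd.DataFrame | np.ndarray,
    methods: list[str] | None = None,
    datasets: list[str] | None = None,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Build a ComparisonReport from a methods-by-datasets score table."""
    if isinstance(scores, pd.DataFrame):
        methods = list(scores.index)
        datasets = list(scores.columns)
        values = scores.to_numpy(dtype=float)
    else:
        values = np.asarray(scores, dtype=float)
        methods = methods or [f"method{i}" for i in range(values.shape[0])]
        datasets = datasets or [f"dataset{j}" for j in range(values.shape[1])]
    stat, p, mean_ranks = friedman_statistic(values)
    cd = nemenyi_cd(values.shape[0], values.shape[1], alpha=alpha)
    return ComparisonReport(
        methods=methods,
        datasets=datasets,
        scores=values,
        mean_ranks=mean_ranks,
        friedman_stat=stat,
        friedman_p=p,
        nemenyi_cd=cd,
        alpha=alpha,
    )
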