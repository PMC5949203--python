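"""Classification of regional-synchrony feature vectors and its evaluation.

Subjects are labelled positive (cochlear-implanted) or negative (non-implanted
control).  Two classifiers: k-nearest neighbours (k = 1 by default, Euclidean
distance) and a soft-margin kernel SVM.  Evaluation uses a repeated balanced
hold-out: each repeat draws a uniform random test set of 3 positives and 3
negatives, trains on the remainder, and scores accuracy, recall, precision
and F1; means and standard deviations over repeats are reported.

Features are standardized to zero mean / unit variance using training-set
statistics only (no leakage); a flag disables this for a strict
raw-feature mode.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import InvalidParameterError, InvalidStateError

logger = logging.getLogger(__name__)

METRICS = ("accuracy", "recall", "precision", "f1")


@dataclass
class LabeledCohort:
    """Feature matrix plus binary labels (1 = positive/implanted)."""

    features: np.ndarray
    labels: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise InvalidParameterError("features must be 2-D (subjects x features)")
        if len(self.labels) != len(self.features):
            raise InvalidParameterError("labels/features length mismatch")
        if not np.isfinite(self.features).all():
            raise InvalidParameterError("features contain missing or non-finite values")
        if not self.subject_ids:
            self.subject_ids = [f"S{i:02d}" for i in range(len(self.labels))]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledCohort":
        """Build from a feature table with ``subject`` and ``group`` columns."""
        feats = df.drop(columns=[c for c in ("subject", "group") if c in df.columns])
        return cls(
            features=feats.to_numpy(dtype=np.float64),
            labels=df["group"].to_numpy(dtype=int),
            subject_ids=[str(s) for s in df.get("subject", pd.RangeIndex(len(df)))],
        )

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())


def _standardize(train_X: np.ndarray, test_X: np.ndarray):
    scaler = StandardScaler().fit(train_X)
    return scaler.transform(train_X), scaler.transform(test_X)


def knn_predict(
    train: LabeledCohort, test_features: np.ndarray, k: int = 1, standardize: bool = True
) -> np.ndarray:
    """Majority label of the k nearest training points under Euclidean distance.

    k must be odd (even k invites trivial vote ties) and at most the training
    size.
    """
    if k % 2 == 0:
        raise InvalidParameterError(f"k must be odd, got {k}")
    if k > len(train.labels):
        raise InvalidParameterError(f"k = {k} exceeds training size {len(train.labels)}")
    test_X = np.atleast_2d(np.asarray(test_features, dtype=np.float64))
    train_X = train.features
    if standardize:
        train_X, test_X = _standardize(train_X, test_X)
    clf = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    clf.fit(train_X, train.labels)
    return clf.predict(test_X)


def svm_predict(
    train: LabeledCohort,
    test_features: np.ndarray,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: float | str = "median",
    standardize: bool = True,
) -> np.ndarray:
    """Soft-margin kernel SVM decision on held-out points.

    ``gamma="median"`` sets the RBF bandwidth by the median heuristic,
    gamma = 1 / (2 * median^2) over pairwise training distances, computed on
    the (train-only) standardized features.
    """
    if len(np.unique(train.labels)) < 2:
        raise InvalidStateError("SVM training set must contain both classes")
    test_X = np.atleast_2d(np.asarray(test_features, dtype=np.float64))
    train_X = train.features
    if standardize:
        train_X, test_X = _standardize(train_X, test_X)
    if gamma == "median":
        d = np.sqrt(
            np.maximum(
                ((train_X[:, None, :] - train_X[None, :, :]) ** 2).sum(-1), 0.0
            )
        )
        med = np.median(d[np.triu_indices(len(train_X), 1)])
        gamma = 1.0 / (2.0 * med**2) if med > 0 else "scale"
    clf = SVC(kernel=kernel, C=C, gamma=gamma if kernel == "rbf" else "scale")
    clf.fit(train_X, train.labels)
    return clf.predict(test_X)


@dataclass
class MetricSet:
    """Confusion counts and the four derived metrics for one evaluation."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    recall: float
    precision: float
    f1: float


def evaluate(pred: np.ndarray, truth: np.ndarray) -> MetricSet:
    """Confusion counts and accuracy/recall/precision/F1.

    Positive = implanted (label 1).  Zero-denominator metrics are defined as
    0 and logged, so all-negative predictions yield recall = precision = 0
    rather than an error.
    """
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise InvalidParameterError("pred/truth length mismatch")
    tp = int(((pred == 1) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.debug("evaluate: %s denominator is 0; defining metric as 0", name)
            return 0.0
        return num / den

    accuracy = safe(tp + tn, tp + tn + fp + fn, "accuracy")
    recall = safe(tp, tp + fn, "recall")
    precision = safe(tp, tp + fp, "precision")
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return MetricSet(tp, tn, fp, fn, accuracy, recall, precision, f1)


@dataclass
class EvalReport:
    """Per-repeat metrics and their summary for one measure/classifier run."""

    per_repeat: pd.DataFrame
    seed: int
    classifier: str
    measure: str = ""
    partition: str = ""

    @property
    def summary(self) -> dict[str, dict[str, float]]:
        return {
            m: {
                "mean": float(self.per_repeat[m].mean()),
                "std": float(self.per_repeat[m].std(ddof=0)),
                "var": float(self.per_repeat[m].var(ddof=0)),
            }
            for m in METRICS
        }

    def mean(self, metric: str = "accuracy") -> float:
        return float(self.per_repeat[metric].mean())

    def std(self, metric: str = "accuracy") -> float:
        return float(self.per_repeat[metric].std(ddof=0))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classifier": self.classifier,
            "measure": self.measure,
            "partition": self.partition,
            "seed": self.seed,
            "summary": self.summary,
            "per_repeat": self.per_repeat.to_dict(orient="list"),
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def summary_row(self) -> dict:
        """One table row: measure x classifier x partition with mean (std)."""
        row: dict = {
            "partition": self.partition,
            "measure": self.measure,
            "classifier": self.classifier,
        }
        for m in METRICS:
            row[m] = self.mean(m)
            row[f"{m}_std"] = self.std(m)
        return row


def _predict(
    classifier: str,
    train: LabeledCohort,
    test_X: np.ndarray,
    params: dict,
) -> np.ndarray:
    if classifier == "knn":
        return knn_predict(train, test_X, **params)
    if classifier == "svm":
        return svm_predict(train, test_X, **params)
    raise InvalidParameterError(f"unknown classifier {classifier!r}; choose 'knn' or 'svm'")


def repeated_holdout(
    cohort: LabeledCohort,
    n_pos_test: int = 3,
    n_neg_test: int = 3,
    repeats: int = 100,
    classifier: str = "knn",
    classifier_params: dict | None = None,
    seed: int = 0,
    measure: str = "",
    partition: str = "",
) -> EvalReport:
    """Repeated balanced hold-out evaluation.

    Each repeat draws ``n_pos_test`` positives and ``n_neg_test`` negatives
    uniformly without replacement as the test set (3 + 3 by default, leaving
    a training set of 19 on a 17 + 8 cohort), trains on the remainder and
    evaluates.  A single seed derives independent per-repeat substreams, so
    reports are bit-reproducible.
    """
    if classifier not in ("knn", "svm"):
        raise InvalidParameterError(f"unknown classifier {classifier!r}")
    pos = np.where(cohort.labels == 1)[0]
    neg = np.where(cohort.labels == 0)[0]
    if len(pos) < n_pos_test + 1 or len(neg) < n_neg_test + 1:
        raise InvalidStateError(
            f"cohort too small: {len(pos)} positives / {len(neg)} negatives "
            f"for a {n_pos_test}+{n_neg_test} hold-out"
        )
    params = dict(classifier_params or {})
    streams = np.random.SeedSequence(seed).spawn(repeats)
    rows = []
    for rep, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        test_idx = np.concatenate([
            rng.choice(pos, n_pos_test, replace=False),
            rng.choice(neg, n_neg_test, replace=False),
        ])
        train_mask = np.ones(len(cohort.labels), dtype=bool)
        train_mask[test_idx] = False
        train = LabeledCohort(
            features=cohort.features[train_mask],
            labels=cohort.labels[train_mask],
            subject_ids=[s for s, m in zip(cohort.subject_ids, train_mask) if m],
        )
        pred = _predict(classifier, train, cohort.features[test_idx], params)
        ms = evaluate(pred, cohort.labels[test_idx])
        rows.append(
            {
                "repeat": rep,
                "tp": ms.tp, "tn": ms.tn, "fp": ms.fp, "fn": ms.fn,
                "accuracy": ms.accuracy, "recall": ms.recall,
                "precision": ms.precision, "f1": ms.f1,
            }
        )
    return EvalReport(
        per_repeat=pd.DataFrame(rows),
        seed=seed,
        classifier=classifier,
        measure=measure,
        partition=partition,
    )
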