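"""Stratified cross-validation benchmark over fingerprint feature sets.

Binary BBB-permeation labels, k-fold stratified CV (k = 5 by default), and
four model families: a uniform-random dummy baseline, an RBF-kernel SVM, a
random forest, and a Bernoulli naive Bayes (appropriate for binary bit
features).  The metric suite is the standard confusion-matrix set —

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    MCC       = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

— plus AUROC in its rank (Mann-Whitney) formulation.  Any metric whose
denominator vanishes is reported as 0 and flagged degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import BernoulliNB
from sklearn.svm import SVC

from .types import BitFingerprint, ConfusionCounts, MetricReport

DEFAULT_MODELS = ("dummy", "svm", "rf", "nb")


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_index: tuple[int, ...]  # fold id per sample position
    seed: int

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        idx = np.asarray(self.fold_index)
        test = np.where(idx == fold)[0]
        train = np.where(idx != fold)[0]
        return train, test


def stratified_folds(labels: Sequence[int], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Deterministic stratified k-fold assignment.

    Members of each class are shuffled (seeded) and dealt cyclically into
    folds, with the starting fold rotating between classes so fold sizes
    stay balanced; per-fold class counts differ by at most one from
    proportional allocation.  Classes smaller than k are allowed — some
    folds then simply contain none of that class.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(labels)
    if len(y) < k:
        raise ValueError("fewer samples than folds")
    rng = np.random.default_rng(seed)
    fold_index = np.empty(len(y), dtype=int)
    offset = 0
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        for j, sample in enumerate(idx):
            fold_index[sample] = (offset + j) % k
        offset = (offset + len(idx)) % k
    return FoldAssignment(k, tuple(int(i) for i in fold_index), seed)


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    yt, yp = np.asarray(y_true), np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> MetricReport:
    """Confusion-matrix metric suite; zero denominators -> 0 with a flag."""
    if c.total < 1:
        raise ValueError("need at least one sample")
    degenerate = []

    accuracy = (c.tp + c.tn) / c.total

    if c.tp + c.fp:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision = 0.0
        degenerate.append("precision")
    if c.tp + c.fn:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall = 0.0
        degenerate.append("recall")
    if precision + recall:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        degenerate.append("f1")

    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    else:
        mcc = 0.0
        degenerate.append("mcc")

    return MetricReport(accuracy, precision, recall, f1, mcc, None, tuple(degenerate))


def auroc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Probability a random positive outscores a random negative (ties = 1/2)."""
    yt = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int((yt == 1).sum())
    n_neg = int((yt == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties
    r_pos = ranks[yt == 1].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def concat_features(fps: Sequence[BitFingerprint]) -> BitFingerprint:
    """Concatenate fingerprints for one molecule; bits offset cumulatively."""
    if not fps:
        raise ValueError("nothing to concatenate")
    offset = 0
    bits: list[int] = []
    schema = "+".join(fp.schema_id for fp in fps)
    for fp in fps:
        bits.extend(b + offset for b in fp.set_bits)
        offset += fp.length
    return BitFingerprint.from_bits(schema, offset, bits)


def _make_model(name: str, seed: int):
    if name == "dummy":
        return DummyClassifier(strategy="uniform", random_state=seed)
    if name == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if name == "rf":
        return RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    if name == "nb":
        return BernoulliNB()
    raise ValueError(f"unknown model {name}")


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(X)[:, 1]
        except AttributeError:  # pragma: no cover
            pass
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    return model.predict(X).astype(float)


@dataclass
class BenchmarkResult:
    """Per (feature set, model, fold, split) metric reports plus their means."""

    records: pd.DataFrame  # long format: feature_set, model, fold, split, metric, value

    def mean_table(self) -> pd.DataFrame:
        """Mean over folds; rows (model, feature_set), columns split/metric."""
        g = (
            self.records.groupby(["model", "feature_set", "split", "metric"])["value"]
            .mean()
            .unstack(["split", "metric"])
        )
        return g

    def mean(self, feature_set: str, model: str, metric: str, split: str = "test") -> float:
        df = self.records
        m = df[
            (df.feature_set == feature_set)
            & (df.model == model)
            & (df.metric == metric)
            & (df.split == split)
        ]
        return float(m["value"].mean())


def run_benchmark(
    features: Mapping[str, np.ndarray],
    labels: Sequence[int],
    models: Sequence[str] = DEFAULT_MODELS,
    k: int = 5,
    seed: int = 0,
    folds: Optional[FoldAssignment] = None,
) -> BenchmarkResult:
    """Train/evaluate every feature set x model over stratified folds.

    ``features`` maps a feature-set name to a dense (n_samples, n_bits)
    array aligned with ``labels``.  Each fold serves once as the test set;
    train and test metrics are recorded per fold.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes")
    for name, X in features.items():
        X = np.asarray(X)
        if X.shape[0] != len(y):
            raise ValueError(f"feature set {name} not aligned with labels")
        if not np.isfinite(X).all():
            raise ValueError(f"feature set {name} contains non-finite values")
    folds = folds or stratified_folds(y, k=k, seed=seed)

    rows = []
    for fset_name, X in features.items():
        X = np.asarray(X, dtype=float)
        for model_name in models:
            for fold in range(folds.k):
                train, test = folds.split(fold)
                assert len(np.intersect1d(train, test)) == 0, "fold leakage"
                model = _make_model(model_name, seed)
                model.fit(X[train], y[train])
                for split, idx in (("train", train), ("test", test)):
                    pred = model.predict(X[idx])
                    rep = metrics(confusion(y[idx], pred))
                    try:
                        auc = auroc(y[idx], _scores(model, X[idx]))
                    except ValueError:
                        auc = float("nan")
                    for metric_name, value in (
                        ("accuracy", rep.accuracy),
                        ("precision", rep.precision),
                        ("recall", rep.recall),
                        ("f1", rep.f1),
                        ("mcc", rep.mcc),
                        ("auroc", auc),
                    ):
                        rows.append(
                            (fset_name, model_name, fold, split, metric_name, value)
                        )
    df = pd.DataFrame(
        rows, columns=["feature_set", "model", "fold", "split", "metric", "value"]
    )
    return BenchmarkResult(df)
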