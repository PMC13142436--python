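"""Full-protein classification harness.

Binary protein classification (condensate-proximal proteome member vs
whole-cell-only) from fixed-length embedding vectors, evaluated over repeated
random protein-level 70/30 train/test splits. The model is a two-stage
pipeline: an L1-penalised linear stage selects features (nonzero
coefficients), then an L2-penalised logistic regression is fit on the
retained features. Standardisation parameters are estimated on the training
fold only — test items never influence selection or scaling.

Performance is the ROC AUC — the probability that a random positive outscores
a random negative, ties counted one half, identical to the Mann-Whitney U
statistic divided by n_pos * n_neg — summarised over splits by the median and
the 16th/84th percentiles (linear-interpolation percentile definition).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

__all__ = [
    "EmbeddingSet", "SplitPlan", "TrainedModel", "AUCSummary",
    "read_embeddings", "write_embeddings",
    "make_splits", "fit_pipeline", "roc_auc", "evaluate",
    "baseline_single_feature",
]

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingSet:
    """Item id -> fixed-length vector, with a binary label per item."""

    ids: List[str]
    X: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("item ids must be unique")
        if self.X.ndim != 2 or self.X.shape[0] != len(self.ids):
            raise ValueError("X must be (n_items, dim)")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.ids)


def read_embeddings(path) -> EmbeddingSet:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    vec_cols = [c for c in df.columns if c not in ("id", "label")]
    return EmbeddingSet(ids=list(df["id"]),
                        X=df[vec_cols].to_numpy(dtype=float),
                        labels=df["label"].to_numpy(dtype=int))


def write_embeddings(emb: EmbeddingSet, path) -> None:
    df = pd.DataFrame(emb.X, columns=[f"v{i}" for i in range(emb.X.shape[1])])
    df.insert(0, "label", emb.labels)
    df.insert(0, "id", emb.ids)
    df.to_csv(path, sep="\t", index=False)


@dataclass
class SplitPlan:
    """Reproducible item-level train/test splits."""

    splits: List[Tuple[np.ndarray, np.ndarray]]
    seed: int
    train_frac: float

    @property
    def n_splits(self) -> int:
        return len(self.splits)


def make_splits(items: Sequence, labels: Sequence[int], n_splits: int = 20,
                train_frac: float = 0.7, seed: int = 0,
                stratified: bool = False, max_retries: int = 100) -> SplitPlan:
    """Random item-level splits, train size = round(train_frac * n).

    Unstratified by default. A draw that leaves either class empty in the
    train or the test fold is resampled (bounded retries) so every split can
    be both fit and scored.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if n != len(items):
        raise ValueError("items and labels lengths differ")
    for cls in (0, 1):
        if (labels == cls).sum() < 2:
            raise ValueError("need at least 2 items in each class")
    n_train = int(round(train_frac * n))
    if n_train < 1 or n_train >= n:
        raise ValueError("train_frac leaves an empty fold")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        if stratified:
            train_idx = []
            for cls in (0, 1):
                cls_idx = np.flatnonzero(labels == cls)
                k = int(round(train_frac * len(cls_idx)))
                k = min(max(k, 1), len(cls_idx) - 1)
                train_idx.append(rng.choice(cls_idx, size=k, replace=False))
            train = np.sort(np.concatenate(train_idx))
            test = np.setdiff1d(np.arange(n), train)
            splits.append((train, test))
            continue
        for _attempt in range(max_retries):
            perm = rng.permutation(n)
            train, test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
            if (len(np.unique(labels[train])) == 2
                    and len(np.unique(labels[test])) == 2):
                splits.append((train, test))
                break
        else:
            raise RuntimeError(
                "could not draw a split with both classes in both folds")
    return SplitPlan(splits=splits, seed=seed, train_frac=train_frac)


@dataclass
class TrainedModel:
    """Standardiser + feature mask + ridge-logistic head, fit on training data only."""

    mean: np.ndarray
    scale: np.ndarray
    selected: np.ndarray          # boolean mask over input features
    clf: LogisticRegression
    n_features_in: int
    l1_strength: float
    l2_strength: float

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in:
            raise ValueError(
                f"expected {self.n_features_in} features, got {X.shape[1]}")
        Z = (X - self.mean) / self.scale
        return self.clf.predict_proba(Z[:, self.selected])[:, 1]


def fit_pipeline(train_vectors: np.ndarray, train_labels: Sequence[int],
                 l1_strength: float = 1.0,
                 l2_strength: float = 1.0) -> TrainedModel:
    """L1 feature selection followed by L2-regularised logistic regression.

    ``l1_strength`` / ``l2_strength`` are the inverse-regularisation C of the
    two stages (larger = weaker penalty; a very large l1_strength drives the
    selector to keep every feature). Should the L1 stage zero out everything,
    the pipeline falls back to all features with a logged warning.
    """
    X = np.asarray(train_vectors, dtype=float)
    y = np.asarray(train_labels, dtype=int)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("train_vectors must be (n_items, dim)")
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present in training data")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    selector = LogisticRegression(l1_ratio=1.0, C=l1_strength,
                                  solver="liblinear", max_iter=2000,
                                  random_state=0)
    selector.fit(Z, y)
    selected = np.abs(selector.coef_[0]) > 0
    if not selected.any():
        logger.warning("L1 stage selected zero features; falling back to all "
                       "%d features", X.shape[1])
        selected = np.ones(X.shape[1], dtype=bool)
    clf = LogisticRegression(l1_ratio=0.0, C=l2_strength, solver="lbfgs",
                             max_iter=5000)
    clf.fit(Z[:, selected], y)
    return TrainedModel(mean=mean, scale=scale, selected=selected, clf=clf,
                        n_features_in=X.shape[1], l1_strength=l1_strength,
                        l2_strength=l2_strength)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """P(random positive outscores random negative), ties counted 1/2.

    Computed from midranks, so it equals the Mann-Whitney U statistic of the
    positive group divided by n_pos * n_neg.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute ROC AUC")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class AUCSummary:
    """Per-split ROC AUCs with median and 16th/84th percentile summaries."""

    aucs: np.ndarray
    median: float
    p16: float
    p84: float

    @classmethod
    def from_aucs(cls, aucs: Sequence[float]) -> "AUCSummary":
        aucs = np.asarray(aucs, dtype=float)
        p16, med, p84 = np.percentile(aucs, [16, 50, 84])
        return cls(aucs=aucs, median=float(med), p16=float(p16), p84=float(p84))


def evaluate(embeddings: EmbeddingSet, plan: SplitPlan,
             l1_strength: float = 1.0, l2_strength: float = 1.0) -> AUCSummary:
    """Fit the pipeline on each training fold and score AUC on its test fold."""
    aucs = []
    for i, (train, test) in enumerate(plan.splits):
        try:
            model = fit_pipeline(embeddings.X[train], embeddings.labels[train],
                                 l1_strength=l1_strength,
                                 l2_strength=l2_strength)
            scores = model.predict_score(embeddings.X[test])
            aucs.append(roc_auc(scores, embeddings.labels[test]))
        except Exception as exc:
            raise RuntimeError(f"split {i} failed: {exc}") from exc
    return AUCSummary.from_aucs(aucs)


def baseline_single_feature(values: Sequence[float], labels: Sequence[int],
                            plan: SplitPlan, **kwargs) -> AUCSummary:
    """The same harness run on one feature (e.g. log10 protein abundance)."""
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    emb = EmbeddingSet(ids=[f"item{i}" for i in range(len(values))],
                       X=values, labels=np.asarray(labels, dtype=int))
    return evaluate(emb, plan, **kwargs)
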