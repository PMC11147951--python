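"""Random-forest classifier separating nucleosomal from linker DNA.

The positive class (label 1) is nucleosomal DNA — 147-bp stretches that a
histone octamer consistently occupies; the negative class (label 0) is linker
DNA.  Training operates on the 288 PSD features of :mod:`nfscore.spectral`.

"Default parameters" of the classic random-forest implementation are pinned
explicitly: 500 trees, floor(sqrt(288)) = 16 candidate features per split,
unlimited depth, no class weighting.  A model's prediction probability is the
fraction of trees voting nucleosomal; ties at 0.5 classify as nucleosomal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .spectral import FEATURE_NAMES

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 500
MODEL_FORMAT_VERSION = 1

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1", "auc", "mcc")


@dataclass
class LabeledSet:
    """An (n x 288) feature matrix with binary labels and per-row ids."""

    features: pd.DataFrame
    labels: np.ndarray
    ids: list

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.features) == len(self.labels) == len(self.ids)):
            raise ValueError("features, labels and ids disagree in length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class NFModel:
    """A fitted tree ensemble plus the metadata needed to reproduce it."""

    forest: RandomForestClassifier
    feature_names: list
    metadata: dict = field(default_factory=dict)

    def _check_columns(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.columns) != list(self.feature_names):
            raise ValueError("feature names do not match the trained model")
        return features.to_numpy(dtype=float)

    def vote_fractions(self, features: pd.DataFrame) -> np.ndarray:
        """Fraction of trees voting nucleosomal, per row."""
        x = self._check_columns(features)
        votes = np.zeros(len(x))
        for tree in self.forest.estimators_:
            votes += tree.predict(x)
        return votes / len(self.forest.estimators_)

    def predict_windows(self, features: pd.DataFrame, **_) -> np.ndarray:
        """Binary labels for a batch of windows (scanner entry point)."""
        return (self.vote_fractions(features) >= 0.5).astype(int)


def train(data: LabeledSet, n_trees: int = DEFAULT_N_TREES, seed: int = 0) -> NFModel:
    """Fit the nucleosomal-vs-linker forest.

    Raises on a single-class training set; a fixed seed makes predictions
    bit-identical across runs.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    classes = np.unique(data.labels)
    if classes.size < 2:
        raise ValueError("single-class training set: both classes required")
    n_feat = data.features.shape[1]
    max_features = max(1, int(np.floor(np.sqrt(n_feat))))
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        max_depth=None,
        class_weight=None,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(data.features.to_numpy(dtype=float), data.labels)
    fingerprint = hash((len(data), float(np.round(data.features.to_numpy().sum(), 6))))
    return NFModel(
        forest=forest,
        feature_names=list(data.features.columns),
        metadata={
            "n_trees": n_trees,
            "max_features_per_split": max_features,
            "seed": seed,
            "n_training_rows": len(data),
            "training_set_fingerprint": fingerprint,
        },
    )


def predict(model: NFModel, fv: pd.Series) -> dict:
    """Classify one feature vector: vote fraction and thresholded label.

    ``prob`` is the fraction of trees voting nucleosomal; ``label`` is 1 iff
    ``prob >= 0.5`` (ties go to nucleosomal).
    """
    frame = fv.to_frame().T if isinstance(fv, pd.Series) else fv
    prob = float(model.vote_fractions(frame)[0])
    return {"label": int(prob >= 0.5), "prob": prob}


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the rank-based probability a positive outscores a negative.

    Ties count one half; equals brute-force pair enumeration.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(tp: int, fp: int, tn: int, fn: int,
                    scores=None, labels=None) -> dict:
    """The six performance measures from a confusion table (+ scores for AUC).

    MCC substitutes 0 when any factor of its denominator is zero; AUC is
    rank-based (NaN when scores are not supplied).
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"negative count {name}={v}")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion table")
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    auc = rank_auc(scores, labels) if scores is not None else float("nan")
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
        "auc": auc,
        "mcc": float(mcc),
    }


@dataclass
class PerformanceReport:
    """Cross-validation metric suite: per-fold values, mean +/- SD, pooled confusion."""

    per_fold: pd.DataFrame
    mean: dict
    sd: dict
    confusion: dict  # pooled tp/fp/tn/fn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": [self.mean[m] for m in METRIC_NAMES],
             "sd": [self.sd[m] for m in METRIC_NAMES]},
            index=list(METRIC_NAMES),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="metric")


def cross_validate(data: LabeledSet, k: int = 10, seed: int = 0,
                   n_trees: int = DEFAULT_N_TREES) -> PerformanceReport:
    """Stratified k-fold cross-validation of the forest.

    Fold assignment is derived from the seed; each fold is scored with
    :func:`compute_metrics` and the report carries per-fold values, their
    mean and SD, and the pooled confusion totals.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(data.labels, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    x = data.features
    y = data.labels
    rows = []
    pooled = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        sub = LabeledSet(x.iloc[tr], y[tr], [data.ids[i] for i in tr])
        model = train(sub, n_trees=n_trees, seed=seed + fold)
        probs = model.vote_fractions(x.iloc[te])
        pred = (probs >= 0.5).astype(int)
        truth = y[te]
        tp = int(((pred == 1) & (truth == 1)).sum())
        fp = int(((pred == 1) & (truth == 0)).sum())
        tn = int(((pred == 0) & (truth == 0)).sum())
        fn = int(((pred == 0) & (truth == 1)).sum())
        pooled["tp"] += tp
        pooled["fp"] += fp
        pooled["tn"] += tn
        pooled["fn"] += fn
        rows.append(compute_metrics(tp, fp, tn, fn, scores=probs, labels=truth)
                    | {"fold": fold, "n": len(te)})
    per_fold = pd.DataFrame(rows).set_index("fold")
    mean = {m: float(per_fold[m].mean()) for m in METRIC_NAMES}
    sd = {m: float(per_fold[m].std(ddof=1)) for m in METRIC_NAMES}
    return PerformanceReport(per_fold=per_fold, mean=mean, sd=sd, confusion=pooled)


def feature_importance(model: NFModel) -> pd.DataFrame:
    """Gini importance (mean decrease in impurity) per feature, descending.

    Ties are broken by feature name so the ordering is deterministic.
    """
    if not hasattr(model.forest, "estimators_"):
        raise ValueError("model is not fitted")
    df = pd.DataFrame({
        "feature": model.feature_names,
        "importance": model.forest.feature_importances_,
    })
    df = df.sort_values(["importance", "feature"],
                        ascending=[False, True], kind="stable")
    return df.reset_index(drop=True)


def save_model(model: NFModel, path) -> None:
    """Serialize a model to a single file with metadata and a format version."""
    joblib.dump({
        "format_version": MODEL_FORMAT_VERSION,
        "forest": model.forest,
        "feature_names": model.feature_names,
        "metadata": model.metadata,
    }, path)


def load_model(path) -> NFModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: {version}")
    return NFModel(
        forest=payload["forest"],
        feature_names=payload["feature_names"],
        metadata=payload["metadata"],
    )


def labeled_set_from_features(features: pd.DataFrame, labels, ids=None) -> LabeledSet:
    if ids is None:
        ids = list(features.index)
    missing = [c for c in FEATURE_NAMES if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature columns, e.g. {missing[0]}")
    return LabeledSet(features[FEATURE_NAMES], np.asarray(labels), list(ids))
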