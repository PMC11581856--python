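"""Stacked-ensemble G1/G2 subgroup classifier over key-gene expression.

Four base learners (k-nearest-neighbours, random forest, gradient
boosting, class-weighted penalized logistic regression) are fitted on a
stratified 80% training split; the ensemble is a convex combination of
their predicted probabilities whose weights minimize log-loss on the held
out 20%.  Cross-cohort application mean-imputes missing feature genes and
requires at least 80% of the features to be present.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, log_loss
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .io import ExpressionMatrix

__all__ = ["ClassifierBundle", "train_subgroup_model", "predict_subgroup"]


@dataclass
class ClassifierBundle:
    """A fitted ensemble: feature genes, base learners, simplex weights."""

    feature_genes: List[str]
    learners: Dict[str, object]
    weights: np.ndarray  # nonnegative, sums to 1, one per learner
    classes: List[str]
    feature_means: pd.Series  # training means, used for imputation
    holdout_accuracy: float
    holdout_logloss: float
    seed: int

    def __post_init__(self) -> None:
        assert (self.weights >= 0).all() and abs(self.weights.sum() - 1) < 1e-9
        assert len(self.feature_genes) > 0


def _base_learners(seed: int, n_samples: int) -> Dict[str, object]:
    k = max(3, min(15, n_samples // 10))
    return {
        "knn": Pipeline([("scale", StandardScaler()),
                         ("knn", KNeighborsClassifier(n_neighbors=k))]),
        "rf": RandomForestClassifier(n_estimators=200, random_state=seed),
        "gb": GradientBoostingClassifier(random_state=seed),
        "logistic": Pipeline([
            ("scale", StandardScaler()),
            ("lr", LogisticRegression(C=0.5, class_weight="balanced",
                                      max_iter=2000, random_state=seed)),
        ]),
    }


def _simplex_grid(n: int, steps: int = 10):
    """All weight vectors on the n-simplex with resolution 1/steps."""
    for combo in itertools.combinations_with_replacement(range(n), steps):
        w = np.bincount(combo, minlength=n) / steps
        yield w


def train_subgroup_model(expr: ExpressionMatrix, labels: pd.Series,
                         test_frac: float = 0.2,
                         seed: int = 0) -> ClassifierBundle:
    """Fit the stacked ensemble on key-gene expression.

    ``expr`` is the key-gene submatrix (genes x samples); ``labels`` maps
    sample -> subgroup (two classes, each with at least 10 samples).  The
    split is stratified; ensemble weights are chosen by grid search over
    the probability simplex to minimize held-out log-loss.
    """
    labels = labels.reindex(expr.values.columns).dropna()
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    counts = labels.value_counts()
    if (counts < 10).any():
        raise ValueError(f"each class needs >= 10 samples, got {dict(counts)}")

    X = expr.values[labels.index].T.to_numpy(dtype=float)  # samples x genes
    y = (labels == classes[1]).astype(int).to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_frac, stratify=y, random_state=seed)

    learners = _base_learners(seed, len(y_tr))
    probs = {}
    for name, model in learners.items():
        model.fit(X_tr, y_tr)
        probs[name] = model.predict_proba(X_te)[:, 1]
    P = np.column_stack([probs[name] for name in learners])

    best_w, best_ll = None, np.inf
    for w in _simplex_grid(P.shape[1]):
        ll = log_loss(y_te, np.clip(P @ w, 1e-12, 1 - 1e-12), labels=[0, 1])
        if ll < best_ll - 1e-12:
            best_w, best_ll = w.copy(), ll
    ens_prob = P @ best_w
    acc = accuracy_score(y_te, (ens_prob >= 0.5).astype(int))

    return ClassifierBundle(
        feature_genes=list(expr.values.index),
        learners=learners,
        weights=best_w,
        classes=classes,
        feature_means=expr.values[labels.index].mean(axis=1),
        holdout_accuracy=float(acc),
        holdout_logloss=float(best_ll),
        seed=seed,
    )


def predict_subgroup(bundle: ClassifierBundle,
                     expr_new: ExpressionMatrix) -> pd.DataFrame:
    """Apply the ensemble to a new cohort.

    At least 80% of the feature genes must be present; missing features
    are imputed with the training-set gene means (with a warning).
    Returns per-sample ``prob_g1``, ``prob_g2``, ``label``.
    """
    present = [g for g in bundle.feature_genes if g in expr_new.values.index]
    frac = len(present) / len(bundle.feature_genes)
    if frac < 0.8:
        raise ValueError(
            f"only {frac:.0%} of feature genes present; need >= 80%")
    missing = [g for g in bundle.feature_genes if g not in set(present)]
    mat = pd.DataFrame(index=bundle.feature_genes,
                       columns=expr_new.values.columns, dtype=float)
    mat.loc[present] = expr_new.values.loc[present].to_numpy()
    if missing:
        warnings.warn(f"imputing {len(missing)} missing feature genes "
                      "with training means")
        for g in missing:
            mat.loc[g] = bundle.feature_means.loc[g]
    X = mat.T.to_numpy(dtype=float)
    P = np.column_stack([model.predict_proba(X)[:, 1]
                         for model in bundle.learners.values()])
    prob_c1 = P @ bundle.weights  # probability of classes[1]
    out = pd.DataFrame({
        f"prob_{bundle.classes[0].lower()}": 1 - prob_c1,
        f"prob_{bundle.classes[1].lower()}": prob_c1,
        "label": np.where(prob_c1 >= 0.5, bundle.classes[1], bundle.classes[0]),
    }, index=expr_new.values.columns)
    return out
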