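"""Five-classifier bank with class weighting, grid search and rejection.

Classifier settings follow the published configuration: linear one-vs-one
SVM, entropy CART with best-of-random splits, a 19-tree random forest,
k=10 Manhattan kNN on a k-d tree, and a single-hidden-layer (15 neuron)
tanh MLP trained with Adam.  Class weights are sqrt(N_total / N_i); the
cross-validation score is the weight-normalized dot product with per-class
accuracies, and predictions below the posterior threshold are carried but
flagged as rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

UNEXPECTED = "unexpected"

CLASSIFIER_KINDS = ("SVM", "DT", "RF", "kNN", "NN")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "SVM": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "DT": {"max_depth": [None, 5, 10]},
    "RF": {"max_depth": [None, 5, 10]},
    "kNN": {},
    "NN": {},
}


@dataclass
class ClassifierSpec:
    kind: str
    grid: dict[str, list] | None = None
    probability_threshold: float = 0.90
    cv_folds: int = 3
    seed: int = 0
    class_weights: dict | None = None

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")
        if not 0.0 <= self.probability_threshold <= 1.0:
            raise ValueError("probability threshold must be in [0, 1]")
        if self.grid is None:
            self.grid = dict(DEFAULT_GRIDS[self.kind])


def class_weights(labels) -> dict:
    """weight_i = sqrt(N_total / N_i); scale-invariant in the class counts."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("no labels")
    classes, counts = np.unique(y, return_counts=True)
    total = counts.sum()
    return {c: float(np.sqrt(total / n)) for c, n in zip(classes, counts)}


def make_classifier(kind: str, seed: int = 0, weights: dict | None = None, **hyper):
    """Instantiate one bank member with the published settings."""
    if kind == "SVM":
        return SVC(
            kernel="linear",
            probability=True,
            decision_function_shape="ovo",
            class_weight=weights,
            random_state=seed,
            **hyper,
        )
    if kind == "DT":
        return DecisionTreeClassifier(
            criterion="entropy",
            splitter="random",
            class_weight=weights,
            random_state=seed,
            **hyper,
        )
    if kind == "RF":
        return RandomForestClassifier(
            n_estimators=19,
            criterion="entropy",
            class_weight=weights,
            random_state=seed,
            **hyper,
        )
    if kind == "kNN":
        return KNeighborsClassifier(
            n_neighbors=10, metric="manhattan", algorithm="kd_tree", **hyper
        )
    if kind == "NN":
        return MLPClassifier(
            hidden_layer_sizes=(15,),
            activation="tanh",
            solver="adam",
            alpha=0.001,
            learning_rate_init=0.001,
            beta_1=0.9,
            beta_2=0.999,
            epsilon=1e-8,
            max_iter=1500,
            random_state=seed,
            **hyper,
        )
    raise ValueError(f"unknown classifier kind {kind!r}")


def default_classifiers(seed: int = 0, weights: dict | None = None) -> dict[str, object]:
    return {k: make_classifier(k, seed=seed, weights=weights) for k in CLASSIFIER_KINDS}


def per_class_accuracy(y_true, y_pred) -> dict:
    """CA_k = correct-in-class-k / predicted-as-class-k (precision-like,
    matching the printed definition).  Classes never predicted are absent."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = {}
    for c in np.unique(y_pred):
        sel = y_pred == c
        out[c] = float((y_true[sel] == c).mean())
    return out


def mca_from_class_accuracies(accuracies) -> float:
    """MCA = unweighted mean of the per-class accuracies."""
    vals = list(accuracies.values()) if isinstance(accuracies, dict) else list(accuracies)
    if not vals:
        raise ValueError("no class accuracies to average")
    return float(np.mean(vals))


def mca(y_true, y_pred, accepted=None) -> float:
    """Mean class accuracy over accepted predictions.

    Truth rows labelled "unexpected" are excluded; classes with zero
    accepted predictions drop out of the mean with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    keep = y_true != UNEXPECTED
    if accepted is not None:
        keep &= np.asarray(accepted, dtype=bool)
    if not keep.any():
        raise ValueError("no accepted predictions to score")
    acc = per_class_accuracy(y_true[keep], y_pred[keep])
    expected = set(np.unique(y_true[keep]))
    missing = expected - set(acc)
    if missing:
        warnings.warn(f"classes with zero accepted predictions excluded: {sorted(missing)}")
    return mca_from_class_accuracies(acc)


def _weighted_fold_score(y_true, y_pred, weights: dict) -> float:
    """Sum of normalized class weights times per-class accuracy."""
    acc = per_class_accuracy(y_true, y_pred)
    if not acc:
        return 0.0
    w = np.array([weights.get(c, 1.0) for c in acc])
    w = w / w.sum()
    return float((w * np.array([acc[c] for c in acc])).sum())


def _fit(model, X, y, weights: dict | None):
    """Fit with per-sample weights where the estimator supports them."""
    if weights and "sample_weight" in model.fit.__code__.co_varnames:
        sw = np.array([weights[c] for c in y])
        try:
            return model.fit(X, y, sample_weight=sw)
        except TypeError:
            pass
    return model.fit(X, y)


def grid_search(spec: ClassifierSpec, X, y) -> tuple[object, dict, float]:
    """Exhaustive grid search with stratified 3-fold CV.

    Returns (model refit on all data, best hyperparameters, best score).
    The fold score is the weight-normalized per-class-accuracy dot product.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < spec.cv_folds:
        raise ValueError("every class needs at least cv_folds samples")
    weights = spec.class_weights or class_weights(y)
    grid = list(ParameterGrid(spec.grid)) if spec.grid else [{}]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    best_params, best_score = None, -np.inf
    for params in grid:
        scores = []
        for tr, te in skf.split(X, y):
            model = make_classifier(spec.kind, seed=spec.seed, weights=None, **params)
            _fit(model, X[tr], y[tr], weights)
            scores.append(_weighted_fold_score(y[te], model.predict(X[te]), weights))
        mean_score = float(np.mean(scores))
        if mean_score > best_score:
            best_params, best_score = params, mean_score
    final = make_classifier(spec.kind, seed=spec.seed, weights=None, **best_params)
    _fit(final, X, y, weights)
    return final, best_params, best_score


def train(kind: str, table: pd.DataFrame, labels, spec: ClassifierSpec | None = None):
    """Grid-search and fit one bank member on a feature table."""
    spec = spec or ClassifierSpec(kind=kind)
    if spec.kind != kind:
        raise ValueError("spec.kind does not match kind")
    y = np.asarray(labels)
    keep = y != UNEXPECTED
    model, params, score = grid_search(spec, table.to_numpy()[keep], y[keep])
    return model


@dataclass
class Prediction:
    nucleus_id: int
    posteriors: dict
    label: str
    accepted: bool


def predict_with_rejection(
    model, table: pd.DataFrame, threshold: float = 0.90
) -> list[Prediction]:
    """Posterior-thresholded predictions; rejected rows are kept, flagged."""
    X = table.to_numpy(dtype=float)
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    out = []
    for idx, row in zip(table.index, proba):
        k = int(np.argmax(row))
        out.append(
            Prediction(
                nucleus_id=int(idx) if np.isscalar(idx) else idx,
                posteriors={c: float(p) for c, p in zip(classes, row)},
                label=classes[k],
                accepted=bool(row[k] >= threshold),
            )
        )
    return out


def predictions_frame(preds: list[Prediction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nucleus_id": [p.nucleus_id for p in preds],
            "class": [p.label for p in preds],
            "posterior_max": [max(p.posteriors.values()) for p in preds],
            "accepted": [p.accepted for p in preds],
        }
    )


def cross_val_mca(model, X, y, seed: int = 0, folds: int = 3) -> float:
    """Out-of-fold MCA (no rejection), used by the subset-size curve."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    weights = class_weights(y)
    for tr, te in skf.split(X, y):
        m = clone(model)
        _fit(m, X[tr], y[tr], weights)
        y_pred[te] = m.predict(X[te])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mca(y, y_pred)
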