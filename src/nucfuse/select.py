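"""Feature normalization, mRMR ranking and the accuracy-vs-subset curve."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXPECTED_CLASSES = ("hypodermal", "intestinal", "muscle", "neuronal")
UNEXPECTED = "unexpected"


def minmax_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Project every column onto [0, 1]; constant columns are dropped."""
    out = {}
    dropped = []
    for col in table.columns:
        x = table[col].astype(float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            dropped.append(col)
            continue
        out[col] = (x - lo) / (hi - lo)
    if dropped:
        warnings.warn(f"dropped constant feature columns: {dropped}")
    return pd.DataFrame(out, index=table.index)


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width binning for continuous inputs; passthrough for labels."""
    x = np.asarray(x)
    if x.dtype.kind in "OUS":  # categorical labels
        _, codes = np.unique(x, return_inverse=True)
        return codes
    if np.issubdtype(x.dtype, np.integer) and len(np.unique(x)) <= bins:
        _, codes = np.unique(x, return_inverse=True)
        return codes
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros(len(x), dtype=int)
    codes = np.floor((x - lo) / (hi - lo) * bins).astype(int)
    return np.clip(codes, 0, bins - 1)


def mutual_information(x, y, bins: int = 10) -> float:
    """Plug-in mutual information (bits) of the discretized joint.

    Continuous inputs are cut into ``bins`` equal-width bins; categorical
    inputs are used as-is.  Non-negative and symmetric.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    if x.size != y.size:
        raise ValueError("length mismatch")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    xi = _discretize(x, bins)
    yi = _discretize(y, bins)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log2(joint[nz] / (px @ py)[nz])).sum())


@dataclass
class MRMRRanking:
    features: list[str]
    relevance: list[float]
    redundancy: list[float]
    criterion: str = "MID"
    bins: int = 10

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("ranking must be a permutation of feature names")


def mrmr_rank(
    table: pd.DataFrame,
    labels,
    bins: int = 10,
    criterion: str = "MID",
) -> MRMRRanking:
    """Greedy forward mRMR ranking of all feature columns.

    Step 1 picks the feature with maximal relevance MI(f; class); step k
    maximizes relevance minus (MID) or divided by (MIQ) the mean MI with
    the already-selected set.
    """
    if criterion not in ("MID", "MIQ"):
        raise ValueError("criterion must be MID or MIQ")
    cols = list(table.columns)
    if not cols:
        raise ValueError("need at least one feature")
    y = np.asarray(labels)
    X = {c: table[c].to_numpy() for c in cols}
    relevance = {c: mutual_information(X[c], y, bins) for c in cols}
    selected: list[str] = []
    rel_out: list[float] = []
    red_out: list[float] = []
    pair_mi: dict[tuple[str, str], float] = {}
    remaining = set(cols)
    while remaining:
        best, best_score, best_red = None, -np.inf, 0.0
        for c in sorted(remaining):
            if selected:
                red = np.mean(
                    [
                        pair_mi.setdefault(
                            (min(c, s), max(c, s)),
                            mutual_information(X[c], X[s], bins),
                        )
                        for s in selected
                    ]
                )
            else:
                red = 0.0
            score = (
                relevance[c] - red
                if criterion == "MID"
                else relevance[c] / (red + 1e-12)
            )
            if score > best_score:
                best, best_score, best_red = c, score, red
        selected.append(best)
        rel_out.append(relevance[best])
        red_out.append(float(best_red))
        remaining.discard(best)
    return MRMRRanking(selected, rel_out, red_out, criterion, bins)


@dataclass
class SubsetCurve:
    n_features: list[int]
    mca: dict[str, list[float]]  # per classifier name
    plateau: dict[str, int] = field(default_factory=dict)
    plateau_overall: int = 0


def subset_curve(
    table: pd.DataFrame,
    labels,
    ranking: MRMRRanking,
    classifiers: dict[str, object] | None = None,
    cv_seed: int = 0,
    tolerance: float = 0.01,
    max_n: int | None = None,
) -> SubsetCurve:
    """Cross-validated accuracy of top-n feature subsets, n = 1..max_n.

    For every classifier the plateau point is the smallest n whose score
    reaches (max - tolerance); the overall plateau uses the per-n mean
    across classifiers.  Rows labelled "unexpected" are excluded.
    """
    from .classify import cross_val_mca, default_classifiers

    y = np.asarray(labels)
    keep = y != UNEXPECTED
    y = y[keep]
    table = table.loc[keep]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 3:
        raise ValueError("every class needs at least 3 members for 3-fold CV")
    if classifiers is None:
        classifiers = default_classifiers(seed=cv_seed)
    n_max = max_n or len(ranking.features)
    ns = list(range(1, n_max + 1))
    curves: dict[str, list[float]] = {name: [] for name in classifiers}
    for n in ns:
        feats = ranking.features[:n]
        X = table[feats].to_numpy()
        for name, clf in classifiers.items():
            curves[name].append(cross_val_mca(clf, X, y, seed=cv_seed))
    curve = SubsetCurve(n_features=ns, mca=curves)
    for name, vals in curves.items():
        arr = np.asarray(vals)
        curve.plateau[name] = int(ns[int(np.argmax(arr >= arr.max() - tolerance))])
    mean_curve = np.mean([curves[name] for name in classifiers], axis=0)
    curve.plateau_overall = int(
        ns[int(np.argmax(mean_curve >= mean_curve.max() - tolerance))]
    )
    return curve
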