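"""Shapley-value feature ranking and top-K column selection.

The production path ranks the fused feature columns by the mean absolute
Shapley attribution of a tree-ensemble model over the training samples — the
ordering a beeswarm summary plot displays. Attributions are computed with the
exact polynomial-time TreeSHAP algorithm as implemented natively by XGBoost
(``Booster.predict(pred_contribs=True)``), on the positive-class margin
(log-odds) output.

For validation, :func:`exhaustive_shapley` evaluates the Shapley value by
direct enumeration of all 2^D coalitions with the correct kernel weight
|S|! (D-|S|-1)! / D!. It is generic over the coalition value function:

* :func:`tree_conditional_value` reproduces TreeSHAP's value function — the
  cover-weighted conditional expectation over the fitted trees — so
  enumeration must agree with ``pred_contribs`` to numerical precision;
* :func:`marginal_value` is the background-marginalization (interventional)
  value function for model-agnostic checks of the Shapley axioms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import xgboost as xgb

from .encoders import HybridMatrix


@dataclass
class ShapRanking:
    """Per-feature importance (mean |SHAP| over samples) and the sort order.

    ``order`` is a permutation of 0..D-1 by descending importance; ties break
    toward the lower original column index (stable).
    """

    feature_labels: list[str]
    mean_abs_shap: np.ndarray
    order: np.ndarray

    def __post_init__(self) -> None:
        self.mean_abs_shap = np.asarray(self.mean_abs_shap, dtype=float)
        if np.any(self.mean_abs_shap < 0):
            raise ValueError("mean |SHAP| cannot be negative")
        if sorted(self.order.tolist()) != list(range(len(self.feature_labels))):
            raise ValueError("order is not a permutation of the columns")


@dataclass
class SelectionResult:
    """The K retained column indices, listed in ranking (importance) order."""

    selected_indices: np.ndarray
    k: int


def _as_booster(model) -> xgb.Booster:
    return model.get_booster() if hasattr(model, "get_booster") else model


def shap_values(model, X: np.ndarray) -> np.ndarray:
    """(n, D) exact TreeSHAP attributions on the margin output (bias dropped)."""
    booster = _as_booster(model)
    contribs = booster.predict(xgb.DMatrix(np.asarray(X, float)), pred_contribs=True)
    return contribs[:, :-1]  # last column is the expected value (bias)


def compute_shap_ranking(model, X: HybridMatrix | np.ndarray) -> ShapRanking:
    """Rank columns by mean |SHAP| of ``model`` over the rows of ``X``."""
    if isinstance(X, HybridMatrix):
        matrix, labels = X.matrix, X.column_labels
    else:
        matrix = np.asarray(X, float)
        labels = [f"f{i}" for i in range(matrix.shape[1])]
    booster = _as_booster(model)
    if booster.num_features() != matrix.shape[1]:
        raise ValueError(
            f"model expects {booster.num_features()} features, matrix has {matrix.shape[1]}"
        )
    importance = np.abs(shap_values(booster, matrix)).mean(axis=0)
    # stable argsort on negated values: ties fall back to ascending column index
    order = np.argsort(-importance, kind="stable")
    return ShapRanking(feature_labels=list(labels), mean_abs_shap=importance, order=order)


def select_top_k(
    X: HybridMatrix | np.ndarray, ranking: ShapRanking, k: int = 64
) -> tuple[np.ndarray, SelectionResult]:
    """Keep the K highest-importance columns (sample order preserved)."""
    matrix = X.matrix if isinstance(X, HybridMatrix) else np.asarray(X, float)
    D = matrix.shape[1]
    if not (1 <= k <= D):
        raise ValueError(f"K={k} out of range for {D} features")
    idx = ranking.order[:k]
    return matrix[:, idx], SelectionResult(selected_indices=idx.copy(), k=k)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def exhaustive_shapley(
    value_fn: Callable[[frozenset[int]], float], D: int, max_features: int = 12
) -> np.ndarray:
    """Shapley values by direct enumeration of all coalitions.

    ``value_fn(S)`` is the model's expected prediction given the features in
    coalition ``S``; phi_i sums |S|!(D-|S|-1)!/D! [v(S+i) - v(S)] over all
    S not containing i.
    """
    if D > max_features:
        raise ValueError(f"D={D} too large to enumerate 2^D coalitions")
    fact = [math.factorial(j) for j in range(D + 1)]
    values: dict[frozenset[int], float] = {}

    def v(S: frozenset[int]) -> float:
        if S not in values:
            values[S] = float(value_fn(S))
        return values[S]

    phi = np.zeros(D)
    all_features = list(range(D))
    for i in all_features:
        others = [j for j in all_features if j != i]
        for size in range(D):
            w = fact[size] * fact[D - size - 1] / fact[D]
            for S in combinations(others, size):
                fs = frozenset(S)
                phi[i] += w * (v(fs | {i}) - v(fs))
    return phi


def marginal_value(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
) -> Callable[[frozenset[int]], float]:
    """Interventional value function: features outside S are drawn from the
    background sample rows and the prediction is averaged."""
    x = np.asarray(x, float).ravel()
    background = np.atleast_2d(np.asarray(background, float))

    def v(S: frozenset[int]) -> float:
        rows = background.copy()
        if S:
            rows[:, list(S)] = x[list(S)]
        return float(np.mean(predict_fn(rows)))

    return v


def _parse_tree_dump(booster: xgb.Booster) -> list[dict]:
    return [json.loads(t) for t in booster.get_dump(dump_format="json", with_stats=True)]


def tree_conditional_value(
    model, x: np.ndarray
) -> Callable[[frozenset[int]], float]:
    """TreeSHAP's value function: the cover-weighted conditional expectation.

    Descending each fitted tree, a split on a feature inside the coalition
    follows the sample's own value; a split on an absent feature averages the
    two children weighted by their training cover. Summed over trees (margin
    output, without the base score, which cancels in Shapley differences).
    """
    booster = _as_booster(model)
    trees = _parse_tree_dump(booster)
    x = np.asarray(x, float).ravel()

    def walk(node: dict, S: frozenset[int]) -> float:
        if "leaf" in node:
            return float(node["leaf"])
        feat = int(node["split"].lstrip("f"))
        kids = {c["nodeid"]: c for c in node["children"]}
        if feat in S:
            # compare in float32, as the booster does: hist split thresholds
            # are bin edges that can tie with data values exactly
            go_yes = np.float32(x[feat]) < np.float32(node["split_condition"])
            return walk(kids[node["yes"] if go_yes else node["no"]], S)
        total = sum(c["cover"] for c in node["children"])
        return sum(c["cover"] / total * walk(c, S) for c in node["children"])

    def v(S: frozenset[int]) -> float:
        return sum(walk(t, S) for t in trees)

    return v


def selection_report(ranking: ShapRanking, selection: SelectionResult):
    """DataFrame of (rank, column label, mean |SHAP|) for the retained columns."""
    import pandas as pd

    rows = [
        {
            "rank": r + 1,
            "feature": ranking.feature_labels[i],
            "mean_abs_shap": ranking.mean_abs_shap[i],
        }
        for r, i in enumerate(selection.selected_indices)
    ]
    return pd.DataFrame(rows)
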