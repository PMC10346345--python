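"""Wilcoxon-statistic feature ranking with greedy redundancy control.

Features are ranked by the absolute standardized u-statistic of the
two-sample unpaired Wilcoxon (Mann-Whitney) test; with more than two
classes the score is the maximum over one-vs-rest splits.  Selection is
greedy: repeatedly take the highest-ranked unselected feature whose mean
absolute Pearson correlation with the already-selected set does not exceed
a redundancy threshold, until ``k`` features are selected or the
candidates are exhausted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io_formats import FeatureTable

__all__ = ["SelectionResult", "wilcoxon_z", "rank_features", "select_features"]


@dataclass
class SelectionResult:
    """Ranked scores and the greedily selected low-redundancy subset."""

    ranked: list[tuple[str, float]]
    selected: list[str]
    corr_threshold: float
    k: int


def wilcoxon_z(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized Mann-Whitney u-statistic with tie correction.

    U counts pairs (i, j) with x_i > y_j plus half the tied pairs;
    z = (U - n1*n2/2) / sigma_U with
    sigma_U = sqrt(n1*n2/12 * ((n+1) - sum(t^3 - t) / (n*(n-1)))) where t
    runs over tie-group sizes in the pooled sample.  All-tied input is
    degenerate and returns 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per sample")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = float(np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0)
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        warnings.warn("all values tied across both samples; z degenerate (0)",
                      RuntimeWarning)
        return 0.0
    return (u - n1 * n2 / 2.0) / np.sqrt(var)


def _scores_for_split(ranks: np.ndarray, tie_var_term: np.ndarray,
                      mask: np.ndarray) -> np.ndarray:
    """|z| per column for one two-group split, from precomputed ranks."""
    n = ranks.shape[0]
    n1 = int(mask.sum())
    n2 = n - n1
    r1 = ranks[mask].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_var_term / (n * (n - 1)))
    z = np.zeros(ranks.shape[1])
    ok = var > 0
    z[ok] = (u[ok] - n1 * n2 / 2.0) / np.sqrt(var[ok])
    return np.abs(z)


def _rank_scores(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    ranks = rankdata(X, axis=0)
    tie_term = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        _, c = np.unique(X[:, j], return_counts=True)
        tie_term[j] = np.sum(c.astype(float)**3 - c)
    if len(classes) == 2:
        return _scores_for_split(ranks, tie_term, labels == classes[0])
    return np.max(
        [_scores_for_split(ranks, tie_term, labels == c) for c in classes],
        axis=0)


def rank_features(table: FeatureTable,
                  labels: np.ndarray) -> list[tuple[str, float]]:
    """Features sorted by |z| descending; rank ties keep column order."""
    labels = np.asarray(labels)
    X = table.values
    if len(labels) != X.shape[0]:
        raise ValueError("labels length does not match table rows")
    scores = _rank_scores(X, labels)
    order = np.argsort(-scores, kind="stable")
    names = table.feature_names
    return [(names[j], float(scores[j])) for j in order]


def select_features(table: FeatureTable, labels: np.ndarray, k: int = 40,
                    corr_threshold: float = 0.8) -> SelectionResult:
    """Greedy distinctive/low-redundancy feature subset of size <= k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = rank_features(table, labels)
    names = table.feature_names
    col = {name: j for j, name in enumerate(names)}
    X = table.values
    if k > len(names):
        warnings.warn(f"k={k} exceeds feature count {len(names)}; selecting "
                      "all eligible features", RuntimeWarning)

    # standardized columns so |corr| is an inner product / n
    sd = X.std(axis=0)
    const = sd == 0
    if np.any(const):
        warnings.warn(f"{int(const.sum())} constant feature column(s); their "
                      "correlation is treated as 0", RuntimeWarning)
    Xs = (X - X.mean(axis=0)) / np.where(const, 1.0, sd)
    Xs[:, const] = 0.0
    n = X.shape[0]

    selected: list[str] = []
    # |corr| of every feature with each selected feature, grown column-wise
    corr_cols: list[np.ndarray] = []
    remaining = [name for name, _ in ranked]
    while len(selected) < k and remaining:
        chosen = None
        for name in remaining:
            j = col[name]
            if not selected:
                mean_corr = 0.0
            else:
                mean_corr = float(np.mean([c[j] for c in corr_cols]))
            if mean_corr <= corr_threshold:
                chosen = name
                break
        if chosen is None:
            break
        selected.append(chosen)
        remaining.remove(chosen)
        corr_cols.append(np.abs(Xs.T @ Xs[:, col[chosen]]) / n)

    # the redundancy constraint holds by construction; assert it anyway
    for i, name in enumerate(selected[1:], start=1):
        j = col[name]
        mean_corr = np.mean([np.abs(Xs[:, j] @ Xs[:, col[s]]) / n
                             for s in selected[:i]])
        assert mean_corr <= corr_threshold + 1e-9
    return SelectionResult(ranked=ranked, selected=selected,
                           corr_threshold=corr_threshold, k=k)
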