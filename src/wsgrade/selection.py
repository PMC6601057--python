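"""Information-gain feature ranking with MDL-stop supervised discretization.

Information gain on a continuous feature needs a discretization.  The
entropy-minimization scheme with the minimum-description-length (MDL)
stopping rule (Fayyad & Irani) recursively bisects the feature at the
class-entropy-minimizing boundary and accepts a cut only when the
information gained pays for encoding it.  A feature with no admissible cut
gets exactly zero information gain — the natural mechanism by which
uninformative features drop out of the retained set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class IGRanking:
    """Per-feature information-gain scores and the retained (IG > 0) subset."""

    scores: dict[int, float]
    retained: list[int]


def _entropy(labels: np.ndarray) -> float:
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def _best_cut(values: np.ndarray, labels: np.ndarray):
    """Entropy-minimizing boundary cut, or None if no candidate exists."""
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]
    n = v.size
    # candidate cuts: midpoints between adjacent distinct values
    change = np.flatnonzero(v[1:] != v[:-1]) + 1
    if change.size == 0:
        return None
    best = None
    for idx in change:
        left, right = y[:idx], y[idx:]
        h = (idx / n) * _entropy(left) + ((n - idx) / n) * _entropy(right)
        if best is None or h < best[0]:
            best = (h, idx)
    h, idx = best
    cut = (v[idx - 1] + v[idx]) / 2.0
    return h, idx, cut, v, y


def _mdl_accept(y, y_left, y_right, h_split) -> bool:
    n = y.size
    h = _entropy(y)
    gain = h - h_split
    k = np.unique(y).size
    k1 = np.unique(y_left).size
    k2 = np.unique(y_right).size
    delta = (np.log2(3.0**k - 2.0) - (k * h - k1 * _entropy(y_left)
                                      - k2 * _entropy(y_right)))
    threshold = (np.log2(n - 1.0) + delta) / n
    return gain > threshold


def supervised_discretize(values, labels) -> list[float]:
    """MDL-stop recursive binary discretization; returns sorted cut points.

    An empty list means the feature admits no split that the MDL criterion
    accepts (constant features trivially so).
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if values.size != labels.size or values.size < 2:
        raise ValueError("need >= 2 samples with matching labels")
    cuts: list[float] = []

    def recurse(v, y):
        if np.unique(y).size < 2:
            return
        found = _best_cut(v, y)
        if found is None:
            return
        h_split, idx, cut, v_sorted, y_sorted = found
        y_left, y_right = y_sorted[:idx], y_sorted[idx:]
        if not _mdl_accept(y_sorted, y_left, y_right, h_split):
            return
        cuts.append(cut)
        recurse(v_sorted[:idx], y_left)
        recurse(v_sorted[idx:], y_right)

    recurse(values, labels)
    return sorted(cuts)


def information_gain(values, labels) -> float:
    """IG in bits: class entropy minus entropy conditioned on the bins.

    Bins come from :func:`supervised_discretize`; with no admissible cuts
    the gain is exactly 0.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    cuts = supervised_discretize(values, labels)
    if not cuts:
        return 0.0
    bins = np.digitize(values, cuts)
    n = labels.size
    h_cond = 0.0
    for b in np.unique(bins):
        sel = bins == b
        h_cond += (sel.sum() / n) * _entropy(labels[sel])
    return max(0.0, _entropy(labels) - h_cond)


def rank_features(table: pd.DataFrame, label_col: str = "degree") -> IGRanking:
    """Score every f<N> column by IG and retain those with IG > 0.

    The retained list is sorted by descending IG, ties by feature number;
    model training consumes only the retained columns.
    """
    if table.empty:
        raise ValueError("empty feature table")
    labels = table[label_col].to_numpy()
    if np.unique(labels).size < 2:
        raise ValueError("need >= 2 classes to rank features")
    feature_cols = [c for c in table.columns if c.startswith("f")
                    and c[1:].isdigit()]
    scores: dict[int, float] = {}
    for col in feature_cols:
        scores[int(col[1:])] = information_gain(table[col].to_numpy(), labels)
    retained = sorted((k for k, v in scores.items() if v > 0),
                      key=lambda k: (-scores[k], k))
    return IGRanking(scores=scores, retained=retained)
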