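"""Independent reference implementations used as test oracles.

Everything here is written as plain loops straight from the definitions,
deliberately sharing no code with the package paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_evaluate_bit(net, X):
    """Straight-loop evaluation of a 3-layer threshold network."""
    out = []
    for i in range(X.shape[0]):
        top = 0.0
        for k, node in enumerate(net.hidden):
            z = 0.0
            for j, f in enumerate(node.feature_indices):
                z += node.weights[j] * X[i, f]
            h = 1.0 if z > node.threshold else 0.0
            top += net.top_weights[k] * h
        out.append(1 if top > net.top_threshold else 0)
    return np.array(out, dtype=np.uint8)


def naive_group_sums(dense_col, values, subset):
    n0 = n1 = 0
    s0 = s1 = 0.0
    for i in subset:
        if dense_col[i]:
            n1 += 1
            s1 += values[i]
        else:
            n0 += 1
            s0 += values[i]
    return n0, s0, n1, s1


def naive_explained_variance(residual, bits):
    """Between-group SS from the group-mean definition."""
    residual = np.asarray(residual, dtype=float)
    bits = np.asarray(bits)
    g0 = residual[bits == 0]
    g1 = residual[bits == 1]
    if len(g0) == 0 or len(g1) == 0:
        return 0.0
    m = residual.mean()
    return len(g0) * (g0.mean() - m) ** 2 + len(g1) * (g1.mean() - m) ** 2


def naive_best_split(dense_block, y, min_node_check=False):
    """Scan columns ascending, strictly-greater wins: (col or None, BGSS)."""
    best_col, best_bg = None, 0.0
    for j in range(dense_block.shape[1]):
        col = dense_block[:, j]
        bg = naive_explained_variance(y, col)
        if (col == col[0]).all():
            continue
        if bg > best_bg:
            best_col, best_bg = j, bg
    return best_col, best_bg


class NaiveTree:
    """Recursive unpacked-bit tree builder with the same split semantics:
    best between-group SS, lowest column on ties, stop on purity,
    ``n < 2 * min_node_size`` or no positive-gain separating split."""

    def __init__(self, block, y, unique_bits, min_node_size):
        self.unique_bits = np.asarray(unique_bits)
        self.n_nodes = 0
        self.root = self._build(np.asarray(block), np.asarray(y, dtype=float), min_node_size)

    def _build(self, block, y, mns):
        self.n_nodes += 1
        node = {"value": y.mean(), "split": None}
        if len(y) < 2 * mns or y.min() == y.max():
            return node
        best_col, best_bg = None, 0.0
        for j in range(block.shape[1]):
            col = block[:, j]
            n1 = col.sum()
            if n1 == 0 or n1 == len(col):
                continue
            # direct two-sided sums: complementary columns tie exactly,
            # so lowest column wins, matching the packed builder
            s1 = float(y @ col.astype(float))
            s0 = float(y @ (1.0 - col.astype(float)))
            n0 = len(col) - n1
            bg = s1 * s1 / n1 + s0 * s0 / n0 - (s1 + s0) * (s1 + s0) / len(col)
            if bg > best_bg:
                best_col, best_bg = j, bg
        if best_col is None:
            return node
        on = block[:, best_col] == 1
        node["split"] = int(self.unique_bits[best_col])
        node["left"] = self._build(block[~on], y[~on], mns)
        node["right"] = self._build(block[on], y[on], mns)
        return node

    def predict_one(self, dense_bits_row):
        node = self.root
        while node["split"] is not None:
            node = node["right"] if dense_bits_row[node["split"]] else node["left"]
        return node["value"]

    def predict(self, dense_bits):
        return np.array([self.predict_one(row) for row in dense_bits])


def brute_auc(scores, labels):
    """Pairwise Mann–Whitney count with ties at 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def hanley_mcneil_ci(a, n_pos, n_neg):
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    se = math.sqrt(
        (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a))
        / (n_pos * n_neg)
    )
    return max(a - 1.959963984540054 * se, 0.0), min(a + 1.959963984540054 * se, 1.0)


def exact_wilcoxon_p(diffs, alternative):
    """Exact signed-rank p by enumerating all sign assignments.

    Assumes no zeros and no ties in |diffs| (ranks 1..n)."""
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1
    w_obs = float(ranks[diffs > 0].sum())
    count = 0
    total = 2**n
    for signs in itertools.product((0, 1), repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        if alternative == "less" and w <= w_obs:
            count += 1
        elif alternative == "greater" and w >= w_obs:
            count += 1
    return count / total
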