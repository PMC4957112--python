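"""Random forest over packed binary features.

The modification relative to a textbook random forest: each tree gets a
bootstrapped sample *and* a bootstrapped (with replacement) subset of bit
features, and every split in a tree scans that tree's whole unique bit set
for the best split — there is no fresh per-split feature draw.  Splits are
binary by construction (left = bit 0, right = bit 1), which is what makes
the packed representation pay off.

For binary 0/1 targets the Gini decrease of a split equals ``2/n`` times
the between-group sum of squares of the targets, i.e. the same quantity
variance reduction maximises — so one scorer serves both tasks and only the
reported score scale differs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bitstore import BitMatrix

__all__ = [
    "ForestConfig",
    "Tree",
    "BitForest",
    "best_split",
    "grow_tree",
    "fit_forest",
    "predict_forest",
]

_LEAF = -1


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    bits_per_tree: int = 800
    sample_fraction: float = 1.0
    min_node_size: int = 1
    task: str = "classification"
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1 or self.bits_per_tree < 1 or self.min_node_size < 1:
            raise ValueError("n_trees, bits_per_tree, min_node_size must be >= 1")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")


class Tree:
    """Flat-array binary tree: ``split_bit[i] == -1`` marks a leaf.

    ``left`` is followed when the split bit is 0, ``right`` when it is 1;
    ``value`` holds the leaf mean (regression) or class-1 fraction
    (classification).
    """

    __slots__ = ("split_bit", "left", "right", "value")

    def __init__(self, split_bit, left, right, value):
        self.split_bit = np.asarray(split_bit, dtype=np.int64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.value = np.asarray(value, dtype=np.float64)

    @property
    def n_nodes(self) -> int:
        return len(self.split_bit)

    def used_bits(self) -> np.ndarray:
        b = self.split_bit[self.split_bit >= 0]
        return np.unique(b)

    def predict(self, bits_new: BitMatrix) -> np.ndarray:
        """Leaf value reached by every sample of ``bits_new``."""
        n = bits_new.n_samples
        out = np.empty(n)
        stack = [(np.arange(n, dtype=np.intp), 0)]
        while stack:
            idx, nid = stack.pop()
            if idx.size == 0:
                continue
            b = self.split_bit[nid]
            if b == _LEAF:
                out[idx] = self.value[nid]
                continue
            vals = bits_new.get_bits(int(b), idx)
            on = vals == 1
            stack.append((idx[~on], int(self.left[nid])))
            stack.append((idx[on], int(self.right[nid])))
        return out


@dataclass
class BitForest:
    trees: list[Tree]
    config: ForestConfig
    n_pool_bits: int


def _between_group_ss(y_node: np.ndarray, bit_block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Between-group SS of ``y_node`` for every bit column of ``bit_block``.

    Returns ``(scores, n1)``; non-separating bits (constant on the node)
    score ``-inf`` so they can never be selected.

    Both group sums are computed directly (not one by subtraction), which
    makes the score exactly invariant under complementing a bit column;
    mathematically tied candidates then tie bit-for-bit and the
    lowest-index tie-break is well defined.
    """
    n = y_node.size
    bf = bit_block.astype(np.float64)
    cf = 1.0 - bf
    n1 = bf.sum(axis=0)
    s1 = y_node @ bf
    s0 = y_node @ cf
    n0 = n - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        bg = s1 * s1 / n1 + s0 * s0 / n0 - (s1 + s0) * (s1 + s0) / n
    bg[(n1 == 0) | (n0 == 0)] = -np.inf
    return bg, n1


def _score_scale(task: str, n_node: int) -> float:
    # variance reduction = BGSS/n; Gini decrease for 0/1 targets = 2*BGSS/n
    return (2.0 if task == "classification" else 1.0) / n_node


def best_split(
    bits: BitMatrix,
    targets: np.ndarray,
    node_indices: np.ndarray,
    candidate_bits: np.ndarray,
    task: str = "regression",
) -> tuple[int | None, float]:
    """Best candidate bit for one node, or ``(None, 0.0)`` if nothing splits.

    Maximises impurity decrease — variance reduction (regression) or Gini
    decrease (classification); for 0/1 targets the two agree up to scale, so
    the selected bit is identical.  Ties go to the lowest bit index.
    """
    node_indices = np.asarray(node_indices, dtype=np.intp)
    if node_indices.size == 0:
        raise ValueError("node_indices must be nonempty")
    cand = np.sort(np.asarray(candidate_bits, dtype=np.intp))
    y_node = np.asarray(targets, dtype=np.float64)[node_indices]
    block = bits.extract(cand, node_indices)
    bg, _ = _between_group_ss(y_node, block)
    best = int(np.argmax(bg))  # first max -> lowest bit index on ties
    if not np.isfinite(bg[best]) or bg[best] <= 0.0:
        return None, 0.0
    return int(cand[best]), float(bg[best] * _score_scale(task, y_node.size))


def _grow_from_draws(
    block: np.ndarray,
    y_boot: np.ndarray,
    unique_bits: np.ndarray,
    min_node_size: int,
) -> Tree:
    """Deterministic tree growth given the bootstrap draws.

    ``block`` is the dense (n_boot, n_unique_bits) bit block of the
    bootstrapped samples; ``unique_bits`` maps its columns back to pool
    indices (ascending, so first-max tie-breaking selects the lowest pool
    index).  Split recursion stops on purity, ``n < 2 * min_node_size``, or
    when no bit attains a positive impurity decrease.
    """
    block_f = block.astype(np.float64)
    split_bit: list[int] = []
    left: list[int] = []
    right: list[int] = []
    value: list[float] = []

    def new_node() -> int:
        split_bit.append(_LEAF)
        left.append(_LEAF)
        right.append(_LEAF)
        value.append(0.0)
        return len(split_bit) - 1

    root = new_node()
    stack = [(np.arange(len(y_boot), dtype=np.intp), root)]
    while stack:
        idx, nid = stack.pop()
        y_node = y_boot[idx]
        n = y_node.size
        value[nid] = float(y_node.mean())
        if n < 2 * min_node_size or y_node.min() == y_node.max():
            continue
        sub = block_f[idx]
        bg, _ = _between_group_ss(y_node, sub)
        best = int(np.argmax(bg))
        if not np.isfinite(bg[best]) or bg[best] <= 0.0:
            continue
        on = sub[:, best] > 0.5
        split_bit[nid] = int(unique_bits[best])
        lid = new_node()
        rid = new_node()
        left[nid] = lid
        right[nid] = rid
        stack.append((idx[~on], lid))
        stack.append((idx[on], rid))

    return Tree(split_bit, left, right, value)


def draw_bootstrap(
    rng: np.random.Generator, n_samples: int, n_pool_bits: int, cfg: ForestConfig
) -> tuple[np.ndarray, np.ndarray]:
    """One tree's bootstrap draws: sample indices (with replacement, size
    ``floor(sample_fraction * n)``) and the unique set of ``bits_per_tree``
    bit indices drawn with replacement."""
    n_boot = max(int(cfg.sample_fraction * n_samples), 1)
    sample_idx = rng.integers(0, n_samples, size=n_boot)
    bit_draw = rng.integers(0, n_pool_bits, size=cfg.bits_per_tree)
    return sample_idx, np.unique(bit_draw)


def grow_tree(
    bits: BitMatrix,
    targets: np.ndarray,
    cfg: ForestConfig,
    tree_rng: np.random.Generator,
) -> Tree:
    targets = np.asarray(targets, dtype=np.float64)
    if bits.n_samples != targets.size:
        raise ValueError("bits.n_samples must equal len(targets)")
    sample_idx, unique_bits = draw_bootstrap(tree_rng, bits.n_samples, bits.n_bits, cfg)
    block = bits.extract(unique_bits, sample_idx)
    return _grow_from_draws(block, targets[sample_idx], unique_bits, cfg.min_node_size)


def fit_forest(bits: BitMatrix, targets: np.ndarray, cfg: ForestConfig) -> BitForest:
    """Grow ``cfg.n_trees`` independent trees from per-tree seed streams."""
    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.n_trees)
    trees = [
        grow_tree(bits, targets, cfg, np.random.Generator(np.random.PCG64(s))) for s in seqs
    ]
    return BitForest(trees, cfg, bits.n_bits)


def predict_forest(forest: BitForest, bits_new: BitMatrix) -> np.ndarray:
    """Mean of per-tree leaf values: a real value (regression) or a
    probability of class 1 (classification)."""
    if bits_new.n_bits != forest.n_pool_bits:
        raise ValueError(
            f"bit matrix has {bits_new.n_bits} bits but the forest was grown "
            f"on a pool of {forest.n_pool_bits}"
        )
    acc = np.zeros(bits_new.n_samples)
    for tree in forest.trees:
        acc += tree.predict(bits_new)
    return acc / len(forest.trees)
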