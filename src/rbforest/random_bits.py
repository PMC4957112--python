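"""The base learner: sparse 3-layer threshold networks with random weights.

Each network maps a standardized feature vector to a single bit.  Every
hidden node is wired to ``twist1`` distinct, uniformly chosen input features
with i.i.d. standard-normal weights; the top node combines the ``twist2``
hidden bits with standard-normal weights.  Both layers are strict
threshold units (output 1 iff the linear summation strictly exceeds the
threshold), and every threshold is data-driven: it is the node's own linear
summation evaluated at one uniformly chosen training sample.  Nothing is
trained — the randomness is the point; discriminative networks are found by
selection (see :mod:`rbforest.boost`), not by fitting weights.

With ``twist1 = twist2 = 1`` the network degenerates to an axis-parallel
threshold on a single raw feature, which serves as the internal
axis-parallel baseline/ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HiddenNode",
    "RandomBitNetwork",
    "NetworkBatch",
    "sample_network",
    "sample_networks",
    "evaluate_bit",
]

# Batched evaluation processes the pool in chunks of this many networks to
# bound the (n_samples, chunk, twist2, twist1) gather buffer.
_EVAL_CHUNK = 256


@dataclass
class HiddenNode:
    """One hidden threshold unit: ``twist1`` distinct inputs, normal weights."""

    feature_indices: np.ndarray  # int, length twist1, distinct
    weights: np.ndarray  # float, length twist1
    threshold: float

    def __post_init__(self):
        self.feature_indices = np.asarray(self.feature_indices, dtype=np.int64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.feature_indices) != len(self.weights):
            raise ValueError("feature_indices and weights must have equal length")
        if len(np.unique(self.feature_indices)) != len(self.feature_indices):
            raise ValueError("feature_indices must be distinct")


@dataclass
class RandomBitNetwork:
    """A full 3-layer network: ``twist2`` hidden nodes and one top unit."""

    hidden: list[HiddenNode]
    top_weights: np.ndarray
    top_threshold: float

    def __post_init__(self):
        self.top_weights = np.asarray(self.top_weights, dtype=np.float64)
        if len(self.hidden) != len(self.top_weights):
            raise ValueError("hidden and top_weights must have equal length")

    @property
    def twist1(self) -> int:
        return len(self.hidden[0].feature_indices)

    @property
    def twist2(self) -> int:
        return len(self.hidden)


class NetworkBatch:
    """A stack of same-shape networks stored as contiguous arrays.

    This is the performance-critical representation: candidate generation in
    the boosting loop and pool evaluation at predict time are batched tensor
    operations over these arrays.  ``to_networks()`` / ``from_networks()``
    convert to and from the per-network dataclass view.
    """

    __slots__ = ("feature_indices", "weights", "hidden_thresholds", "top_weights", "top_thresholds")

    def __init__(self, feature_indices, weights, hidden_thresholds, top_weights, top_thresholds):
        self.feature_indices = np.asarray(feature_indices, dtype=np.int64)  # (P, t2, t1)
        self.weights = np.asarray(weights, dtype=np.float64)  # (P, t2, t1)
        self.hidden_thresholds = np.asarray(hidden_thresholds, dtype=np.float64)  # (P, t2)
        self.top_weights = np.asarray(top_weights, dtype=np.float64)  # (P, t2)
        self.top_thresholds = np.asarray(top_thresholds, dtype=np.float64)  # (P,)

    def __len__(self) -> int:
        return self.feature_indices.shape[0]

    @property
    def twist1(self) -> int:
        return self.feature_indices.shape[2]

    @property
    def twist2(self) -> int:
        return self.feature_indices.shape[1]

    def __getitem__(self, i: int) -> RandomBitNetwork:
        hidden = [
            HiddenNode(self.feature_indices[i, k], self.weights[i, k], float(self.hidden_thresholds[i, k]))
            for k in range(self.twist2)
        ]
        return RandomBitNetwork(hidden, self.top_weights[i], float(self.top_thresholds[i]))

    def to_networks(self) -> list[RandomBitNetwork]:
        return [self[i] for i in range(len(self))]

    @classmethod
    def from_networks(cls, networks: list[RandomBitNetwork]) -> "NetworkBatch":
        return cls(
            np.stack([[h.feature_indices for h in net.hidden] for net in networks]),
            np.stack([[h.weights for h in net.hidden] for net in networks]),
            np.stack([[h.threshold for h in net.hidden] for net in networks]),
            np.stack([net.top_weights for net in networks]),
            np.array([net.top_threshold for net in networks]),
        )

    @classmethod
    def concatenate(cls, batches: list["NetworkBatch"]) -> "NetworkBatch":
        return cls(
            np.concatenate([b.feature_indices for b in batches]),
            np.concatenate([b.weights for b in batches]),
            np.concatenate([b.hidden_thresholds for b in batches]),
            np.concatenate([b.top_weights for b in batches]),
            np.concatenate([b.top_thresholds for b in batches]),
        )

    def evaluate(self, X_std: np.ndarray, chunk: int = _EVAL_CHUNK) -> np.ndarray:
        """Bits of every network on every sample: uint8 (n_samples, n_networks)."""
        X_std = np.asarray(X_std, dtype=np.float64)
        out = np.empty((X_std.shape[0], len(self)), dtype=np.uint8)
        for lo in range(0, len(self), chunk):
            hi = min(lo + chunk, len(self))
            # identical reduction order to sample_networks, so a stored
            # threshold ties exactly with its own sample's summation
            z = _hidden_summations(X_std, self.feature_indices[lo:hi], self.weights[lo:hi])
            h = (z > self.hidden_thresholds[lo:hi, :, None]).astype(np.float64)
            tz = _top_summations(h, self.top_weights[lo:hi])
            out[:, lo:hi] = (tz > self.top_thresholds[lo:hi, None]).T
        return out


def _hidden_summations(X_std: np.ndarray, feat_idx: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Linear summations z of every hidden node: (C, twist2, n_samples).

    The sum over the ``twist1`` inputs is accumulated term by term with
    elementwise operations rather than a fused reduction: elementwise IEEE
    arithmetic is independent of the batch shape, so a sample's summation
    (and hence any strict-``>`` threshold tie) is bit-identical whether the
    sample is evaluated alone or inside a batch.
    """
    t1 = feat_idx.shape[2]
    z = weights[:, :, 0, None] * X_std[:, feat_idx[:, :, 0]].transpose(1, 2, 0)
    for j in range(1, t1):
        z += weights[:, :, j, None] * X_std[:, feat_idx[:, :, j]].transpose(1, 2, 0)
    return z


def _top_summations(h: np.ndarray, top_weights: np.ndarray) -> np.ndarray:
    """Top-unit summations from hidden bits h (C, t2, n): (C, n_samples).

    Same term-by-term accumulation as :func:`_hidden_summations`, for the
    same batch-shape-independence reason.
    """
    t2 = h.shape[1]
    tz = top_weights[:, 0, None] * h[:, 0, :]
    for k in range(1, t2):
        tz += top_weights[:, k, None] * h[:, k, :]
    return tz


def sample_networks(
    X_std: np.ndarray,
    twist1: int,
    twist2: int,
    count: int,
    rng: np.random.Generator,
) -> tuple[NetworkBatch, np.ndarray]:
    """Draw ``count`` networks and evaluate them on the training sample.

    Thresholds are set from the data during sampling: each hidden node's
    threshold is its summation z at one uniformly chosen training sample,
    and the top threshold is chosen the same way from the top summations of
    the hidden-bit vectors.  Returns ``(batch, bits)`` with ``bits`` of shape
    ``(count, n_samples)`` (uint8) — the training bits come for free.

    The RNG draw order is fixed and documented (feature subsets, hidden
    weights, hidden threshold samples, top weights, top threshold samples),
    so a given generator state determines the batch exactly.
"""
    X_std = np.asarray(X_std, dtype=np.float64)
    n, n_features = X_std.shape
    if not 1 <= twist1 <= n_features:
        raise ValueError(f"twist1 must be in [1, n_features={n_features}], got {twist1}")
    if twist2 < 1:
        raise ValueError("twist2 must be >= 1")
    if n < 2:
        raise ValueError("need at least 2 samples to set data-driven thresholds")

    # Distinct uniform feature subsets: first twist1 entries of a uniform
    # random permutation per node, realised by ranking i.i.d. uniforms.
    u = rng.random((count, twist2, n_features))
    feat_idx = np.argsort(u, axis=-1, kind="stable")[..., :twist1].astype(np.int64)
    weights = rng.standard_normal((count, twist2, twist1))
    hid_sample = rng.integers(0, n, size=(count, twist2))
    top_weights = rng.standard_normal((count, twist2))
    top_sample = rng.integers(0, n, size=count)

    z = _hidden_summations(X_std, feat_idx, weights)  # (C, t2, n)
    hid_thr = np.take_along_axis(z, hid_sample[:, :, None], axis=2)[:, :, 0]
    h = (z > hid_thr[:, :, None]).astype(np.float64)
    tz = _top_summations(h, top_weights)  # (C, n)
    top_thr = tz[np.arange(count), top_sample]
    bits = (tz > top_thr[:, None]).astype(np.uint8)

    batch = NetworkBatch(feat_idx, weights, hid_thr, top_weights, top_thr)
    return batch, bits


def sample_network(
    n_features: int,
    twist1: int,
    twist2: int,
    X_std: np.ndarray,
    rng: np.random.Generator,
) -> RandomBitNetwork:
    """Draw a single network (see :func:`sample_networks` for the scheme)."""
    X_std = np.asarray(X_std, dtype=np.float64)
    if X_std.shape[1] != n_features:
        raise ValueError("X_std column count does not match n_features")
    batch, _ = sample_networks(X_std, twist1, twist2, 1, rng)
    return batch[0]


def evaluate_bit(net: RandomBitNetwork, X_std: np.ndarray) -> np.ndarray:
    """Deterministic bit of one network on each row of ``X_std`` (uint8).

    Strict ``>`` at both layers: a sample whose summation ties a threshold
    (in particular the very sample the threshold was taken from) emits 0 at
    that node.
    """
    X_std = np.asarray(X_std, dtype=np.float64)
    # term-by-term elementwise accumulation in the same order as the
    # batched path, so threshold ties resolve identically to it
    top_sum = None
    for k, node in enumerate(net.hidden):
        z = node.weights[0] * X_std[:, node.feature_indices[0]]
        for j in range(1, len(node.weights)):
            z += node.weights[j] * X_std[:, node.feature_indices[j]]
        term = net.top_weights[k] * (z > node.threshold).astype(np.float64)
        top_sum = term if top_sum is None else top_sum + term
    return (top_sum > net.top_threshold).astype(np.uint8)
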