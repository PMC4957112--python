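"""Gradient-boosting selection of the random-bit feature pool.

Rather than feeding raw random projections to the forest, the pool is built
by ``B`` independent least-squares boosting chains of ``S`` steps each.  A
chain keeps a working residual (initialised to the working target once per
chain); at every step it draws ``C`` candidate networks, scores each by the
residual variance it explains — the between-group sum of squares of the
residual split by the candidate's bit — keeps the best, and subtracts the
selected bit's conditional group means from the residual.  Subtracting the
conditional means removes exactly the explained component, so the chain's
sum of squared residuals is non-increasing.  The ``B * S`` selected
networks, in chain-major order, form the feature pool.

Selection is what makes a ~10,000-bit budget effective: each kept bit must
explain residual structure the earlier bits in its chain did not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .bitstore import BitMatrix, pack
from .random_bits import NetworkBatch, RandomBitNetwork, sample_networks

__all__ = [
    "BoostConfig",
    "ChainResult",
    "explained_variance",
    "explained_variance_many",
    "update_residual",
    "run_chain",
    "build_pool",
]


@dataclass(frozen=True)
class BoostConfig:
    """Pool-construction parameters.

    B chains of S steps give a pool of ``B * S`` bits; C candidates compete
    at every step (C > 100 recommended — C = 1 disables selection and
    degenerates to naive random projection).
    """

    B: int = 256
    S: int = 40
    C: int = 128
    twist1: int = 3
    twist2: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("B", "S", "C", "twist1", "twist2"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def pool_size(self) -> int:
        return self.B * self.S


@dataclass
class ChainResult:
    """One chain's selected networks, their training bits, and final SSE."""

    networks: list[RandomBitNetwork]
    train_bits: list[np.ndarray]
    final_sse: float


def explained_variance(residual: np.ndarray, bits: np.ndarray) -> float:
    """Between-group sum of squares of ``residual`` split by a binary vector.

    Equals ``n0*(m0 - m)**2 + n1*(m1 - m)**2`` with ``m`` the grand mean and
    ``m0``/``m1`` the group means; 0 when either group is empty.
    """
    residual = np.asarray(residual, dtype=np.float64)
    bits = np.asarray(bits)
    if residual.size == 0:
        raise ValueError("empty residual")
    if residual.shape != bits.shape:
        raise ValueError("residual and bits must have equal length")
    n = residual.size
    n1 = int(bits.sum())
    if n1 == 0 or n1 == n:
        return 0.0
    bf = np.asarray(bits, dtype=np.float64)
    # both group sums computed directly -> score is exactly invariant under
    # complementing the bit vector (ties resolve consistently)
    s1 = float(residual @ bf)
    s0 = float(residual @ (1.0 - bf))
    n0 = n - n1
    return s1 * s1 / n1 + s0 * s0 / n0 - (s1 + s0) * (s1 + s0) / n


def explained_variance_many(residual: np.ndarray, bits: np.ndarray) -> np.ndarray:
    """Vectorised :func:`explained_variance` for bits of shape (C, n)."""
    residual = np.asarray(residual, dtype=np.float64)
    n = residual.size
    bf = bits.astype(np.float64)
    n1 = bf.sum(axis=1)
    s1 = bf @ residual
    s0 = (1.0 - bf) @ residual
    n0 = n - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        var = s1 * s1 / n1 + s0 * s0 / n0 - (s1 + s0) * (s1 + s0) / n
    var[(n1 == 0) | (n0 == 0)] = 0.0
    return var


def update_residual(residual: np.ndarray, bits: np.ndarray) -> np.ndarray:
    """One boosting update: subtract the conditional mean of each group.

    ``residual(i) -= Mean[bit(i)]``; the mean over an empty group is taken
    as 0 (no sample receives it).  Removes exactly the between-group plus
    grand-mean component, so the sum of squares never increases.
    """
    residual = np.asarray(residual, dtype=np.float64)
    b = np.asarray(bits).astype(bool)
    n1 = int(b.sum())
    mean1 = residual[b].mean() if n1 else 0.0
    mean0 = residual[~b].mean() if n1 < residual.size else 0.0
    return residual - np.where(b, mean1, mean0)


def run_chain(
    Y_work: np.ndarray,
    X_std: np.ndarray,
    cfg: BoostConfig,
    chain_rng: np.random.Generator,
    record: Callable[[int, NetworkBatch, np.ndarray, np.ndarray, int], None] | None = None,
) -> ChainResult:
    """Run one boosting chain of ``cfg.S`` steps.

    The residual starts at ``Y_work``.  Each step draws ``cfg.C`` candidates,
    selects the strictly-largest explained variance (first candidate wins
    ties, matching a ``Var > MaxVar`` scan from 0), and updates
    ``residual -= Mean[selected bit value]`` per sample.  If every candidate
    scores 0 the first candidate is stored to keep the pool aligned and the
    residual is left untouched.

    ``record``, if given, is called per step with
    ``(step, batch, candidate_bits, variances, selected_index)`` — a test
    hook for auditing the argmax against the actual candidate set.
    """
    Y_work = np.asarray(Y_work, dtype=np.float64)
    if Y_work.size < 2:
        raise ValueError("need at least 2 samples")
    residual = Y_work.copy()
    networks: list[RandomBitNetwork] = []
    train_bits: list[np.ndarray] = []

    for step in range(cfg.S):
        batch, bits = sample_networks(X_std, cfg.twist1, cfg.twist2, cfg.C, chain_rng)
        var = explained_variance_many(residual, bits)
        max_var = var.max()
        if max_var > 0.0:
            best = int(np.argmax(var))  # first index attaining the max
            residual = update_residual(residual, bits[best])
        else:
            best = 0  # no candidate explains anything; store a placeholder bit
        if record is not None:
            record(step, batch, bits, var, best)
        networks.append(batch[best])
        train_bits.append(bits[best])

    return ChainResult(networks, train_bits, float(residual @ residual))


def build_pool(
    Y_work: np.ndarray,
    X_std: np.ndarray,
    cfg: BoostConfig,
) -> tuple[NetworkBatch, BitMatrix, np.ndarray]:
    """Run ``cfg.B`` independent chains and collect the pool.

    Per-chain generators are spawned deterministically from ``cfg.seed``, so
    chains share no state and any execution order yields an identical pool;
    order in the pool is chain-major (chain * S + step).  Returns the pooled
    networks, the packed training bits (one column per pool bit), and the
    per-chain final SSEs.
    """
    X_std = np.asarray(X_std, dtype=np.float64)
    seqs = np.random.SeedSequence(cfg.seed).spawn(cfg.B)
    chains = [run_chain(Y_work, X_std, cfg, np.random.Generator(np.random.PCG64(s))) for s in seqs]

    pool = NetworkBatch.from_networks([net for ch in chains for net in ch.networks])
    cols = [b for ch in chains for b in ch.train_bits]
    bit_matrix = pack(cols, n_samples=len(Y_work))
    sses = np.array([ch.final_sse for ch in chains])
    return pool, bit_matrix, sses
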