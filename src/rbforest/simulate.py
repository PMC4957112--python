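"""Seeded synthetic benchmark generators.

Four task families exercise the regimes the method is built for:

* ``gen_hill_valley`` — a *deep* task: length-100 series that are a random
  flat baseline plus a single Gaussian bump, upward ("hill") or downward
  ("valley"), under additive noise.  No single time point is informative
  because the baseline shifts the whole series, so axis-parallel learners
  struggle; recognising the bump requires combining points.
* ``gen_oblique`` — a linear boundary deliberately not aligned with any
  axis, with optional label noise.
* ``gen_surface`` — a smooth nonlinear regression surface on the unit
  square (altitude-map style).
* ``gen_genotypes`` — biallelic SNPs under Hardy–Weinberg equilibrium with
  a sparse additive log-odds disease model, for the GWAS pipeline.  No
  linkage disequilibrium or population structure is simulated.

Every generator is a pure function of its arguments: equal seeds give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "gen_hill_valley",
    "gen_oblique",
    "gen_surface",
    "gen_genotypes",
    "GenotypeData",
    "FIXTURE_VERSION",
]

# Bump fixture versioning: the functional forms below are frozen; any change
# must bump this so downstream golden tests fail loudly.
FIXTURE_VERSION = 1


def gen_hill_valley(
    n: int,
    length: int = 100,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced hill/valley series classification data.

    Each row is ``baseline + sign * bump + noise`` evaluated at integer
    times ``t = 0..length-1``: baseline ~ U(0, 10) (constant over the row),
    bump ``a * exp(-(t - c)^2 / (2 w^2))`` with amplitude a ~ U(1, 5),
    centre c ~ U(0.2 L, 0.8 L), width w ~ U(5, 15); sign +1 for hills
    (y = 1) and -1 for valleys (y = 0); i.i.d. N(0, noise_sd) noise per
    point.  Class counts differ by at most one and rows are shuffled.
    """
    if length < 10:
        raise ValueError("length must be >= 10")
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[: (n + 1) // 2] = 1
    y = y[rng.permutation(n)]

    t = np.arange(length, dtype=np.float64)
    baseline = rng.uniform(0.0, 10.0, size=n)
    amp = rng.uniform(1.0, 5.0, size=n)
    centre = rng.uniform(0.2 * length, 0.8 * length, size=n)
    width = rng.uniform(5.0, 15.0, size=n)
    sign = np.where(y == 1, 1.0, -1.0)

    bump = amp[:, None] * np.exp(-((t[None, :] - centre[:, None]) ** 2) / (2 * width[:, None] ** 2))
    X = baseline[:, None] + sign[:, None] * bump
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=(n, length))
    return X, y


def gen_oblique(
    n: int,
    d: int,
    margin_noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Oblique (non-axis-parallel) linear boundary in d dimensions.

    X ~ N(0, I); y = 1[w . x > 0] for a fixed random unit vector w drawn
    from the seed; labels are then flipped independently with probability
    ``margin_noise``.
    """
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(d)
    w /= np.linalg.norm(w)
    X = rng.standard_normal((n, d))
    y = (X @ w > 0).astype(int)
    if margin_noise > 0:
        flips = rng.random(n) < margin_noise
        y = np.where(flips, 1 - y, y)
    return X, y


def gen_surface(
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth 2-D regression surface (altitude prediction analogue).

    X uniform on the unit square;
    ``y = sin(4 pi x1) * cos(4 pi x2) + 0.5 x1 + N(0, noise_sd)``.
    """
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n, 2))
    y = np.sin(4 * np.pi * X[:, 0]) * np.cos(4 * np.pi * X[:, 1]) + 0.5 * X[:, 0]
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return X, y


@dataclass
class GenotypeData:
    """A simulated case-control genotype panel.

    ``G`` holds minor-allele counts in {0, 1, 2} (n x m); ``y`` the binary
    phenotype; ``maf`` the per-SNP minor-allele frequency used;
    ``causal_indices`` the SNP columns that carry the effect.
    """

    G: np.ndarray
    y: np.ndarray
    maf: np.ndarray
    causal_indices: np.ndarray


def gen_genotypes(
    n: int,
    m_snps: int,
    n_causal: int,
    beta: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
    prevalence_intercept: float = 0.0,
    seed: int = 0,
) -> GenotypeData:
    """Hardy–Weinberg genotypes with an additive log-odds disease model.

    Per SNP, maf ~ U(maf_range) and genotypes ~ Binomial(2, maf).  The
    liability is ``intercept + sum_causal beta * (g - 2 maf)`` (mean-centred
    additive coding) and ``y ~ Bernoulli(logistic(liability))``.  Causal
    SNPs are a uniform random subset of columns.
    """
    if n_causal > m_snps:
        raise ValueError("n_causal cannot exceed m_snps")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, size=m_snps)
    G = rng.binomial(2, maf[None, :], size=(n, m_snps)).astype(np.int8)
    causal = np.sort(rng.choice(m_snps, size=n_causal, replace=False))
    centred = G[:, causal].astype(np.float64) - 2.0 * maf[causal][None, :]
    liability = prevalence_intercept + beta * centred.sum(axis=1)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-liability))).astype(int)
    return GenotypeData(G, y, maf, causal)
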