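"""Case-control GWAS prediction pipeline.

Workflow: score every SNP on the training cohort with the allelic
(allele-count) chi-square association test, rank by p-value, sweep the
number of top-ranked SNPs fed to a learner by AUC on an independent test
cohort, and report final cross-validated and test-set performance at the
chosen size.

Choosing the SNP count on the *test* cohort reproduces the original study
design faithfully but is optimistically biased; every sweep report carries
that caveat explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from sklearn.base import clone

from .metrics import CVResult, ROCResult, kfold_cv, roc_auc, roc_report

__all__ = [
    "AssociationResult",
    "SweepResult",
    "GwasReport",
    "allelic_assoc",
    "assoc_table",
    "rank_snps",
    "sweep_k",
    "final_report",
    "SELECTION_BIAS_NOTE",
]

SELECTION_BIAS_NOTE = (
    "The number of SNPs was chosen by maximising AUC on the independent "
    "test cohort; the reported test AUC is therefore optimistically biased."
)


@dataclass
class AssociationResult:
    """One SNP's allelic association summary against a binary phenotype."""

    snp_index: int
    chi2: float
    p: float
    odds_ratio: float  # NaN when any allele-count cell is zero
    r_squared: float


def _allele_counts(genotypes: np.ndarray, phenotype: np.ndarray) -> tuple[int, int, int, int]:
    case = phenotype == 1
    n_case = int(case.sum())
    n_ctrl = int(phenotype.size - n_case)
    a = int(genotypes[case].sum())  # case minor alleles
    c = int(genotypes[~case].sum())  # control minor alleles
    return a, 2 * n_case - a, c, 2 * n_ctrl - c


def allelic_assoc(genotypes, phenotype, snp_index: int = 0) -> AssociationResult:
    """Allelic chi-square test of one SNP (each subject contributes 2 alleles).

    The 2x2 table is (case minor a, case major b; control minor c, control
    major d); ``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))`` with
    ``N = a+b+c+d`` and p from the 1-df chi-square distribution.  A zero
    marginal gives chi2 = 0; any zero cell leaves the odds ratio missing
    (NaN) rather than zero or infinite.
    """
    genotypes = np.asarray(genotypes)
    phenotype = np.asarray(phenotype)
    if not np.isin(np.unique(genotypes), (0, 1, 2)).all():
        raise ValueError("genotypes must be coded 0/1/2")
    uniq = np.unique(phenotype)
    if not (np.isin(uniq, (0, 1)).all() and uniq.size == 2):
        raise ValueError("phenotype must be binary 0/1 with both classes present")

    a, b, c, d = _allele_counts(genotypes, phenotype)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = n * (a * d - b * c) ** 2 / denom
        p = float(chi2_dist.sf(chi2, 1))
    oratio = a * d / (b * c) if min(a, b, c, d) > 0 else float("nan")
    g = genotypes.astype(np.float64)
    if g.std() == 0.0 or phenotype.std() == 0.0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(g, phenotype)[0, 1] ** 2)
    return AssociationResult(int(snp_index), float(chi2), float(p), float(oratio), r2)


def _assoc_scan(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised chi2 and p for every SNP column of G."""
    G = np.asarray(G, dtype=np.float64)
    y = np.asarray(y)
    case = y == 1
    n_case = int(case.sum())
    n_ctrl = int(y.size - n_case)
    a = G[case].sum(axis=0)
    c = G[~case].sum(axis=0)
    b = 2.0 * n_case - a
    d = 2.0 * n_ctrl - c
    n = 2.0 * y.size
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / denom
    chi2 = np.where(denom == 0.0, 0.0, chi2)
    p = chi2_dist.sf(chi2, 1)
    return chi2, p


def assoc_table(G, y) -> pd.DataFrame:
    """Per-SNP association table: chi2, p, odds ratio, r^2."""
    G = np.asarray(G)
    rows = [allelic_assoc(G[:, j], y, j) for j in range(G.shape[1])]
    return pd.DataFrame(
        {
            "snp_index": [r.snp_index for r in rows],
            "chi2": [r.chi2 for r in rows],
            "p": [r.p for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "r_squared": [r.r_squared for r in rows],
        }
    )


def rank_snps(G, y) -> np.ndarray:
    """SNP indices ordered by ascending association p-value.

    Stable: ties (equal p) break by ascending SNP index, so a ranking
    restricted to any subset of SNPs is consistent with the full ranking.
    """
    G = np.asarray(G)
    _, p = _assoc_scan(G, y)
    return np.lexsort((np.arange(G.shape[1]), p))


@dataclass
class SweepResult:
    table: pd.DataFrame  # columns: k, test_auc
    best_k: int
    ranking: np.ndarray
    note: str = SELECTION_BIAS_NOTE


def sweep_k(train, test, k_grid, estimator) -> SweepResult:
    """Test-set AUC for each top-k SNP subset; ``best_k`` maximises it.

    ``train``/``test`` are ``(G, y)`` pairs; SNPs are ranked on the training
    cohort only.  Ties in the AUC maximum go to the smaller k; k values
    exceeding the SNP count are skipped with a warning.
    """
    G_tr, y_tr = train
    G_te, y_te = test
    G_tr = np.asarray(G_tr)
    G_te = np.asarray(G_te)
    m = G_tr.shape[1]
    ranking = rank_snps(G_tr, y_tr)

    ks, aucs = [], []
    for k in k_grid:
        if k > m:
            warnings.warn(f"skipping k={k}: only {m} SNPs available", stacklevel=2)
            continue
        top = ranking[:k]
        est = clone(estimator)
        est.fit(G_tr[:, top].astype(np.float64), y_tr)
        scores = est.predict_proba(G_te[:, top].astype(np.float64))[:, 1]
        ks.append(int(k))
        aucs.append(roc_auc(scores, np.asarray(y_te)))
    if not ks:
        raise ValueError("no valid k in k_grid")
    table = pd.DataFrame({"k": ks, "test_auc": aucs})
    best_k = int(table.loc[table["test_auc"].idxmax(), "k"])  # idxmax -> first max, smaller k
    return SweepResult(table, best_k, ranking)


@dataclass
class GwasReport:
    best_k: int
    snp_indices: np.ndarray
    cv: CVResult
    test: ROCResult
    note: str = SELECTION_BIAS_NOTE


def final_report(train, test, best_k: int, estimator, cv_folds: int = 10, seed: int = 0) -> GwasReport:
    """Final evaluation at the chosen SNP count.

    Reports stratified ``cv_folds``-fold cross-validation metrics on the
    training cohort and the independent-test ROC analysis (AUC with
    Hanley–McNeil CI, Youden operating point) of a model fitted on the full
    training cohort.
    """
    G_tr, y_tr = train
    G_te, y_te = test
    ranking = rank_snps(G_tr, y_tr)
    top = ranking[:best_k]
    Xtr = np.asarray(G_tr)[:, top].astype(np.float64)
    Xte = np.asarray(G_te)[:, top].astype(np.float64)

    cv = kfold_cv(Xtr, np.asarray(y_tr), estimator, k=cv_folds, seed=seed)
    est = clone(estimator)
    est.fit(Xtr, np.asarray(y_tr))
    scores = est.predict_proba(Xte)[:, 1]
    test_rep = roc_report(scores, np.asarray(y_te))
    return GwasReport(int(best_k), top, cv, test_rep)
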