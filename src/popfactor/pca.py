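"""Principal component analysis of standardized genotype matrices.

PCA is cast as matrix factorization: the standardized matrix Z is
approximated by the best rank-K product Lambda F with orthogonal loading
columns and orthonormal factor rows (the SVD solution).  Standardizing
removes the column means, so on the raw allele-count scale PCA implies a
(K+1)-factor model whose extra factor is the vector of genotype means
with an all-ones loading; ``implied_raw_factorization`` materializes
that representation so PCA can be compared like-for-like with the
sparse-factor and admixture factorizations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from popfactor.io import GenotypeMatrix

log = logging.getLogger("popfactor")


@dataclass
class PcaResult:
    loadings: np.ndarray           # n x K, columns orthogonal, scaled by singular values
    factors: np.ndarray            # K x p, rows orthonormal
    singular_values: np.ndarray    # K, non-increasing
    column_means: np.ndarray       # p-vector (retained SNPs)
    column_sds: np.ndarray         # p-vector (retained SNPs, ddof=1)
    snp_ids: list[str]
    dropped_snp_ids: list[str]

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of the covariance of standardized individuals."""
        n = self.loadings.shape[0]
        return self.singular_values**2 / (n - 1)


def _values_ids(X):
    if isinstance(X, GenotypeMatrix):
        return X.values, list(X.snp_ids)
    Xv = np.asarray(X, dtype=float)
    return Xv, [f"snp{j}" for j in range(Xv.shape[1])]


def standardize(X) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Mean-center each SNP column and divide by its sample standard
    deviation (denominator n-1).  Monomorphic (zero-variance) columns are
    undefined under this scaling and are dropped; their ids are returned.
    """
    Xv, snp_ids = _values_ids(X)
    means = Xv.mean(axis=0)
    sds = Xv.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all SNP columns are monomorphic; nothing to standardize")
    dropped = [sid for sid, k in zip(snp_ids, keep) if not k]
    if dropped:
        log.warning("dropped %d monomorphic SNPs before standardization", len(dropped))
    Z = (Xv[:, keep] - means[keep]) / sds[keep]
    return Z, means[keep], sds[keep], dropped


def pca_fit(X, K: int) -> PcaResult:
    """PCA of the standardized genotype matrix via SVD.

    Loadings are the first K left singular vectors scaled by their
    singular values; factors are the first K right singular vectors.  The
    rank-K product is the best rank-K approximation of Z in squared
    error.  Sign convention: the largest-magnitude entry of each factor
    row is made positive, so output is deterministic.
    """
    Xv, snp_ids = _values_ids(X)
    Z, means, sds, dropped = standardize(Xv)
    kept_ids = [sid for sid in snp_ids if sid not in set(dropped)]
    if K > min(Z.shape):
        raise ValueError(f"K={K} exceeds min(n, p_retained)={min(Z.shape)}")
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    U, s, Vt = U[:, :K], s[:K], Vt[:K]
    for k in range(K):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    return PcaResult(
        loadings=U * s,
        factors=Vt,
        singular_values=s,
        column_means=means,
        column_sds=sds,
        snp_ids=kept_ids,
        dropped_snp_ids=dropped,
    )


def implied_raw_factorization(result: PcaResult, K: int | None = None):
    """The factorization of the raw allele-count matrix implied by
    standardized PCA: factor 0 is the vector of genotype column means
    with loading 1 for every individual, and factors 1..K are the PCA
    factors rescaled by the column standard deviations.  The product
    reconstructs X with the error of the rank-K approximation of Z
    (reweighted by the sds).
    """
    if K is None:
        K = result.factors.shape[0]
    if K > result.factors.shape[0]:
        raise ValueError("K exceeds the number of fitted components")
    n = result.loadings.shape[0]
    Lambda_aug = np.column_stack([np.ones(n), result.loadings[:, :K]])
    F_aug = np.vstack([result.column_means, result.factors[:K] * result.column_sds])
    return Lambda_aug, F_aug
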