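"""Cross-method and cross-run comparison utilities.

Factor models are identified only up to permutation, sign and (for some
methods) scale of their components, so comparing two fits requires
matching components first.  ``match_factors`` resolves label switching
by optimal assignment on absolute Pearson correlation;
``procrustes_align`` resolves the rotational ambiguity of loadings;
``loadings_to_admixture`` converts all-positive sparse-factor loadings
into admixture-proportion estimates; ``robustness_experiment`` measures
how much each method's loadings move when part of one group is removed
from the sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import orthogonal_procrustes
from scipy.optimize import linear_sum_assignment

from popfactor.admixture import admix_fit
from popfactor.pca import pca_fit
from popfactor.sfa import SfaConfig, fit_sfa

log = logging.getLogger("popfactor")


@dataclass
class FactorMatch:
    permutation: np.ndarray    # matched[k] of A corresponds to B[k]
    signs: np.ndarray          # +/-1 per matched pair
    correlations: np.ndarray   # matched absolute Pearson correlations


def _safe_corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between all row pairs; zero-variance rows get
    correlation 0 by convention."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    an = np.linalg.norm(Ac, axis=1)
    bn = np.linalg.norm(Bc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (Ac @ Bc.T) / np.outer(an, bn)
    C[~np.isfinite(C)] = 0.0
    return C


def match_factors(A: np.ndarray, B: np.ndarray) -> FactorMatch:
    """Bijection between the rows of A and B maximizing the total
    absolute Pearson correlation (Hungarian assignment).  Signs are
    chosen so matched correlations are nonnegative; ties break toward
    the lowest index (linear_sum_assignment is deterministic)."""
    A = np.atleast_2d(A)
    B = np.atleast_2d(B)
    if A.shape != B.shape:
        raise ValueError("match_factors requires equal shapes")
    C = _safe_corr_matrix(A, B)
    rows, cols = linear_sum_assignment(-np.abs(C))
    # permutation[k] = row of A matched to row k of B
    perm = np.empty(A.shape[0], dtype=int)
    perm[cols] = rows
    matched = C[perm, np.arange(A.shape[0])]
    signs = np.where(matched < 0, -1.0, 1.0)
    return FactorMatch(permutation=perm, signs=signs, correlations=np.abs(matched))


def procrustes_align(L: np.ndarray, target: np.ndarray):
    """Orthogonal matrix R minimizing ||L R - target||_F; returns
    (R, L @ R).  Rank-deficient crossproducts fall back to the SVD's
    smallest-singular-value convention with a warning."""
    L = np.asarray(L, dtype=float)
    target = np.asarray(target, dtype=float)
    if L.shape != target.shape:
        raise ValueError("procrustes_align requires equal shapes")
    M = L.T @ target
    if np.linalg.matrix_rank(M) < M.shape[0]:
        log.warning("rank-deficient crossproduct in Procrustes alignment; "
                    "rotation not unique (SVD convention used)")
    R, _ = orthogonal_procrustes(L, target)
    return R, L @ R


def loadings_to_admixture(Lambda: np.ndarray) -> np.ndarray:
    """Normalize all-positive loading rows to admixture proportions.

    Valid only when every loading in a row is strictly positive (the
    factors then represent ancestral-population allele frequencies on
    comparable scales); rows violating positivity are returned as NaN.
    Accepts a single k-vector or an n x k matrix.
    """
    Lam = np.atleast_2d(np.asarray(Lambda, dtype=float))
    out = np.full_like(Lam, np.nan)
    ok = np.all(Lam > 0, axis=1)
    out[ok] = Lam[ok] / Lam[ok].sum(axis=1, keepdims=True)
    return out[0] if np.asarray(Lambda).ndim == 1 else out


def _fit_loadings(X: np.ndarray, method: str, K: int, seed: int):
    """Loadings (n x K) and factors (K x p) for one method, used by the
    robustness experiment."""
    if method == "sfa":
        model = fit_sfa(X, SfaConfig(K=K, mean_term=False, seed=seed))
        return model.Omega, model.F
    if method == "pca":
        res = pca_fit(X, K)
        # re-embed factors over all p SNPs (zeros at dropped monomorphic
        # columns) so fits on different subsamples stay comparable
        if res.dropped_snp_ids:
            kept = np.array([sid not in set(res.dropped_snp_ids)
                             for sid in (f"snp{j}" for j in range(X.shape[1]))])
            full = np.zeros((K, X.shape[1]))
            full[:, kept] = res.factors
            return res.loadings, full
        return res.loadings, res.factors
    if method == "admixture":
        res = admix_fit(X, K, seed=seed)
        return res.Q, res.P
    raise ValueError(f"unknown method: {method!r}")


def robustness_experiment(
    X: np.ndarray,
    group_labels: np.ndarray,
    drop_group,
    drop_fraction: float,
    methods: tuple[str, ...] = ("sfa", "pca", "admixture"),
    K: int = 3,
    seed: int = 0,
) -> dict[str, float]:
    """Sensitivity of each method's loadings to the sampling scheme.

    Fits each method on the full sample and on a reduced sample with
    ``drop_fraction`` of ``drop_group`` removed, matches components via
    the factors (over SNPs), and reports the Pearson correlation of the
    retained individuals' loadings between the two fits (mean across
    matched components).  Correlations are computed over individuals.
    """
    X = np.asarray(X, dtype=float)
    group_labels = np.asarray(group_labels)
    in_group = np.where(group_labels == drop_group)[0]
    if in_group.size == 0:
        raise ValueError(f"no individuals in group {drop_group!r}")
    n_drop = int(round(drop_fraction * in_group.size))
    if drop_fraction > 0 and n_drop == 0:
        raise ValueError("group too small to drop the requested fraction")
    rng = np.random.default_rng(seed)
    dropped = rng.choice(in_group, size=n_drop, replace=False)
    keep = np.setdiff1d(np.arange(X.shape[0]), dropped)

    results: dict[str, float] = {}
    for method in methods:
        L_full, F_full = _fit_loadings(X, method, K, seed)
        L_red, F_red = _fit_loadings(X[keep], method, K, seed)
        match = match_factors(F_red, F_full)
        L_red_matched = L_red[:, match.permutation] * match.signs[None, :]
        corrs = [
            abs(np.corrcoef(L_full[keep, k], L_red_matched[:, k])[0, 1])
            for k in range(L_full.shape[1])
        ]
        results[method] = float(np.mean(corrs))
    return results
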