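"""Binomial admixture model as a constrained matrix factorization.

Each genotype x_ij is Binomial(2, (QP)_ij): Q (n x K) holds admixture
proportions with rows on the simplex, P (K x p) holds population allele
frequencies in [0, 1].  The product QP is the expected allele frequency
of each individual at each SNP, so the model is the factorization X ~ 2 QP
with a convexity constraint on the loadings.  Fitting is by EM over the
latent assignment of each allele copy to a source population, which
keeps the constraints satisfied exactly after every M-step and increases
the likelihood monotonically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from popfactor.io import GenotypeMatrix

log = logging.getLogger("popfactor")

_EPS = 1e-9  # probability clamp


@dataclass
class AdmixResult:
    Q: np.ndarray                       # n x K admixture proportions, simplex rows
    P: np.ndarray                       # K x p allele frequencies in [0, 1]
    loglik_trace: list[float] = field(default_factory=list)


def _values(X) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def admix_loglik(X, Q: np.ndarray, P: np.ndarray) -> float:
    """Binomial log likelihood sum_ij log Bin(x_ij; 2, (QP)_ij), with the
    success probability clamped to [eps, 1-eps]."""
    Xv = _values(X)
    prob = np.clip(Q @ P, _EPS, 1.0 - _EPS)
    # log C(2, x) = log 2 for x == 1, else 0
    combo = np.where(Xv == 1.0, np.log(2.0), 0.0)
    return float(np.sum(combo + Xv * np.log(prob) + (2.0 - Xv) * np.log1p(-prob)))


def admix_fit(
    X,
    K: int,
    seed: int = 0,
    max_iter: int = 2000,
    rel_tol: float = 1e-6,
    n_restarts: int = 1,
) -> AdmixResult:
    """Fit Q and P by EM.

    E-step: expected allele-copy counts assigned to each population,
    a_ijk = x_ij q_ik p_kj / (QP)_ij for the reference allele and
    b_ijk = (2-x_ij) q_ik (1-p_kj) / (Q(1-P))_ij for the alternate.
    M-step: p_kj = sum_i a / sum_i (a+b), q_ik = sum_j (a+b) / 2p.
    The likelihood is non-decreasing; stops on relative tolerance.
    P is initialized from perturbed overall frequencies and Q from a
    symmetric Dirichlet(1); with restarts the best final likelihood wins.
    """
    Xv = _values(X)
    if not np.allclose(Xv, np.rint(Xv)) or Xv.min() < 0 or Xv.max() > 2:
        raise ValueError("admixture model requires integer genotypes in {0,1,2}")
    best: AdmixResult | None = None
    for r in range(n_restarts):
        res = _admix_fit_once(Xv, K, int((seed + r) % (2**31)), max_iter, rel_tol)
        if best is None or res.loglik_trace[-1] > best.loglik_trace[-1]:
            best = res
    return best


def _em_step(Xv, Alt, Q, P, rng, base):
    """One EM sweep.  E: expected allele-copy counts per population;
    M: closed-form Q and P.  Empty components are re-seeded."""
    p = Xv.shape[1]
    ref_mix = np.clip(Q @ P, _EPS, None)            # (n, p)
    alt_mix = np.clip(Q @ (1.0 - P), _EPS, None)
    Ra = Xv / ref_mix
    Rb = Alt / alt_mix
    # summed expected counts; the n x p x K array is never formed
    A_cols = (Q.T @ Ra) * P                          # (K, p): sum_i a_ijk
    B_cols = (Q.T @ Rb) * (1.0 - P)                  # (K, p): sum_i b_ijk
    A_rows = (Ra @ P.T) * Q                          # (n, K): sum_j a_ijk
    B_rows = (Rb @ (1.0 - P).T) * Q                  # (n, K): sum_j b_ijk

    resp = A_cols + B_cols
    P_new = P.copy()
    empty = resp.sum(axis=1) < 1e-12
    for k in np.where(empty)[0]:
        log.warning("admixture component %d empty; re-seeding its frequencies", k)
        P_new[k] = np.clip(base + 0.1 * rng.standard_normal(p), _EPS, 1.0 - _EPS)
    alive = ~empty
    P_new[alive] = A_cols[alive] / np.maximum(resp[alive], 1e-300)
    P_new = np.clip(P_new, _EPS, 1.0 - _EPS)
    Q_new = (A_rows + B_rows) / (2.0 * p)
    Q_new /= Q_new.sum(axis=1, keepdims=True)  # guard tiny drift off the simplex
    return Q_new, P_new


def _project(Q, P):
    Q = np.maximum(Q, 0.0)
    Q /= Q.sum(axis=1, keepdims=True)
    return Q, np.clip(P, _EPS, 1.0 - _EPS)


def _admix_fit_once(Xv, K, seed, max_iter, rel_tol) -> AdmixResult:
    """Safeguarded SQUAREM-accelerated EM.

    Each cycle takes two plain EM steps, extrapolates along the implied
    direction (Varadhan-Roland squared extrapolation), projects back to
    the constraint set, and stabilizes with one more EM step; whenever
    the extrapolated point does not improve on the two plain steps, the
    plain steps are kept.  Fixed points coincide with EM's, and because
    the fallback is always available the recorded likelihood trace is
    non-decreasing, as for plain EM.  ``max_iter`` counts EM sweeps.
    """
    n, p = Xv.shape
    rng = np.random.default_rng(seed)
    base = np.clip(Xv.mean(axis=0) / 2.0, 0.05, 0.95)
    P = np.clip(base[None, :] + 0.1 * rng.standard_normal((K, p)), _EPS, 1.0 - _EPS)
    Q = rng.dirichlet(np.ones(K), size=n)

    Alt = 2.0 - Xv
    ll = admix_loglik(Xv, Q, P)
    trace = [ll]
    sweeps = 0
    while sweeps < max_iter:
        Q1, P1 = _em_step(Xv, Alt, Q, P, rng, base)
        Q2, P2 = _em_step(Xv, Alt, Q1, P1, rng, base)
        sweeps += 2
        rQ, rP = Q1 - Q, P1 - P
        vQ, vP = (Q2 - Q1) - rQ, (P2 - P1) - rP
        vnorm = np.sqrt((vQ**2).sum() + (vP**2).sum())
        ll_new = admix_loglik(Xv, Q2, P2)
        Qn, Pn = Q2, P2
        if vnorm > 1e-30:
            alpha = -np.sqrt(((rQ**2).sum() + (rP**2).sum())) / vnorm
            alpha = min(alpha, -1.0)
            Qs, Ps = _project(Q - 2 * alpha * rQ + alpha**2 * vQ,
                              P - 2 * alpha * rP + alpha**2 * vP)
            Qs, Ps = _em_step(Xv, Alt, Qs, Ps, rng, base)
            sweeps += 1
            ll_s = admix_loglik(Xv, Qs, Ps)
            if np.isfinite(ll_s) and ll_s > ll_new:
                Qn, Pn, ll_new = Qs, Ps, ll_s
        Q, P = Qn, Pn
        trace.append(ll_new)
        if abs(ll_new - ll) / (abs(ll) + 1e-12) < rel_tol:
            break
        ll = ll_new
    return AdmixResult(Q=Q, P=P, loglik_trace=trace)


UNIT_SQUARE_CORNERS = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


def assign_components_to_corners(Q: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Order four admixture components by habitat corner.

    Component labels are arbitrary, so before the 2-D mapping each
    component is assigned to the habitat corner nearest its
    loading-weighted centroid (Hungarian assignment).  Returns the
    permutation ``perm`` such that ``Q[:, perm]`` lists components in
    corner order (min,min), (max,min), (min,max), (max,max).
    """
    from scipy.optimize import linear_sum_assignment

    Q = np.asarray(Q, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if Q.shape[1] != 4:
        raise ValueError("corner assignment requires exactly 4 components")
    centroids = (Q.T @ coords) / Q.sum(axis=0)[:, None]
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    corners = np.array([[lo[0], lo[1]], [hi[0], lo[1]], [lo[0], hi[1]], [hi[0], hi[1]]])
    dist = np.linalg.norm(centroids[:, None, :] - corners[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(dist)
    perm = np.empty(4, dtype=int)
    perm[cols] = rows
    return perm


def map_admixture_2d(Q: np.ndarray) -> np.ndarray:
    """Map 4-component admixture proportions to the unit square as the
    convex combination of the corners (0,0), (1,0), (0,1), (1,1)."""
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[1] != 4:
        raise ValueError("map_admixture_2d requires an n x 4 proportion matrix")
    if np.any(Q < -1e-10) or np.any(np.abs(Q.sum(axis=1) - 1.0) > 1e-8):
        raise ValueError("rows of Q must lie on the simplex")
    return Q @ UNIT_SQUARE_CORNERS
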