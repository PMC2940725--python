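"""Sparse factor analysis of genotype matrices with an ARD prior.

The model decomposes an n x p genotype matrix X as

    X = 1 mu' + Lambda F + E

with K latent factors.  Row i of the loading matrix Lambda has an
automatic relevance determination (ARD) prior, lambda_i ~ N(0, Sigma_i)
with Sigma_i = diag(sigma2_i1..sigma2_iK); the sigma2 are estimated by
type-II maximum likelihood, and an estimate of exactly zero removes the
loading, inducing sparsity.  Residuals are Gaussian with either
individual-specific (row) or SNP-specific (column) variances psi, and a
gamma prior on the inverse residual variance acts as a regularizer.  The
variant with the column-mean term mu is called SFAm; SFA fixes mu = 0.

Fitting is by an expectation conditional maximization either (ECME)
algorithm: mu, F and psi maximize the expected complete-data log
likelihood given posterior loading moments, while Sigma directly
maximizes the marginal likelihood (the fast type-II update of sparse
Bayesian regression).  Loading moments are not refreshed between the CM
steps, so monotone convergence is not guaranteed (decreases are logged);
in practice the objective converges well.  After each iteration every
factor is rescaled to unit sample variance (the scale of a factor and
its loadings is otherwise non-identifiable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from popfactor.io import GenotypeMatrix

log = logging.getLogger("popfactor")

_JITTER = 1e-10  # ridge added to singular K x K systems


class SfaNumericalError(RuntimeError):
    """A linear-algebra step failed (singular or non-PD working matrix)."""


class SfaFitError(RuntimeError):
    """All restarts failed; carries the log-likelihood traces."""

    def __init__(self, msg: str, traces: list[list[float]]):
        super().__init__(msg)
        self.traces = traces


@dataclass
class SfaConfig:
    """Settings for an SFA/SFAm fit.

    K is the number of latent factors; ``mean_term`` selects SFAm (the
    model with an explicit column-mean factor) over SFA.  ``variance_mode``
    chooses individual-specific ("row") or SNP-specific ("column")
    residual variances.  ``prior_shape``/``prior_rate`` are the gamma
    hyperparameters (a, b) on the inverse residual variance; the default
    a = b = 1 puts prior mean 1 on the precision of roughly unit-scale
    genotype residuals.  ``psi_floor`` guards against the residual-variance
    degeneracy seen on low-frequency SNPs.
    """

    K: int
    mean_term: bool = True
    variance_mode: str = "row"
    prior_shape: float = 1.0
    prior_rate: float = 1.0
    max_iter: int = 200
    rel_tol: float = 1e-5
    n_restarts: int = 1
    seed: int = 0
    psi_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.variance_mode not in ("row", "column"):
            raise ValueError("variance_mode must be 'row' or 'column'")
        if self.prior_shape <= 0 or self.prior_rate < 0:
            raise ValueError("gamma prior hyperparameters must be positive")
        if self.psi_floor <= 0:
            raise ValueError("psi_floor must be positive")
        if self.max_iter < 1 or self.rel_tol <= 0 or self.n_restarts < 1:
            raise ValueError("invalid iteration settings")


@dataclass
class SfaModel:
    """State of the SFA/SFAm model evolved by the ECME algorithm."""

    F: np.ndarray          # K x p factors (rows rescaled to unit variance)
    mu: np.ndarray         # p column means (zeros when mean_term is off)
    psi: np.ndarray        # n (row mode) or p (column mode) residual variances
    Sigma: np.ndarray      # n x K ARD prior variances, exact zeros allowed
    mean_term: bool = True
    variance_mode: str = "row"
    prior_shape: float = 1.0
    prior_rate: float = 1.0
    psi_floor: float = 1e-6
    Omega: np.ndarray | None = None    # n x K posterior mean loadings
    Vpost: np.ndarray | None = None    # n x K x K posterior covariances
    loglik_trace: list[float] = field(default_factory=list)
    _rng: np.random.Generator = field(
        default_factory=np.random.default_rng, repr=False
    )

    @property
    def K(self) -> int:
        return self.F.shape[0]

    def copy(self) -> "SfaModel":
        return SfaModel(
            F=self.F.copy(), mu=self.mu.copy(), psi=self.psi.copy(),
            Sigma=self.Sigma.copy(), mean_term=self.mean_term,
            variance_mode=self.variance_mode, prior_shape=self.prior_shape,
            prior_rate=self.prior_rate, psi_floor=self.psi_floor,
            Omega=None if self.Omega is None else self.Omega.copy(),
            Vpost=None if self.Vpost is None else self.Vpost.copy(),
            loglik_trace=list(self.loglik_trace), _rng=self._rng,
        )


def _values(X) -> np.ndarray:
    if isinstance(X, GenotypeMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _row_sd(F: np.ndarray) -> np.ndarray:
    return F.std(axis=1, ddof=1)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_model(X, cfg: SfaConfig, seed: int | None = None) -> SfaModel:
    """Random starting point: standard-normal F rescaled to unit row
    variance, empirical mu and psi, all-ones Sigma.  Deterministic given
    the seed."""
    Xv = _values(X)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("genotype matrix contains non-finite entries")
    n, p = Xv.shape
    if cfg.K >= min(n, p):
        raise ValueError(f"K={cfg.K} must be < min(n, p) = {min(n, p)}")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    F = rng.standard_normal((cfg.K, p))
    F /= _row_sd(F)[:, None]

    mu = Xv.mean(axis=0) if cfg.mean_term else np.zeros(p)
    centered = Xv - mu
    if cfg.variance_mode == "row":
        psi = centered.var(axis=1, ddof=1)
    else:
        psi = centered.var(axis=0, ddof=1)
    psi = np.maximum(psi, cfg.psi_floor)

    return SfaModel(
        F=F, mu=mu, psi=psi, Sigma=np.ones((n, cfg.K)),
        mean_term=cfg.mean_term, variance_mode=cfg.variance_mode,
        prior_shape=cfg.prior_shape, prior_rate=cfg.prior_rate,
        psi_floor=cfg.psi_floor, _rng=rng,
    )


# ---------------------------------------------------------------------------
# working-space quantities shared by the E-step, the likelihood and the
# ARD update.  All are K-dimensional; the p x p marginal covariance
# C_i = Psi_i + F' Sigma_i F is never formed.
# ---------------------------------------------------------------------------

def _working_quantities(Xv, model):
    """Return (A, U, G, M) where, per individual i,

    A_i = F Psi_i^-1 F'   (K x K),
    U_i = F Psi_i^-1 (x_i - mu)   (K),
    G_i = sqrt(Sigma_i)  elementwise,
    M_i = I + G_i A_i G_i.

    With sigma2 = 0 handled exactly: those coordinates of G are zero, so
    M stays well conditioned and the Woodbury forms below clamp the
    corresponding loadings to zero.
    """
    F, mu, psi = model.F, model.mu, model.psi
    R = Xv - mu
    if model.variance_mode == "row":
        A0 = F @ F.T
        inv_psi = 1.0 / psi                       # (n,)
        A = A0[None, :, :] * inv_psi[:, None, None]
        U = (R @ F.T) * inv_psi[:, None]
    else:
        W = F / psi[None, :]
        A = np.broadcast_to((W @ F.T)[None, :, :], (Xv.shape[0],) + (F.shape[0],) * 2)
        U = R @ W.T
    G = np.sqrt(model.Sigma)                      # (n, K)
    K = F.shape[0]
    M = np.eye(K)[None, :, :] + G[:, :, None] * A * G[:, None, :]
    return A, U, G, M


def _chol_batch(M, context="working matrix"):
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        for i in range(M.shape[0]):
            try:
                np.linalg.cholesky(M[i])
            except np.linalg.LinAlgError:
                raise SfaNumericalError(
                    f"non-positive-definite {context} for individual {i}"
                ) from None
        raise SfaNumericalError(f"non-positive-definite {context}") from None


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------

def estep_moments(X, model: SfaModel) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and covariance of each individual's loadings.

    For individual i the posterior over lambda_i given x_i is Gaussian
    with covariance V_i = (Sigma_i^- + F Psi_i^-1 F')^-1 (generalized
    inverse: coordinates with sigma2 = 0 are clamped to zero mean and
    zero variance) and mean omega_i = V_i F Psi_i^-1 (x_i - mu).
    Returns (Omega: n x K, Vpost: n x K x K).
    """
    Xv = _values(X)
    if not np.all(np.isfinite(model.psi)) or np.any(model.psi < model.psi_floor * 0.999):
        raise ValueError("psi must be finite and >= psi_floor")
    _, U, G, M = _working_quantities(Xv, model)
    _chol_batch(M, "posterior working matrix")
    # V_i = G_i M_i^-1 G_i,  omega_i = G_i M_i^-1 G_i U_i
    Minv = np.linalg.inv(M)
    V = G[:, :, None] * Minv * G[:, None, :]
    Omega = np.einsum("ikl,il->ik", V, U)
    return Omega, V


def second_moments(Omega: np.ndarray, Vpost: np.ndarray) -> np.ndarray:
    """E[lambda_i' lambda_i] = V_i + omega_i omega_i' per individual."""
    return Vpost + np.einsum("ik,il->ikl", Omega, Omega)


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

def log_marginal_likelihood(X, model: SfaModel) -> float:
    """Log marginal likelihood sum_i log N(x_i; mu, F'Sigma_i F + Psi_i),
    plus the log gamma prior on the inverse residual variances (so the
    trace is the objective the ECME algorithm maximizes).  Evaluated via
    the matrix inversion and determinant lemmas in K-dimensional space.
    """
    Xv = _values(X)
    n, p = Xv.shape
    R = Xv - model.mu
    _, U, G, M = _working_quantities(Xv, model)
    L = _chol_batch(M, "marginal covariance working matrix")
    logdet_M = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
    if model.variance_mode == "row":
        logdet_Psi = p * np.log(model.psi)
        quad_full = (R * R).sum(axis=1) / model.psi
    else:
        logdet_Psi = np.full(n, np.log(model.psi).sum())
        quad_full = ((R * R) / model.psi[None, :]).sum(axis=1)
    GU = G * U
    y = np.linalg.solve(M, GU[:, :, None])[:, :, 0]
    quad = quad_full - np.einsum("ik,ik->i", GU, y)
    ll = -0.5 * np.sum(p * np.log(2.0 * np.pi) + logdet_Psi + logdet_M + quad)

    a, b = model.prior_shape, model.prior_rate
    eta = 1.0 / model.psi  # inverse residual variances
    ll += np.sum(a * np.log(b) - gammaln(a) + (a - 1.0) * np.log(eta) - b * eta)
    return float(ll)


# ---------------------------------------------------------------------------
# CM steps (expected complete-data log likelihood maximizers).
# Moments are those from the E-step at the top of the iteration; they are
# deliberately not refreshed between steps.
# ---------------------------------------------------------------------------

def cm_update_mu(X, model: SfaModel, moments) -> np.ndarray:
    """Precision-weighted residual mean per SNP (unweighted in column
    mode, where the weights are shared within a column).  Returns zeros
    when the mean term is off."""
    Xv = _values(X)
    if not model.mean_term:
        return np.zeros(Xv.shape[1])
    Omega, _ = moments
    resid = Xv - Omega @ model.F
    if model.variance_mode == "row":
        w = 1.0 / model.psi
        return (w @ resid) / w.sum()
    return resid.mean(axis=0)


def _solve_ridge(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    try:
        out = np.linalg.solve(A, B)
        if np.all(np.isfinite(out)):
            return out
    except np.linalg.LinAlgError:
        pass
    log.warning("singular K x K system in factor update; applying ridge jitter")
    return np.linalg.solve(A + _JITTER * np.eye(A.shape[0]), B)


def cm_update_F(X, model: SfaModel, moments) -> np.ndarray:
    """Per-SNP generalized least squares on the posterior loading moments:
    f_j = [sum_i E_i / psi_ij]^-1 sum_i omega_i' (x_ij - mu_j) / psi_ij.
    In row mode the K x K system is shared by all SNPs; in column mode the
    common psi_j cancels."""
    Xv = _values(X)
    Omega, Vpost = moments
    E = second_moments(Omega, Vpost)
    R = Xv - model.mu
    if model.variance_mode == "row":
        w = 1.0 / model.psi
        A = np.einsum("i,ikl->kl", w, E)
        B = (Omega * w[:, None]).T @ R
    else:
        A = E.sum(axis=0)
        B = Omega.T @ R
    return _solve_ridge(A, B)


def cm_update_psi(X, model: SfaModel, moments) -> np.ndarray:
    """Residual-variance update including the gamma prior:
    psi_i = (2b + S_i) / (p + 2(a-1)) in row mode (column mode sums over
    individuals with denominator n + 2(a-1)), floored at psi_floor, where
    S collects the expected squared residuals under the loading posterior.
    """
    Xv = _values(X)
    n, p = Xv.shape
    a, b = model.prior_shape, model.prior_rate
    Omega, Vpost = moments
    E = second_moments(Omega, Vpost)
    R = Xv - model.mu
    fit = Omega @ model.F
    # f_j' E_i f_j for all i, j
    quad = np.einsum("ikl,kj,lj->ij", E, model.F, model.F, optimize=True)
    S = R * R - 2.0 * R * fit + quad
    if model.variance_mode == "row":
        denom = p + 2.0 * (a - 1.0)
        if denom <= 0:
            raise ValueError("psi update denominator p + 2(a-1) <= 0; adjust prior")
        psi = (2.0 * b + S.sum(axis=1)) / denom
    else:
        denom = n + 2.0 * (a - 1.0)
        if denom <= 0:
            raise ValueError("psi update denominator n + 2(a-1) <= 0; adjust prior")
        psi = (2.0 * b + S.sum(axis=0)) / denom
    return np.maximum(psi, model.psi_floor)


# ---------------------------------------------------------------------------
# ARD update (marginal-likelihood maximizer)
# ---------------------------------------------------------------------------

def update_sigma_ard(X, model: SfaModel) -> np.ndarray:
    """Type-II maximum-likelihood update of the ARD variances.

    For each (individual, factor) pair, compute the sparsity and quality
    statistics S_ik = f_k C_i^-1 f_k' and Q_ik = f_k C_i^-1 (x_i - mu)'
    with C_i the current marginal covariance, de-inflate them to the
    leave-k-out values s = S/(1 - sigma2 S), q = Q/(1 - sigma2 S), and set
    sigma2 = (q^2 - s)/s^2 when q^2 > s, else exactly 0.  All pairs are
    updated in one sweep from start-of-sweep covariances.
    """
    Xv = _values(X)
    A, U, G, M = _working_quantities(Xv, model)
    _chol_batch(M, "ARD working matrix")
    Minv = np.linalg.inv(M)
    # F C^-1 F' = A - A G M^-1 G A ;  F C^-1 r = U - A G M^-1 G U
    AG = A * G[:, None, :]
    core = np.einsum("ikl,ilm->ikm", AG @ Minv, np.swapaxes(AG, 1, 2))
    S = np.einsum("ikk->ik", A - core)
    Q = U - np.einsum("ikl,il->ik", AG @ Minv, G * U)

    denom = 1.0 - model.Sigma * S
    near_zero = np.abs(denom) < 1e-12
    safe = np.where(near_zero, 1.0, denom)
    s = np.where(near_zero, S, S / safe)
    q = np.where(near_zero, Q, Q / safe)

    new = np.zeros_like(model.Sigma)
    pos = (q * q > s) & (s > 0)
    new[pos] = (q[pos] ** 2 - s[pos]) / s[pos] ** 2
    return new


# ---------------------------------------------------------------------------
# identifiability rescaling
# ---------------------------------------------------------------------------

def rescale_factors(model: SfaModel) -> SfaModel:
    """Divide each factor row by its sample standard deviation and scale
    the corresponding loading representation to compensate (Omega column
    by s_k, Sigma column by s_k^2).  The reconstruction and the marginal
    likelihood are unchanged.  A zero-variance factor row is re-drawn
    from the model's RNG with a warning."""
    out = model.copy()
    sd = _row_sd(out.F)
    for k in np.where(sd == 0)[0]:
        log.warning("factor %d has zero variance; re-drawing from RNG", k)
        out.F[k] = out._rng.standard_normal(out.F.shape[1])
        sd[k] = _row_sd(out.F[k : k + 1])[0]
    out.F /= sd[:, None]
    out.Sigma *= sd[None, :] ** 2
    if out.Omega is not None:
        out.Omega *= sd[None, :]
    if out.Vpost is not None:
        out.Vpost *= sd[None, :, None] * sd[None, None, :]
    return out


# ---------------------------------------------------------------------------
# full ECME fit
# ---------------------------------------------------------------------------

def _fit_once(Xv: np.ndarray, cfg: SfaConfig, seed: int) -> SfaModel:
    model = init_model(Xv, cfg, seed=seed)
    ll = log_marginal_likelihood(Xv, model)
    model.loglik_trace = [ll]
    for it in range(cfg.max_iter):
        moments = estep_moments(Xv, model)
        model.mu = cm_update_mu(Xv, model, moments)
        model.F = cm_update_F(Xv, model, moments)
        model.psi = cm_update_psi(Xv, model, moments)
        model.Sigma = update_sigma_ard(Xv, model)
        model.Omega, model.Vpost = moments
        model = rescale_factors(model)
        ll_new = log_marginal_likelihood(Xv, model)
        model.loglik_trace.append(ll_new)
        if ll_new < ll - 1e-8:
            log.debug("iteration %d: objective decreased by %.3g", it, ll - ll_new)
        if it % 10 == 0:
            log.info("iteration %d: log marginal likelihood %.6f", it, ll_new)
        if abs(ll_new - ll) / (abs(ll) + 1e-12) < cfg.rel_tol:
            ll = ll_new
            break
        ll = ll_new
    # final moments under the converged parameters
    model.Omega, model.Vpost = estep_moments(Xv, model)
    # deterministic sign convention: factor rows (scaled allele-frequency
    # combinations) point "up" — row mean positive, loadings compensated
    flip = model.F.mean(axis=1) < 0
    model.F[flip] *= -1.0
    model.Omega[:, flip] *= -1.0
    return model


def fit_sfa(X, cfg: SfaConfig) -> SfaModel:
    """Fit SFA/SFAm by ECME; with n_restarts > 1, run from distinct seeds
    and keep the model with the highest final log marginal likelihood."""
    Xv = _values(X)
    best: SfaModel | None = None
    traces: list[list[float]] = []
    for r in range(cfg.n_restarts):
        seed = int((cfg.seed + r) % (2**31))
        try:
            model = _fit_once(Xv, cfg, seed)
        except (SfaNumericalError, np.linalg.LinAlgError) as exc:
            log.warning("restart %d failed numerically: %s", r, exc)
            traces.append([])
            continue
        traces.append(model.loglik_trace)
        if best is None or model.loglik_trace[-1] > best.loglik_trace[-1]:
            best = model
    if best is None:
        raise SfaFitError("all restarts failed numerically", traces)
    return best


def normalized_loadings(Omega: np.ndarray) -> np.ndarray:
    """Each individual's |loading| shares across factors (rows sum to 1;
    zero rows are left at zero)."""
    mag = np.abs(Omega)
    tot = mag.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return mag / tot
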