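"""Synthetic population-genetic scenarios with known ground truth.

Generates genotype matrices for the study designs the factorization
methods are contrasted on:

* ``discrete`` — well-separated populations under the Balding–Nichols
  model (ancestral frequency p, per-population frequencies
  Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst)).
* ``admixed`` — individuals draw alleles from a convex mixture of
  Balding–Nichols population frequencies with user-supplied proportions.
* ``line_1d`` / ``grid_2d`` / ``clustered_1d`` — stepping-stone isolation
  by distance.  Instead of a coalescent simulation, each SNP's deme
  frequencies are an allele-frequency random field on the logit scale:
  a random walk along the line (1-D) or a Gaussian field with
  exponentially decaying covariance in grid Manhattan distance (2-D),
  calibrated so adjacent demes differ by logit-scale increments of
  standard deviation tau.  This reproduces the spatial covariance
  structure that defines the scenarios while keeping SNPs independent.
* ``two_grids`` — two independent 2-D habitats sharing ancestral
  frequencies, each with an extra habitat-level logit shift of standard
  deviation delta that creates discrete between-habitat divergence.

All generators are deterministic given their seed.  Monomorphic SNPs
are resampled so every column is usable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from popfactor.io import GenotypeMatrix


@dataclass
class SimConfig:
    """Scenario settings.  ``fst`` applies to the discrete/admixed
    Balding–Nichols scenarios; ``tau`` is the logit-scale drift between
    adjacent demes in the stepping-stone scenarios; ``delta`` the
    habitat-level logit shift of the two-habitat design.  Ancestral minor
    allele frequencies are uniform on ``ancestral_maf_range`` (mirrored
    to the upper half at random) so SNPs stay polymorphic."""

    scenario: str = "discrete"
    n_per_deme: int = 1
    n_snps: int = 1000
    n_pops: int = 3
    n_demes: int = 50
    grid_side: int = 10
    sampled_demes: int = 5
    fst: float = 0.1
    tau: float = 0.15
    delta: float = 0.5
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError("fst must be in (0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if min(self.n_per_deme, self.n_snps, self.n_pops, self.n_demes,
               self.grid_side, self.sampled_demes) < 1:
            raise ValueError("all sizes must be >= 1")
        lo, hi = self.ancestral_maf_range
        if not 0 < lo < hi <= 0.5:
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")


@dataclass
class SimTruth:
    """A simulated genotype matrix plus its generating quantities."""

    genotypes: GenotypeMatrix
    deme_coords: np.ndarray | None = None     # per-individual 1-D or 2-D coords
    true_Q: np.ndarray | None = None          # n x K admixture proportions
    true_freqs: np.ndarray | None = None      # per-population/deme x p frequencies
    habitat_labels: np.ndarray | None = None  # two_grids only
    deme_index: np.ndarray | None = None      # per-individual row of true_freqs


def _ancestral_freqs(rng: np.random.Generator, n_snps: int, maf_range) -> np.ndarray:
    lo, hi = maf_range
    p = rng.uniform(lo, hi, size=n_snps)
    flip = rng.random(n_snps) < 0.5
    return np.where(flip, 1.0 - p, p)


def _balding_nichols(rng, ancestral: np.ndarray, fst: float, n_pops: int) -> np.ndarray:
    c = (1.0 - fst) / fst
    a = ancestral * c
    b = (1.0 - ancestral) * c
    freqs = rng.beta(a[None, :], b[None, :], size=(n_pops, len(ancestral)))
    return np.clip(freqs, 1e-12, 1.0 - 1e-12)


def _genotypes_from_probs(rng, probs: np.ndarray) -> np.ndarray:
    return rng.binomial(2, probs).astype(float)


def _resample_monomorphic(rng, make_columns, genotypes, max_rounds=50):
    """Redraw SNP columns whose sample is monomorphic.  ``make_columns``
    regenerates full columns (genotypes and truth) for given indices."""
    for _ in range(max_rounds):
        mono = np.where(np.ptp(genotypes, axis=0) == 0)[0]
        if mono.size == 0:
            return
        make_columns(mono)


def sim_discrete(cfg: SimConfig) -> SimTruth:
    """Discrete populations under the Balding–Nichols model; ``n_per_deme``
    individuals per population; true_Q is one-hot."""
    if cfg.n_pops < 2:
        raise ValueError("discrete scenario requires n_pops >= 2")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pops * cfg.n_per_deme
    pop = np.repeat(np.arange(cfg.n_pops), cfg.n_per_deme)

    ancestral = _ancestral_freqs(rng, cfg.n_snps, cfg.ancestral_maf_range)
    freqs = _balding_nichols(rng, ancestral, cfg.fst, cfg.n_pops)
    geno = _genotypes_from_probs(rng, freqs[pop])

    def redo(cols):
        anc = _ancestral_freqs(rng, len(cols), cfg.ancestral_maf_range)
        f = _balding_nichols(rng, anc, cfg.fst, cfg.n_pops)
        freqs[:, cols] = f
        geno[:, cols] = _genotypes_from_probs(rng, f[:, :][pop])

    _resample_monomorphic(rng, redo, geno)

    Q = np.zeros((n, cfg.n_pops))
    Q[np.arange(n), pop] = 1.0
    ids = [f"pop{k}_ind{i}" for k, i in zip(pop, range(n))]
    return SimTruth(
        genotypes=GenotypeMatrix(geno, ids, [f"snp{j}" for j in range(cfg.n_snps)]),
        true_Q=Q,
        true_freqs=freqs,
        deme_index=pop,
    )


def sim_admixed(cfg: SimConfig, Q_spec: np.ndarray) -> SimTruth:
    """Admixed individuals: each row of ``Q_spec`` (on the simplex) mixes
    the Balding–Nichols population frequencies; genotypes are
    Binomial(2, sum_k q_ik p_kj)."""
    Q_spec = np.asarray(Q_spec, dtype=float)
    if Q_spec.ndim != 2 or np.any(Q_spec < -1e-12) or np.any(
        np.abs(Q_spec.sum(axis=1) - 1.0) > 1e-8
    ):
        raise ValueError("Q_spec rows must lie on the simplex")
    rng = np.random.default_rng(cfg.seed)
    n_pops = Q_spec.shape[1]
    ancestral = _ancestral_freqs(rng, cfg.n_snps, cfg.ancestral_maf_range)
    freqs = _balding_nichols(rng, ancestral, cfg.fst, n_pops)
    probs = Q_spec @ freqs
    geno = _genotypes_from_probs(rng, probs)

    def redo(cols):
        anc = _ancestral_freqs(rng, len(cols), cfg.ancestral_maf_range)
        f = _balding_nichols(rng, anc, cfg.fst, n_pops)
        freqs[:, cols] = f
        geno[:, cols] = _genotypes_from_probs(rng, Q_spec @ f)

    _resample_monomorphic(rng, redo, geno)
    n = Q_spec.shape[0]
    return SimTruth(
        genotypes=GenotypeMatrix(
            geno, [f"ind{i}" for i in range(n)], [f"snp{j}" for j in range(cfg.n_snps)]
        ),
        true_Q=Q_spec,
        true_freqs=freqs,
    )


def gradient_Q(n: int, K: int = 2) -> np.ndarray:
    """An n-row admixture gradient from (1,0,...) to (...,0,1) for the
    two-ancestral-population recovery experiments (K=2 gives a linear
    cline in the first component)."""
    t = np.linspace(0.0, 1.0, n)
    if K == 2:
        return np.column_stack([1.0 - t, t])
    Q = np.zeros((n, K))
    seg = t * (K - 1)
    lo = np.minimum(seg.astype(int), K - 2)
    frac = seg - lo
    Q[np.arange(n), lo] = 1.0 - frac
    Q[np.arange(n), lo + 1] = frac
    return Q


def _field_1d(rng, n_demes: int, n_snps: int, tau: float) -> np.ndarray:
    """Per-SNP logit-scale random walk along a line of demes; increments
    between adjacent demes are N(0, tau^2).  Centered so the ancestral
    frequency stays representative of the habitat."""
    steps = rng.normal(0.0, tau, size=(n_demes - 1, n_snps))
    z = np.vstack([np.zeros((1, n_snps)), np.cumsum(steps, axis=0)])
    return z - z.mean(axis=0, keepdims=True)


def _grid_cov_cholesky(grid_side: int, tau: float) -> np.ndarray:
    """Cholesky factor of the unit-variance 2-D field covariance
    exp(-d1/l) over the grid (d1 = Manhattan distance in deme units),
    with the correlation length l solved so adjacent demes differ by
    logit increments of sd tau: 2(1 - exp(-1/l)) = tau^2."""
    if tau**2 >= 2.0:
        raise ValueError("tau too large for a unit-variance spatial field")
    coords = np.array(
        [(i, j) for i in range(grid_side) for j in range(grid_side)], dtype=float
    )
    d1 = np.abs(coords[:, None, :] - coords[None, :, :]).sum(axis=2)
    ell = -1.0 / np.log(1.0 - tau**2 / 2.0)
    cov = np.exp(-d1 / ell)
    return np.linalg.cholesky(cov + 1e-10 * np.eye(len(coords))), coords


def _field_2d(rng, grid_side: int, n_snps: int, tau: float) -> tuple[np.ndarray, np.ndarray]:
    L, coords = _grid_cov_cholesky(grid_side, tau)
    z = L @ rng.standard_normal((len(coords), n_snps))
    return z - z.mean(axis=0, keepdims=True), coords


def sim_stepping_stone(cfg: SimConfig) -> SimTruth:
    """1-D line, 2-D grid, or clustered sampling from a 1-D line.

    Deme allele frequencies are inverse-logit(logit(ancestral) + z) with
    z the spatial field.  ``line_1d``/``grid_2d`` sample one diploid
    individual per deme; ``clustered_1d`` samples ``n_per_deme``
    individuals from ``sampled_demes`` evenly spaced demes of the line.
    """
    if cfg.scenario not in ("line_1d", "grid_2d", "clustered_1d"):
        raise ValueError(f"not a stepping-stone scenario: {cfg.scenario!r}")
    rng = np.random.default_rng(cfg.seed)
    ancestral = _ancestral_freqs(rng, cfg.n_snps, cfg.ancestral_maf_range)

    if cfg.scenario == "grid_2d":
        z, coords = _field_2d(rng, cfg.grid_side, cfg.n_snps, cfg.tau)
    else:
        z = _field_1d(rng, cfg.n_demes, cfg.n_snps, cfg.tau)
        coords = np.arange(cfg.n_demes, dtype=float)[:, None]
    deme_freqs = np.clip(expit(logit(ancestral)[None, :] + z), 1e-12, 1 - 1e-12)

    if cfg.scenario == "clustered_1d":
        sampled = np.linspace(0, cfg.n_demes - 1, cfg.sampled_demes).round().astype(int)
        deme_of_ind = np.repeat(sampled, cfg.n_per_deme)
    else:
        deme_of_ind = np.repeat(np.arange(len(coords)), cfg.n_per_deme)

    geno = _genotypes_from_probs(rng, deme_freqs[deme_of_ind])

    def redo(cols):
        anc = _ancestral_freqs(rng, len(cols), cfg.ancestral_maf_range)
        if cfg.scenario == "grid_2d":
            znew, _ = _field_2d(rng, cfg.grid_side, len(cols), cfg.tau)
        else:
            znew = _field_1d(rng, cfg.n_demes, len(cols), cfg.tau)
        f = np.clip(expit(logit(anc)[None, :] + znew), 1e-12, 1 - 1e-12)
        deme_freqs[:, cols] = f
        geno[:, cols] = _genotypes_from_probs(rng, f[deme_of_ind])

    _resample_monomorphic(rng, redo, geno)

    n = len(deme_of_ind)
    ids = [f"deme{d}_ind{i}" for i, d in enumerate(deme_of_ind)]
    return SimTruth(
        genotypes=GenotypeMatrix(geno, ids, [f"snp{j}" for j in range(cfg.n_snps)]),
        deme_coords=coords[deme_of_ind],
        true_freqs=deme_freqs,
        deme_index=deme_of_ind,
    )


def sim_two_grids(cfg: SimConfig) -> SimTruth:
    """Two independent 2-D habitats with shared ancestral frequencies.

    Each habitat has its own spatial field plus an independent
    habitat-level logit shift of sd ``delta``, creating discrete
    between-habitat divergence on top of the within-habitat continuum.
    """
    if cfg.delta <= 0:
        raise ValueError("delta must be positive for the two-habitat scenario")
    rng = np.random.default_rng(cfg.seed)
    ancestral = _ancestral_freqs(rng, cfg.n_snps, cfg.ancestral_maf_range)

    def habitat_fields(n_cols):
        za, coords = _field_2d(rng, cfg.grid_side, n_cols, cfg.tau)
        zb, _ = _field_2d(rng, cfg.grid_side, n_cols, cfg.tau)
        shift_a = rng.normal(0.0, cfg.delta, size=n_cols)
        shift_b = rng.normal(0.0, cfg.delta, size=n_cols)
        return za + shift_a[None, :], zb + shift_b[None, :], coords

    za, zb, coords = habitat_fields(cfg.n_snps)
    base = logit(ancestral)[None, :]
    deme_freqs = np.clip(
        expit(np.vstack([base + za, base + zb])), 1e-12, 1 - 1e-12
    )
    n_demes = len(coords)
    deme_of_ind = np.repeat(np.arange(2 * n_demes), cfg.n_per_deme)
    geno = _genotypes_from_probs(rng, deme_freqs[deme_of_ind])

    def redo(cols):
        anc = _ancestral_freqs(rng, len(cols), cfg.ancestral_maf_range)
        a2, b2, _ = habitat_fields(len(cols))
        f = np.clip(
            expit(np.vstack([logit(anc)[None, :] + a2, logit(anc)[None, :] + b2])),
            1e-12, 1 - 1e-12,
        )
        deme_freqs[:, cols] = f
        geno[:, cols] = _genotypes_from_probs(rng, f[deme_of_ind])

    _resample_monomorphic(rng, redo, geno)

    habitat = (deme_of_ind >= n_demes).astype(int)
    all_coords = np.vstack([coords, coords])[deme_of_ind]
    ids = [f"hab{h}_deme{d % n_demes}_ind{i}"
           for i, (h, d) in enumerate(zip(habitat, deme_of_ind))]
    return SimTruth(
        genotypes=GenotypeMatrix(geno, ids, [f"snp{j}" for j in range(cfg.n_snps)]),
        deme_coords=all_coords,
        true_freqs=deme_freqs,
        habitat_labels=habitat,
        deme_index=deme_of_ind,
    )


def simulate(cfg: SimConfig, Q_spec: np.ndarray | None = None) -> SimTruth:
    """Dispatch on ``cfg.scenario``."""
    if cfg.scenario == "discrete":
        return sim_discrete(cfg)
    if cfg.scenario == "admixed":
        if Q_spec is None:
            Q_spec = gradient_Q(cfg.n_per_deme * cfg.n_pops, cfg.n_pops)
        return sim_admixed(cfg, Q_spec)
    if cfg.scenario in ("line_1d", "grid_2d", "clustered_1d"):
        return sim_stepping_stone(cfg)
    if cfg.scenario == "two_grids":
        return sim_two_grids(cfg)
    raise ValueError(f"unknown scenario: {cfg.scenario!r}")


# ---------------------------------------------------------------------------
# F_ST estimators used to validate the generators
# ---------------------------------------------------------------------------

def fst_weir_cockerham(geno: np.ndarray, pops: np.ndarray) -> float:
    """Multi-population Weir–Cockerham (1984) theta from diploid genotype
    counts, averaged over SNPs as ratio of sums.  Requires at least two
    diploid individuals per population."""
    geno = np.asarray(geno, dtype=float)
    pops = np.asarray(pops)
    labels = np.unique(pops)
    r = len(labels)
    n_i = np.array([(pops == g).sum() for g in labels], dtype=float)
    if np.any(n_i < 2):
        raise ValueError("Weir-Cockerham needs >= 2 individuals per population")
    p_i = np.stack([geno[pops == g].mean(axis=0) / 2.0 for g in labels])  # (r, p)
    h_i = np.stack([(geno[pops == g] == 1.0).mean(axis=0) for g in labels])

    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i[:, None] * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_i).sum(axis=0) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    denom = (a + b + c).sum()
    if denom == 0:
        return 0.0
    return float(a.sum() / denom)


def fst_hudson_freqs(p1: np.ndarray, p2: np.ndarray) -> float:
    """Hudson-style F_ST between two populations from their (known) allele
    frequencies: 1 - Hw/Hb as ratio of SNP sums.  Appropriate when the
    true frequencies are available (e.g. from a simulator's truth), where
    no sample-size correction is needed."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())
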