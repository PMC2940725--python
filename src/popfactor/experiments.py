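"""Reproducible study scenarios contrasting SFA/SFAm, PCA and admixture.

Each function runs one desk-scale experiment end to end — simulate a
scenario with known truth, fit the methods, measure recovery — and
returns a flat dict of named quantities.  These are the experiments the
acceptance checks and the reproduction script both run; problem sizes
are chosen so every experiment completes in minutes on one CPU.

Fits here run the ECME/EM optimizers to tight relative tolerances
(1e-8 to 1e-9): genotype-scale log likelihoods are O(1e5), so looser
settings stop well short of the sparse optimum.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr, spearmanr

from popfactor.admixture import (
    admix_fit,
    assign_components_to_corners,
    map_admixture_2d,
)
from popfactor.compare import (
    loadings_to_admixture,
    match_factors,
    procrustes_align,
    robustness_experiment,
)
from popfactor.pca import pca_fit
from popfactor.sfa import SfaConfig, fit_sfa, normalized_loadings
from popfactor.simulate import (
    SimConfig,
    gradient_Q,
    sim_admixed,
    sim_discrete,
    sim_stepping_stone,
    sim_two_grids,
)

# saturation: an admixture proportion within this distance of a simplex
# vertex counts as saturated at 0/1
SATURATION_TOL = 0.05


def _abs_r(x, y) -> float:
    return float(abs(pearsonr(x, y).statistic))


def _standardized(M: np.ndarray) -> np.ndarray:
    C = M - M.mean(axis=0)
    return C / C.std(axis=0, ddof=1)


def _procrustes_axis_r(loadings: np.ndarray, coords: np.ndarray) -> float:
    """Mean per-axis Pearson r between Procrustes-aligned standardized
    loadings and standardized habitat coordinates."""
    T = _standardized(coords)
    L = _standardized(loadings)
    _, aligned = procrustes_align(L, T)
    return float(np.mean([_abs_r(aligned[:, d], T[:, d]) for d in range(T.shape[1])]))


def experiment_discrete_recovery(seed: int = 1) -> dict[str, float]:
    """Three Balding-Nichols populations (20 each, 2000 SNPs, F_ST 0.15):
    SFA with K=3 concentrates each individual on one factor whose row
    matches that population's allele frequencies, while PCA spreads every
    individual across its components."""
    truth = sim_discrete(SimConfig(
        scenario="discrete", n_pops=3, n_per_deme=20, n_snps=2000,
        fst=0.15, seed=seed,
    ))
    model = fit_sfa(truth.genotypes, SfaConfig(
        K=3, mean_term=False, seed=seed, max_iter=2000, rel_tol=1e-9,
        n_restarts=3,
    ))
    shares = normalized_loadings(model.Omega)
    match = match_factors(model.F, truth.true_freqs)
    pca = pca_fit(truth.genotypes, 3)
    # unit-norm eigenvector loadings (the usual plotting convention) for
    # the cross-method density comparison
    pca_shares = normalized_loadings(pca.loadings / pca.singular_values)
    return {
        "sfa_mean_dominant_share": float(shares.max(axis=1).mean()),
        "sfa_exact_zero_fraction": float(np.mean(model.Sigma == 0.0)),
        "sfa_min_factor_truth_corr": float(match.correlations.min()),
        "pca_max_dominant_share": float(pca_shares.max(axis=1).max()),
    }


def experiment_sampling_robustness(seed: int = 1) -> dict[str, float]:
    """Drop half of one population and refit: SFA and admixture loadings
    for the retained individuals barely move; PCA's move appreciably."""
    truth = sim_discrete(SimConfig(
        scenario="discrete", n_pops=3, n_per_deme=20, n_snps=2000,
        fst=0.15, seed=seed,
    ))
    res = robustness_experiment(
        truth.genotypes.values, truth.deme_index, drop_group=0,
        drop_fraction=0.5, K=3, seed=seed,
    )
    return {f"{m}_retained_loading_corr": v for m, v in res.items()}


def experiment_line_1d(seed: int = 1) -> dict[str, float]:
    """50-deme stepping-stone line (tau 0.15, 2000 SNPs): SFA K=2
    loadings vary monotonically with position, SFAm's single non-mean
    factor tracks position linearly, and the admixture baseline
    saturates at the simplex vertices near the line's ends."""
    truth = sim_stepping_stone(SimConfig(
        scenario="line_1d", n_demes=50, n_snps=2000, tau=0.15, seed=seed,
    ))
    pos = truth.deme_coords[:, 0]

    sfa = fit_sfa(truth.genotypes, SfaConfig(
        K=2, mean_term=False, seed=seed, max_iter=2000, rel_tol=1e-9,
        n_restarts=2,
    ))
    rho = [abs(spearmanr(sfa.Omega[:, k], pos).statistic) for k in range(2)]

    sfam = fit_sfa(truth.genotypes, SfaConfig(
        K=1, mean_term=True, seed=seed, max_iter=2000, rel_tol=1e-9,
        n_restarts=2,
    ))
    lam = sfam.Omega[:, 0]
    lo, hi = lam.min(), lam.max()
    span = hi - lo
    sfam_sat = float(np.mean(
        (lam <= lo + SATURATION_TOL * span) | (lam >= hi - SATURATION_TOL * span)
    ))

    adm = admix_fit(truth.genotypes, 2, seed=seed, n_restarts=2,
                    max_iter=30000, rel_tol=1e-12)
    adm_sat = float(np.mean(adm.Q.max(axis=1) >= 1.0 - SATURATION_TOL))
    return {
        "sfa_min_abs_spearman_vs_position": float(min(rho)),
        "sfam_abs_pearson_vs_position": _abs_r(lam, pos),
        "admixture_saturated_fraction": adm_sat,
        "sfam_saturated_fraction": sfam_sat,
    }


def experiment_grid_2d(seed: int = 1) -> dict[str, float]:
    """10x10 stepping-stone grid: SFAm (K=2 plus mean) and PCA (the two
    components after the implicit mean factor) both recover the map up
    to rotation; admixture needs four corner components, whose 2-D
    mapping preserves grid adjacency."""
    truth = sim_stepping_stone(SimConfig(
        scenario="grid_2d", grid_side=10, n_snps=2000, tau=0.15, seed=seed,
    ))
    coords = truth.deme_coords

    sfam = fit_sfa(truth.genotypes, SfaConfig(
        K=2, mean_term=True, seed=seed, max_iter=1500, rel_tol=1e-8,
        n_restarts=2,
    ))
    pca = pca_fit(truth.genotypes, 2)
    adm = admix_fit(truth.genotypes, 4, seed=seed, n_restarts=2,
                    max_iter=12000, rel_tol=1e-11)
    perm = assign_components_to_corners(adm.Q, coords)
    xy = map_admixture_2d(adm.Q[:, perm])
    adjacency = float(spearmanr(pdist(xy), pdist(coords)).statistic)
    return {
        "sfam_procrustes_axis_r": _procrustes_axis_r(sfam.Omega, coords),
        "pca_procrustes_axis_r": _procrustes_axis_r(pca.loadings, coords),
        "admixture_distance_rank_corr": adjacency,
    }


def experiment_two_habitats(seed: int = 1) -> dict[str, float]:
    """Two independent 10x10 grids with a discrete habitat-level shift
    (delta 0.5): SFA with K=6 devotes ~3 factors to each habitat, with
    near-zero loadings across habitats, and each habitat's factor pairs
    recover its internal geometry."""
    truth = sim_two_grids(SimConfig(
        scenario="two_grids", grid_side=10, n_snps=2000, tau=0.15,
        delta=0.5, seed=seed,
    ))
    hab = truth.habitat_labels
    sfa = fit_sfa(truth.genotypes, SfaConfig(
        K=6, mean_term=False, seed=seed, max_iter=1500, rel_tol=1e-8,
        n_restarts=2,
    ))
    mean_abs = np.stack([np.abs(sfa.Omega[hab == h]).mean(axis=0) for h in (0, 1)])
    owner = np.argmax(mean_abs, axis=0)
    own = mean_abs[owner, np.arange(6)]
    cross = mean_abs[1 - owner, np.arange(6)]
    factors_per_habitat = np.bincount(owner, minlength=2)

    pair_r = []
    for h in (0, 1):
        ks = np.where(owner == h)[0]
        coords_h = truth.deme_coords[hab == h]
        for a in range(len(ks)):
            for b in range(a + 1, len(ks)):
                L = sfa.Omega[hab == h][:, [ks[a], ks[b]]]
                pair_r.append(_procrustes_axis_r(L, coords_h))
    pair_r = np.sort(pair_r)[::-1]
    return {
        "min_factors_per_habitat": float(factors_per_habitat.min()),
        "cross_to_own_loading_ratio": float(np.mean(cross) / np.mean(own)),
        "second_best_pair_procrustes_r": float(
            pair_r[1] if len(pair_r) > 1 else np.nan
        ),
    }


def experiment_admixture_estimation(seed: int = 1) -> dict[str, float]:
    """Admixture gradient between two ancestral populations (n=100,
    5000 SNPs, F_ST 0.1): SFA loadings normalized to proportions, the
    first PCA loading, and the admixture baseline's Q all track the true
    proportions."""
    Q_true = gradient_Q(100, 2)
    truth = sim_admixed(
        SimConfig(scenario="admixed", n_snps=5000, fst=0.1, seed=seed), Q_true
    )
    sfa = fit_sfa(truth.genotypes, SfaConfig(
        K=2, mean_term=False, seed=seed, max_iter=4000, rel_tol=1e-9,
        n_restarts=2,
    ))
    conv = loadings_to_admixture(sfa.Omega)
    ok = ~np.isnan(conv[:, 0])
    sfa_r = _abs_r(conv[ok, 0], Q_true[ok, 0]) if ok.sum() >= 10 else 0.0

    pca = pca_fit(truth.genotypes, 1)
    adm = admix_fit(truth.genotypes, 2, seed=seed, n_restarts=2,
                    max_iter=5000, rel_tol=1e-9)
    return {
        "sfa_converted_proportion_corr": sfa_r,
        "sfa_defined_fraction": float(ok.mean()),
        "pca_loading1_corr": _abs_r(pca.loadings[:, 0], Q_true[:, 0]),
        "admixture_Q_corr": _abs_r(adm.Q[:, 0], Q_true[:, 0]),
    }


ALL_EXPERIMENTS = {
    "discrete": experiment_discrete_recovery,
    "robustness": experiment_sampling_robustness,
    "line1d": experiment_line_1d,
    "grid2d": experiment_grid_2d,
    "two_habitats": experiment_two_habitats,
    "admixed": experiment_admixture_estimation,
}
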