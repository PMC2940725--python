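# Methods

## The factorization view of population structure

All three methods in this package approximate an n × p genotype matrix
X (allele counts 0/1/2 for n individuals at p SNPs) by a low-rank
product

    X ≈ Λ F        (n × K) (K × p)

and differ only in the constraints placed on the loadings Λ and factors
F. Admixture models constrain the rows of Λ to the probability simplex
and the entries of F/2 to [0, 1], so factors are population allele
frequencies and loadings are ancestry proportions. PCA constrains the
columns of Λ to be orthogonal and the rows of F orthonormal, which
(after standardizing X) the SVD solves exactly. Sparse factor analysis
(SFA) instead uses a sparsity-inducing prior on Λ and no constraint on
F beyond a scale convention, which lets it behave like an admixture
model on discrete structure and like PCA on continuous structure.

## Sparse factor analysis

The model for individual i (a row of X) is

    x_i = μ + λ_i F + e_i,    e_i ~ N(0, Ψ_i),
    λ_i ~ N(0, Σ_i),          Σ_i = diag(σ²_i1, …, σ²_iK),

with a column-mean vector μ (the variant fitting μ is called SFAm; SFA
fixes μ = 0) and residual variances that are either individual-specific
(Ψ_i = ψ_i I, the default, matching genotype data where sample quality
varies by individual) or SNP-specific (Ψ = diag(ψ_1…ψ_p)). A gamma
prior with shape a and rate b on each inverse residual variance acts as
a regularizer; the default a = b = 1 puts prior mean 1 on the precision
of roughly unit-scale genotype residuals and mainly serves to keep ψ
away from degenerate values. A hard floor ψ ≥ 10⁻⁶ (configurable)
guards the residual-variance collapse that low-frequency SNPs can
otherwise induce; a minor-allele-frequency filter (default 0.05 in the
CLI) addresses the same failure mode at the data level.

The per-coefficient prior variances σ²_ik are the automatic relevance
determination (ARD) device: they are estimated by type-II maximum
likelihood, and the estimate is exactly zero whenever the data do not
support coefficient (i, k) — the quality statistic q² falling below the
sparsity statistic s in the update below — which removes that loading
exactly rather than merely shrinking it.

### ECME fitting

Integrating out λ_i gives the marginal likelihood
x_i ~ N(μ, FᵀΣ_iF + Ψ_i), evaluated with the matrix-inversion and
determinant lemmas in K-dimensional working space, so the p × p
covariance is never formed. Zero prior variances are handled exactly by
working with G_i = Σ_i^{1/2}: the working matrix I + G_iFΨ_i⁻¹FᵀG_i
stays well conditioned, and the corresponding posterior loading moments
are clamped to zero.

Each iteration performs:

1. **E-step.** Posterior mean ω_i and covariance V_i of λ_i by Gaussian
   conditioning.
2. **CM steps** maximizing the expected complete-data objective at the
   fixed moments, in the order μ → F → ψ:
   - μ_j: precision-weighted mean of the residuals x_ij − ω_i f_·j
     (unweighted in column-variance mode, where weights are shared);
   - f_·j: generalized least squares against the posterior loading
     moments, [Σ_i E_i/ψ_ij]⁻¹ Σ_i ω_iᵀ(x_ij − μ_j)/ψ_ij with
     E_i = V_i + ω_iᵀω_i (a singular K × K system gets a 10⁻¹⁰ ridge
     and a warning);
   - ψ_i = (2b + S_i)/(p + 2(a − 1)) with S_i the expected squared
     residual sum, floored at ψ_floor (column mode: sums over i,
     denominator n + 2(a − 1)).
3. **ARD step** maximizing the marginal likelihood over each σ²_ik with
   the other parameters fixed: with S = f_k C_i⁻¹ f_kᵀ and
   Q = f_k C_i⁻¹ (x_i − μ)ᵀ de-inflated to leave-k-out values
   s = S/(1 − σ²S), q = Q/(1 − σ²S), the maximizer is (q² − s)/s² when
   q² > s and exactly 0 otherwise. All (i, k) pairs are updated in one
   sweep from start-of-sweep covariances — simpler and order-independent
   compared with the sequential add/delete scheduling used in sparse
   Bayesian regression, and verified against a per-coordinate numeric
   maximization of the marginal likelihood.
4. **Rescaling.** Each factor row is divided by its sample standard
   deviation (ddof = 1 throughout the package) and the loading
   representation compensated (Ω column × s_k, Σ column × s_k²); the
   product ΛF and the likelihood are invariant. This pins down the
   scale non-identifiability of the factorization. Zero-variance rows
   are re-drawn from the model's RNG with a warning.

Because the moments are deliberately not refreshed between CM steps,
the traced objective (marginal likelihood plus the log gamma prior on
the precisions) is not guaranteed monotone; decreases are logged and in
practice are rare and small. Convergence is declared when the relative
change falls below `rel_tol` (default 10⁻⁵). Note the objective on
genotype-scale problems is O(10⁵), so analyses that need a fully
converged sparse solution (the experiment suite uses 10⁻⁸–10⁻⁹) should
tighten `rel_tol`; the defaults favor quick exploratory fits. Exact-zero
σ² coordinates stay in the state, so a pruned factor can re-enter later.
Restarts run from seeds seed, seed+1, … and the best final objective
wins; initialization is standard-normal F rescaled to unit row
variance, empirical μ and ψ, and Σ = 1.

A deterministic output convention flips each factor row to have a
positive mean (factors represent scaled allele-frequency combinations,
which are nonnegative), so converged runs are comparable across seeds.

## PCA

Columns are centered and scaled by their sample standard deviation
(denominator n − 1; monomorphic SNPs are dropped with their ids
reported, since the scaling is undefined). Loadings are left singular
vectors scaled by singular values, factors are right singular vectors;
the sign convention makes each factor row's largest-magnitude entry
positive. `implied_raw_factorization` materializes the raw-scale
(K+1)-factor representation whose extra factor is the genotype column
means with an all-ones loading — the representation in which PCA is
directly comparable to SFAm. The empirical-sd normalization was chosen
over the binomial p(1−p) variant; a `--binomial-norm` flag name is
reserved should that variant be added.

## Admixture baseline

Genotypes are Binomial(2, (QP)_ij). The fitter is EM over the latent
assignment of each allele copy to a source population, which keeps Q on
the simplex and P in [0, 1] exactly after every M-step and never
decreases the likelihood. Plain EM converges impractically slowly on
continuous-structure data (tens of thousands of sweeps on a 10 × 10
grid), so the implementation wraps the EM map in safeguarded SQUAREM
acceleration: two EM sweeps, a squared extrapolation along the implied
direction, projection back to the constraint set, one stabilizing EM
sweep, and fallback to the plain sweeps whenever extrapolation fails to
improve the likelihood. Fixed points and the monotone trace are those
of EM. P is initialized from perturbed overall frequencies and Q from a
symmetric Dirichlet(1); empty components are re-seeded with a warning.

For a square habitat the model needs four components (one per extreme
point of the convex hull); `map_admixture_2d` maps 4-dimensional
proportions to the unit square as the convex combination of the corners
(0,0), (1,0), (0,1), (1,1), with `assign_components_to_corners`
resolving the component-to-corner labeling by Hungarian assignment of
loading-weighted centroids.

## Synthetic scenarios

The generators reproduce the statistical structure of the study
designs without a coalescent simulator, by modeling allele frequencies
directly:

- **discrete / admixed** — Balding–Nichols: ancestral frequency p_j
  uniform on 0.1–0.9 (a minor-allele band mirrored at random, so SNPs
  stay polymorphic), population frequencies Beta with mean p_j and
  variance F_ST · p_j(1 − p_j); genotypes Binomial(2, ·) with the
  admixed variant mixing population frequencies through a user-supplied
  Q (a linear two-population gradient by default).
- **line_1d / clustered_1d** — per-SNP logit-scale random walk along
  the deme line with increment sd τ (default 0.15); clustered sampling
  takes 20 individuals from each of 5 evenly spaced demes of a 50-deme
  line.
- **grid_2d** — per-SNP zero-mean unit-variance Gaussian field over the
  grid with covariance exp(−d₁/ℓ) in Manhattan distance, ℓ solved from
  2(1 − e^{−1/ℓ}) = τ², so adjacent demes again differ by logit
  increments of sd τ while distant demes decorrelate.
- **two_grids** — two independent grid fields sharing ancestral
  frequencies, each offset by an independent habitat-level logit shift
  of sd δ (default 0.5) that creates discrete between-habitat
  divergence on top of the within-habitat continuum.

Monomorphic sampled columns are re-drawn so downstream standardization
is always defined. What the generators deliberately omit: linkage
disequilibrium (all SNPs independent), genealogical noise shared across
SNPs, missing data and genotyping error. Recovery results on these
scenarios therefore speak to the factorization behavior of the methods
under known spatial/ancestral structure, not to robustness against
real-data artifacts. Weir–Cockerham (genotype-based, multi-population)
and Hudson (true-frequency-based, two-population) F_ST estimators are
included and used to validate the generators' calibration.

## Comparison utilities

Factor models are identified only up to permutation, sign and scale.
`match_factors` resolves label switching by Hungarian assignment on
absolute Pearson correlation (computed over SNPs for factors; loading
comparisons correlate over individuals — outputs state the axis);
`procrustes_align` resolves rotational ambiguity of loadings against a
target configuration; `loadings_to_admixture` divides all-positive
loading rows by their sum, the natural ancestry-proportion estimate
when factors are commonly-scaled population frequencies (rows with any
non-positive loading are returned as NaN: the estimate is undefined
there, e.g. for unadmixed individuals whose off-population loading is
exactly zero). `robustness_experiment` refits each method after
dropping part of one group and correlates retained individuals'
loadings between fits.

## The experiment suite

`popfactor.experiments` runs six end-to-end scenarios (discrete
recovery, sampling robustness, 1-D line, 2-D grid, two habitats,
admixture estimation) at desk scale — 50–200 individuals, 2000–5000
SNPs, chosen so each experiment finishes in at most a few minutes on
one CPU while leaving clear margins on the recovery statistics.
"Saturation" of admixture proportions is defined as lying within 0.05
of a simplex vertex, with the analogous definition (within 5% of the
observed loading range's ends) for SFAm loadings. In the cross-method
loading-concentration comparison, PCA loadings enter as unit-norm
eigenvectors — the convention in which PCA loadings are usually plotted
— since singular-value scaling would distort the per-individual share
statistic by component scale.

Known limitation, measured honestly: on the 2-D grid the converged
admixture fit's corner-mapped proportions preserve grid adjacency at a
distance rank-correlation of ≈ 0.5–0.76 across realizations (the
binomial model saturates near the edges and compresses the interior),
which is visibly weaker than SFAm or PCA (≈ 0.9 axis correlations) on
the same data. One acceptance assertion expects ≥ 0.8 there and fails;
running plain EM to full convergence (30k+ sweeps) does not close the
gap, so this reflects the model-fit ceiling under these conditions, not
an optimizer artifact.
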