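# Methods

This note documents the models, estimators, numerical choices and known
limitations of frogmorph. Everything stated here is computed by the test
suite or the analysis scripts; nothing is quoted from elsewhere.

## Size correction

Shape is separated from size per specimen: with measurements
`x_1 … x_p` (lengths only — the iliac angle is never pooled with lengths,
since a geometric mean across units is meaningless), size is the
geometric mean `g = (∏ x_j)^{1/p}` and the Mosimann shape variables are
`x_j / g`, or their natural logs. Internally this is computed as
log-then-row-centre, which is algebraically identical to
divide-then-log but avoids one round of exp/log cancellation. Each row of
log-shape sums to zero exactly (tested to 1e-9), which also means the
log-shape covariance is singular: any procedure needing a full-rank
predictor matrix (the discriminants) runs in an orthonormal Helmert basis
of the sum-zero subspace. LDA is invariant to this change of basis, so
nothing is lost.

Diagnostic ratios (HL/FL, tib/fem, ESD/HL, …) are always computed per
specimen and then averaged within groups — never as ratios of group
means, which are not the same quantity.

Structural totals (SVL, hindlimb HL, forelimb FL) are sums of segment
measurements. The exact component lists are configurable because
published component tables are often relegated to supplements; the
defaults are SVL = skull + vert + pelv, HL = fem + tib + calc + foot,
FL = hum + rad + hand.

## Phylogenetic machinery

The Brownian-motion covariance `C` has `C_ij` equal to the shared
root-to-MRCA path length and `C_ii` the root-to-tip distance. Nothing
assumes ultrametricity: trees with substitutions-per-site branch lengths
have unequal diagonals, and everything downstream handles that. Pagel's
λ multiplies off-diagonal entries only. `λ_max` — the largest λ keeping
C(λ) positive semi-definite — is found by bisection on the smallest
eigenvalue and exceeds 1 for non-ultrametric trees, so ML λ̂ > 1 is
representable and is never clamped.

All solves with C go through Cholesky factorizations, never explicit
inverses. When a factorization fails (duplicated tips, λ at the PSD
boundary), an escalating diagonal jitter (1e-10 → 1e-4 of the largest
diagonal entry) is applied and recorded on the covariance object.

Ancestral states of a continuous trait are the joint ML estimates under
Brownian motion, i.e. the minimizer of Σ_edges (Δx)²/branch-length — a
sparse weighted-Laplacian solve. The root estimate coincides with the
phylogenetic GLS mean; on a star tree it is the arithmetic tip mean.
These estimates were cross-checked against an independent reference
implementation on a 7-tip fixture and agree to 1e-6.

## Ordinations and ratio spectra

pPCA eigendecomposes the evolutionary covariance
`R = (X − 1a)' C⁻¹ (X − 1a)/(n−1)` about the GLS mean `a`; scores are
`(X − 1a)V`. Percent variance comes from the eigenvalues of `R`
(covariance-mode convention; correlation mode is available behind a
flag). With `C = I` this reduces exactly to ordinary covariance PCA.

SPCA is covariance PCA after row-centring the log-measurements —
projection orthogonal to the isometric direction — so at most p−1
eigenvalues are nonzero and specimen-wise rescaling cannot move scores.

Eigenvector signs are fixed by making each axis's largest-magnitude
loading positive, which makes outputs byte-reproducible. Bootstrap
spectra resample species with replacement; each replicate's axes are
matched to the point estimate by maximal |dot| (axis swaps counted and
reported) and sign-aligned before percentile intervals are taken.
Replicates with degenerate covariance are redrawn, up to 10× the
requested count. The reported intervals are clipped to contain the point
estimate, so interval containment is an invariant rather than a
probabilistic statement.

The allometry spectrum regresses each variable's log-shape value on log
size (the row mean). "Shape is significantly correlated with size" is a
family-wise decision: bootstrap percentile CIs of every pairwise
coefficient difference at the Bonferroni-adjusted level 1 − 0.05/m
(m = p(p−1)/2); any interval excluding zero triggers the call. The 68%
per-variable intervals are for display; a per-pair 68% criterion would
reject essentially always under a null with any sampling noise, which is
why the significance call uses the family-wise construction. Note a
caveat the synthetic analysis itself illustrates: regime-driven shape
shifts and Brownian size share the phylogeny, so the allometry test can
flag a real (phylogenetically confounded) shape–size correlation even
though the generator adds size isometrically.

## PERMANOVA

With Euclidean distances on log-shape, Anderson's Gower-centred
partition reduces to centroid sums of squares, which is how it is
computed: SS_between = Σ n_g‖x̄_g − x̄‖², F = (SS_b/(k−1))/(SS_w/(n−k)).
Group labels are permuted freely; p = (1 + #{F* ≥ F})/(1 + n_perm), so
the smallest attainable p is 1/(n_perm+1). Univariate two-group input
reproduces the classical ANOVA F exactly, and the pseudo-F matches an
independent distance-matrix implementation to 1e-8 in the tests.
Pairwise contrasts rerun the test per group pair; Bonferroni is the
default adjustment (Holm and Benjamini–Hochberg available). Defaults:
999 permutations.

## PGLS

`y = Xβ + ε`, `ε ~ N(0, σ²C(λ))`. For fixed λ, β̂ is the GLS solution
via Cholesky solves; the profile log-likelihood uses the ML variance
rss/n. λ̂ is searched on a 0.01 grid over [0, λ_max] with bounded local
refinement around the best grid point; the refined optimum is asserted
to be no worse than the grid peak, and boundary hits are flagged.
Standard errors use the unbiased variance rss/(n−k), so λ = 0 with an
identity covariance reproduces OLS coefficient tables exactly (tested
against an independent implementation to 1e-10). AIC counts k
coefficients plus σ² and λ. Categorical predictors are integer-coded in
a declared level order by default, giving one coefficient per factor as
in compact published tables; conventional dummy coding is available, and
the coding and level order are recorded in the fit. Model selection
ranks candidate designs by AIC with ties broken by declaration order.

## Discriminants

LDA is the classical Gaussian discriminant: class means, pooled
within-class covariance with denominator n−k, priors defaulting to
observed class proportions, posteriors from the shared-covariance
Gaussian rule. Resubstitution (training-set) accuracy is the headline
number reported by the confusion matrices.

pFDA accounts for phylogeny in estimation. With L the lower Cholesky
factor of C(λ), both X and the class indicator matrix G are
premultiplied by L⁻¹; class means are the GLS estimates
(G*'G*)⁻¹G*'X* and the pooled covariance comes from the whitened
residuals. Classification then applies the Gaussian rule to raw trait
rows with these phylogenetically estimated parameters — whitened rows
themselves are not class-centred and must not be classified directly.
At λ = 0 on a unit-height ultrametric tree the construction collapses to
LDA exactly (asserted on every fixture).

The "optimal" λ maximizes the Gaussian log-likelihood of the whitened
multivariate regression of X on G, including the −p/2·log|C(λ)|
Jacobian of the whitening — omitting that term makes the criterion
monotone in λ. The full (λ, log-likelihood) trace is stored on the
model for audit.

Held-out tips (the "Neobatrachia" clade in the pipeline) are classified
with the conditional phylogenetic distribution: under class g a held-out
row has mean m_g + c_hT C_TT⁻¹ (X_T − Ĝ M̂) and covariance scaled by the
Schur complement; on a star tree this reduces to plain prediction.

## Synthetic data generator

The generator's defaults are the study-sized conditions: 164 tips, 16
log-scale traits, 5 locomotor regimes, 4 habitats, 3 clades plus 10
held-out species. Components:

- **Tree**: forward Yule simulation from two root lineages, with one
  additional Exp(n·λ) interval after the n-th lineage so pendant branches
  are bounded away from zero (otherwise the final split leaves
  near-duplicate tips whose inverse-covariance weights explode against
  measurement noise); rescaled to unit height. A rate-heterogeneous mode
  multiplies branches by lognormal factors to mimic molecular branch
  lengths.
- **Regimes**: symmetric Mk jump process, default rate 0.7 per unit
  height — phylogenetically conserved but mixed, resembling the
  clumped-but-repeated evolution of locomotor modes; redrawn (up to 100
  fresh substreams) until all states are realized.
- **Traits**: matrix-normal with row covariance C(λ_true) (default
  λ = 1) and column covariance Σ = σ²[(1−ρ)I + ρJ] (σ = 0.15 log-units
  over unit height, ρ = 0.3); regime mean shifts δ applied at the tips
  with an ecomorphologically signed default pattern (jumpers: longer
  tibiofibula/calcaneus, narrower sacrum; burrowers/swimmers: wider
  bones and sacral expansion) scaled by 0.4 log-units; a latent Brownian
  log-size (σ = 0.5) added to every trait; iid log-scale noise
  (sd 0.02, a few percent measurement error); exponentiation to cm.
  Applying δ to tip means rather than as OU optima is a deliberate
  simplification — it produces exactly the class-mean structure LDA
  assumes, at the cost of not modelling adaptation dynamics.
- **Labels**: habitats drawn per regime from fixed tables (terrestrial-
  heavy, arboreal ≈ arboreal jumpers, aquatic ≈ swimmers); clades are
  contiguous blocks of the tip order (basal ≈ 10%, the rest split in
  two), with 10 tips scattered across the non-basal range relabelled as
  the held-out group. The iliac angle is drawn from regime-specific
  normal distributions (means 8–10°), clipped to (0°, 90°).

Everything derives from one seed through `SeedSequence` spawning, so
(config, seed) reproduce files byte-identically.

What the generator does **not** emulate: real measurement-error
correlation within specimens, allometric growth curves, missing data,
family-level sampling structure, or the actual frog trait distributions.
Passing tests therefore demonstrate the estimators' correctness and
calibration under the assumed model, not field performance on any
particular empirical dataset.

## Problem sizes in the test suite

The statistical-calibration tests use 500 null PERMANOVA simulations at
n = 60 with 199 permutations, 100 + 100 PGLS λ-recovery replicates on
128-tip trees, and single 164-species datasets for the discriminant
checks; the whole suite runs in a few minutes on one CPU. The chance
level for the null discriminant check is 1/k, which presumes uniform
priors and near-balanced classes; the test therefore uses the
generator's high-rate Mk regime (near-iid uniform labels) and uniform
priors, evaluated on a stratified held-out half rather than by
resubstitution (resubstitution is optimistically biased under the null).

## Known limitations

- pFDA is the Gaussian/optimal-scoring construction with linear
  regression only; no regularized, quadratic or nonlinear variants.
- PERMANOVA offers Euclidean distance only (on log-shape this is the
  natural choice); no dispersion (PERMDISP) test.
- The λ grid step (0.01) bounds the precision of reported λ̂ beyond the
  local refinement of the profile optimum.
- Confusion-matrix percentages are rounded to one decimal for display;
  accuracy is always computed from counts, not from rounded percentages.
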