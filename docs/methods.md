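# Methods

## Model

`sparsesem` estimates a linear structural equation system linking an
n × M matrix of phenotypes Y (endogenous) to an n × K matrix of genetic
variables X (exogenous):

    Y Γ + X B + E = 0,        γ_ii ≡ −1,

so that each column reads y_i = Y₋ᵢ γ₋ᵢ + X Bᵢ + eᵢ.  Γ[j, i] is the path
coefficient of the directed phenotype edge j → i, B[k, i] the coefficient
of the edge from exogenous column k to phenotype i.  Errors are assumed
independent across equations and uncorrelated with X; no intercepts appear
because all columns are mean-centred before estimation.  The support of
(Γ, B) is the inferred genotype–phenotype network.

Ordinary least squares on each equation is inconsistent because Y₋ᵢ is
endogenous.  Estimation therefore uses the exogenous matrix as
instruments.  With W = [Y₋ᵢ X], A = XᵀW, Mx = (XᵀX)⁻¹ and b = Xᵀyᵢ, the
generalised least squares estimate

    Δ̂ᵢ = [Aᵀ Mx A]⁻¹ Aᵀ Mx b

is identical to classical two-stage least squares (project W on the column
space of X, then regress yᵢ on the projections); the package asserts this
identity in its tests.  Sparsity is imposed per equation by minimising

    f(Δ) + λ‖Δ‖₁,    f(Δ) = (b − AΔ)ᵀ Mx (b − AΔ),

with an alternating-direction method of multipliers (ADMM).

## ADMM solver

Scaled-form lasso ADMM with the splitting Δ = z:

* quadratic update: solve (2AᵀMxA + ρI)Δ = 2AᵀMx b + ρ(z − u), with the
  Cholesky factor cached per ρ and reused along a λ path (the matrix does
  not depend on λ);
* z-update: elementwise soft-threshold of Δ + u at λ/ρ;
* dual update: u ← u + Δ − z.

The reported solution is z, so zeros are exact.  ρ starts at 1.0 and is
adapted by residual balancing (doubled/halved when the primal and dual
residuals differ by more than 10×, rescaling u accordingly), which makes
convergence insensitive to the scale of A.  Stopping uses the standard
absolute/relative criteria with defaults tol_abs 1e-6, tol_rel 1e-4,
max_iter 2000.  The smallest penalty that zeroes an equation is
λ_max = 2‖AᵀMx b‖_∞.  The solver is validated against an independent
coordinate-descent lasso on the Cholesky-reformulated problem
(Mx = LLᵀ; standard lasso on (LᵀA, Lᵀb)) to 1e-6 in objective value.

(XᵀX)⁻¹ is computed by eigendecomposition with a relative eigenvalue floor
of 1e-10·trace; an optional ridge is added both to XᵀX and to the GLS
bracket, because when W has more columns than there are instruments the
bracket — not XᵀX — is the singular matrix.  The unpenalised estimator
refuses to run on a rank-deficient bracket unless a ridge is supplied.

## Column standardisation

Phenotype columns are amplified through the network (variances can exceed
the genotype columns' by orders of magnitude), so a uniform λ on centred
but unscaled columns penalises genotype coefficients far more heavily than
phenotype coefficients and distorts support recovery.  All fitting
therefore standardises columns to unit variance by default (coefficients
are mapped back to the original scale afterwards), the same convention as
glmnet.  `standardize=False` restores centring-only behaviour.

## Penalty selection

λ is chosen per equation by K-fold cross-validation (default 5) minimising
the held-out GLS criterion f, computed on each validation fold with that
fold's own moment matrices; folds come from a seeded permutation, so
selection is deterministic given the seed.  Ties break toward the larger
(sparser) penalty.

Because every equation has M−1+K candidate columns but only K instruments,
f has a flat (unidentified) subspace of dimension M−1: the held-out
criterion cannot penalise coefficient movement in that subspace and
decreases monotonically as λ → 0 instead of turning upward.  The λ grid
therefore carries a floor, by default 0.02·λ_max over 10 log-spaced
points, which bounds the density of the cross-validated solution the same
way glmnet's small-λ cutoff does in p > n problems.  The floor is the one
tuning constant that materially shapes the inferred network density and is
exposed as `lambda_grid(min_ratio=...)`.

Inside the simulation harness, the CV path runs the ADMM at screening
accuracy (max_iter 500, tolerances 1e-5/1e-3) — the held-out criterion is
insensitive to the final digits of path solutions — and the final fit at
the selected λ uses full accuracy.

## Genotype coding and functional representation

Genotypes are coded with allele-frequency weights: QQ → 2P_q,
Qq → P_q − P_Q, qq → −2P_Q, which has expectation zero under
Hardy–Weinberg equilibrium at frequencies (P_Q, P_q).  Missing calls are
imputed to that zero mean.  Q is the VCF reference allele; frequencies
absent from the input are estimated from the sample.

For gene-based analysis, the coded genotypes of a gene's SNPs are viewed
as observations of a genotype function x(t) of genomic position.
Positions are affinely rescaled to [0, 1] and a discretised
Karhunen–Loève decomposition is computed: SVD of the centred profile
matrix weighted by trapezoid quadrature weights, giving eigenfunctions
orthonormal in the weighted inner product and per-sample scores
η_l = Σ_k w_k (x(t_k) − x̄(t_k)) φ_l(t_k).  No spline smoothing is applied:
SNP grids are sparse and irregular, and the discretised estimator keeps
the single-SNP case exact (a one-SNP gene degenerates to the centred coded
genotype).  Components are kept until a cumulative variance fraction
`var_target` (default 0.8) is reached; components below 1e-10 of the
leading eigenvalue are always dropped.  The functional SEM is then exactly
the SNP-based model with X replaced by the concatenated score matrix η,
and the genetic effect function of gene j on phenotype i is
β_ji(t) = Σ_g b_jig φ_jg(t).

For genome-scale inputs the analysis runs in two stages: genes are
partitioned into groups (pathways, or chunks of at most 100 genes in
position order), the functional SEM is fitted per group, genes with any
gene-level test p-value below α₁ = 0.05 (unadjusted — this is a screening
stage) are pooled, and the model is refitted on the pooled set.

## Inference

Hypothesis tests are computed from an unpenalised two-stage least squares
refit on the selected support — the classical covariance formulas assume
no shrinkage, and the refit removes the lasso bias from the tested
estimates.  For equation i with refit residuals e:

    σ̂_ii = eᵀe / n,
    Σ̂ᵢ = σ̂_ii [WᵀX(XᵀX)⁻¹XᵀW]⁻¹   (restricted to the refit columns).

A single coefficient is tested with T_c = Δ̂²/var(Δ̂) ~ χ²(1); a gene's
whole FPC block with T_g = b̂ᵀΛ⁻¹b̂ ~ χ²(G), where Λ is the block submatrix
of Σ̂ᵢ and G the number of retained components.  The tested column or
block is always added to the refit, so coefficients the lasso dropped
remain testable.  When the selected support plus the tested block exceeds
the number of effective instruments (singular bracket), the refit falls
back to the equation's phenotype support plus the tested columns — the
smallest refit that still adjusts for the phenotype network.  Null
calibration of both statistics is verified by simulation (size within
[0.035, 0.065] at α = 0.05 over 1000 replicates; quantile agreement at
0.5/0.9/0.95).

Multiplicity is handled by Bonferroni or Benjamini–Hochberg adjustment
(statsmodels implementations).  Stability selection refits the model on
resampled data (bootstrap of size n by default; n/2 subsampling available)
and keeps an edge only if its full-data p-value is below `p_thresh`
(default 0.05) and its selection frequency is at least `freq_thresh`
(default 0.8 over 100 resamples).

## Effect decomposition

On the fitted directed coefficient graph, the direct effect of X on Y is
the X → Y edge coefficient (zero if absent); the total effect is the sum
over all simple directed paths of the product of path coefficients; the
indirect effect is their difference, equivalently the sum over paths of
length ≥ 2.  For acyclic phenotype networks the path sum equals the
closed form (I − C)⁻¹ − I with C = Γ + I.  The same quantity is available
as an intervention regression: the coefficient of X in the least-squares
regression of Y on X and X's parents, which for parentless nodes (SNPs,
genes) is the simple-regression (marginal) slope.  The correlation
identity β_{YX.Z} = β_{YX}(1 − ρ_YZ ρ_ZX/ρ_YX)/(1 − ρ_XZ²) links the two
and is verified numerically.  Pairs whose connecting subgraph contains a
cycle (including two-directional edges, which this class of model can
produce) are refused and flagged rather than assigned a value: path sums
are not well defined without an acyclic route, and guessing would be
worse than declining.  Reported tables round to 4 decimals.

## Synthetic-data generator

The generator reproduces the benchmark design the estimators are assessed
under:

* phenotype network: random DAG from a uniformly random topological order
  with independent edge inclusion at probability d/(M−1); the expected
  total degree d defaults to 3;
* nonzero Γ entries uniform on (0.5, 1) or (−1, −0.5), equal sign
  probability; nonzero B entries uniform on (0, 1) or (−1, 0);
* genotype connections: by default each phenotype is affected by 3
  genetic units (SNPs or genes) drawn without replacement (pleiotropy
  arises when units are shared); a one-unit-per-phenotype scheme is
  available for no-pleiotropy scenarios.  For gene-based runs every SNP
  of a selected gene receives an independent U(0, 1) magnitude with a
  shared per-edge sign;
* genotypes: Hardy–Weinberg draws at MAF ~ U(0.05, 0.5) for common
  variants and U(0.005, 0.01) for rare (monomorphic draws are resampled);
  the rare band keeps the expected minor-allele count near 45 at n = 3000
  so estimation is feasible;
* phenotypes: Y = −(XB + ε)Γ⁻¹ with ε ~ N(0, 0.01·I) (noise sd 0.1).

What the generator does not emulate: linkage disequilibrium between SNPs
(columns are independent given their MAFs), population structure,
covariates, missing data, and real exome site-frequency spectra.  Passing
recovery benchmarks on these draws therefore demonstrates correctness of
the estimator under the stated model, not performance on real cohorts,
where LD in particular redistributes signal across neighbouring variants.

Recovery is scored as PD = (true edges detected)/(true edges) and
FDR = (false edges detected)/(edges detected), with FDR defined as 0 when
nothing is detected.  Detection is membership in the fitted support at
the cross-validated λ; for gene-based scoring a gene–phenotype edge
counts as detected when any coefficient in the gene's block (or, for the
SNP-based estimator, any member SNP) is nonzero.

## Benchmark problem sizes

The shipped benchmark (`scripts/acceptance.py`) runs 20 replicates of two
scenarios: the gene-based functional SEM on 10 phenotypes × 10 genes of
10 rare SNPs at n = 3200 (reporting mean PD), and the SNP-based model on
30 phenotypes × 100 rare SNPs at n = 3000 (reporting mean FDR).  Twenty
replicates put the Monte-Carlo standard error of the reported means near
one percentage point, which is sufficient to place both quantities
relative to their reference levels.

## Known limitations

* Each equation is only partially identified (M−1 more candidate columns
  than instruments); the L1 penalty supplies the missing identification,
  so the inferred network — especially edge directions between
  highly-correlated phenotypes, and the split between a parent phenotype
  and that parent's own genetic determinants — depends on the penalty
  level.  In the near-noiseless regime of the benchmark design the
  structural and reduced-form representations of an equation have almost
  equal L1 norm, which keeps the support-level false discovery rate of
  the SNP-based estimator substantial even at large n.  Significance
  pruning and stability selection mitigate but do not remove this.
* Two-directional phenotype edges can be reported (each direction is
  estimated in a different equation); effect decomposition refuses such
  pairs rather than resolving them.
* Post-selection inference: p-values come from an unpenalised refit on a
  data-driven support and are calibrated under the null of no signal, not
  corrected for selection.
* No acyclicity constraint is imposed during estimation; a combinatorial
  DAG search is out of scope.
* Rare-variant runs with K ≥ n require the ridge option; the default
  configurations keep K well below n.
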