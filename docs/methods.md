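# Methods

## Model

`ridgepath` fits the penalized linear model for genomic prediction: for a
line with marker dosages x ∈ R^p and phenotype y,

    y_i = β₀ + x_iᵀβ + ε_i,          E[ε_i] = 0,

with coefficients estimated by minimizing, at each candidate penalty λ ≥ 0
and mixing parameter α ∈ [0, 1],

    (1/(2n)) Σ_i (y_i − β₀ − x_iᵀβ)² + λ [ (1−α)/2 ‖β‖₂² + α ‖β‖₁ ].

α = 0 is ridge regression (the primary use case), α = 1 the lasso, and
intermediate values the elastic net.  We use the per-observation (1/(2n))
normalization throughout because both grid constructions presuppose it;
the textbook penalized residual sum of squares with no 1/n factor
corresponds to the penalty λ·n on our scale (the ½ factors cancel for
ridge).  When λ = 0 and n > p the solution is ordinary least squares.

All fitting happens on standardized data.  Standardization uses the
**population (1/n) variance convention** for both the marker columns and
the response — this is deliberate and load-bearing: under it the squared
column norms of the standardized training matrix sum exactly to p, which
is what gives the variance-ratio grid its closed form.  Statistics are
always estimated on the training partition alone; held-out rows are
transformed with training statistics and predictions are mapped back to
the observed phenotype scale (ŷ = ȳ_trn + σ_y,trn·ŷ_std) before any metric
is computed.  Zero-variance (monomorphic) columns are dropped with a
logged warning and an index map, because cross-validation subsampling of
marker panels routinely produces monomorphic columns within a fold.

## The two λ grids

**Conventional (glmnet-style) path.**  On standardized training data the
per-column scores S_j = (Σ_i Xs_ij·ys_i)·1000/n are computed; λ_max is the
largest |S_j|, λ_min = λ_max·r with r = 0.01 when p > n and 0.0001
otherwise, and 100 values are placed log-uniformly from λ_max down to
λ_min.  The literal factor 1000 is glmnet's internal ridge surrogate (the
ridge path's exact λ_max is infinite, so glmnet computes it at α = 0.001);
we reproduce it rather than "correct" it, since the whole point of this
generator is fidelity to the conventional tool.  glmnet's deviance-based
early termination of the path is documented here but not implemented:
the full grid is always evaluated.

**Variance-ratio grid.**  A log-spaced sequence of proportions of
phenotypic variance attributable to the markers, R²_l from 1e-5 to 0.9999
(endpoints exact), is mapped to penalties via the mixed-model ratio of
variance components λ = σ²/σ_β².  With the error share σ² = (1−R²)s_y²
and the genetic share R²s_y², normalized by the mean squared row norm
m = (1/n)Σ_i x_iᵀx_i of the standardized markers,

    λ_l = ((1 − R²_l) / R²_l) / m  =  (1 − R²_l) / (R²_l · p),

the last equality holding exactly under 1/n standardization.  The
phenotypic variance cancels; the implementation still accepts s_y² and a
test asserts the invariance.  The resulting grid spans ~9 orders of
magnitude — in particular it reaches far below the conventional path's
floor of 0.01·λ_max, which is where the optimal ridge penalty for a
polygenic trait typically lives.  That extra reach is the method's entire
contribution; the conventional grid's inability to go below its floor is
what it is being compared against.

A note on the m-normalization: an alternative convention multiplies
rather than divides by m (the two differ by a factor m², and variance-
component bookkeeping can be set up to argue for either).  We prototyped
both; multiplying leaves an enormous gap in the grid below λ ≈ 0.12·p
(the log-spacing of R² concentrates points at small R², i.e. large λ),
which makes the grid select *stronger* penalties than the conventional
path and reverses every qualitative behavior this method exists to
produce.  Dividing produces those behaviors, so division is what we
implement.

## Penalty selection and evaluation protocol

Nested cross-validation.  The **inner loop** (default 10-fold) selects λ:
the grid is built once from the full outer-training block (matching
cv.glmnet, which also shares one grid across its folds) while
standardization is refit on each inner-training block, so validation rows
never touch the fitted coefficients.  Validation MSE is computed on the
observed phenotype scale and recorded both as a raw sum of squares and as
a per-observation mean; fold averaging uses the mean so unequal folds
weight correctly.  Exact ties resolve to the largest (most regularized)
λ.  After selection the model is refit at λ_opt on the whole training
block.

The **outer loop** (default 10-fold) estimates accuracy.  Per fold and
per method we report Pearson correlation (Cor) and the mean-normalized
error NRMSE = sqrt(MSE)/mean(y_obs).  The un-rooted variant MSE/mean(y)
is available behind a switch (`nrmse_variant="plain"`) since the name and
the printed formula of this metric diverge in parts of the literature; we
default to the rooted form because it is the one that is scale-free in
the way cross-trait comparison requires.  NRMSE is undefined (raises) for
zero-mean responses.  All compared methods consume identical outer folds
and identical per-fold inner seeds, making every comparison paired.
Aggregation reports fold means with across-fold sample SDs per trait,
across-trait means per dataset (SD = 0 for single-trait datasets, by
convention), an across-dataset grand summary, and the percent Cor/NRMSE
gain of the variance-ratio grid over the conventional path.  The per-fold
diagnostic log(λ_opt,conventional / λ_opt,variance-ratio) summarizes which
strategy penalizes harder; in the p ≫ n regime the conventional path
selects the stronger penalty in the majority of folds.

## GBLUP comparator

The mixed model y_i = μ + g_i + ε_i with g ~ N(0, σ_g²G) and the VanRaden
(method 1) genomic relationship matrix G = ZZᵀ/(2Σ_j p_j(1−p_j)),
Z = X − 2p, allele frequencies from column means.  Variance components
are estimated by restricted maximum likelihood profiled to one dimension:
after a single eigendecomposition of the training-block G, the restricted
log-likelihood is maximized over the variance ratio δ = σ²/σ_g² by
bounded scalar search on log δ ∈ [log 1e-9, log 1e9] (xatol 1e-8).
Predictions for unphenotyped lines are
ĝ = G[test,train](G[train,train] + δI)⁻¹(y − μ̂) with μ̂ by GLS.  A
non-PSD G (beyond −1e-8) is ridge-stabilized by 1e-6 on the diagonal with
a warning.  In cross-validation contexts allele frequencies default to
the training partition only (leakage control); a whole-data mode exists
behind `g_mode="all"`.

GBLUP is a reparameterization of marker ridge: with G = ZZᵀ/c, BLUP at
ratio δ equals ridge-on-Z prediction at the per-observation penalty
λ = δ·c/n (push-through identity).  This equivalence is asserted
numerically to 1e-6 in the tests and acceptance script, and is the reason
a single frequentist comparator suffices where Bayesian and frequentist
GBLUP implementations agree to ~3 decimals anyway.  MCMC-based GBLUP is
out of scope.

## Synthetic data

The simulator emulates a genomic-selection panel: n lines in the
hundreds, p ≫ n biallelic markers coded {0,1,2}.  Haplotypes are
first-order Markov chains over adjacent markers with target correlation
`ld_rho` (default 0.3 in the benchmark scenarios) — a crude
linkage-disequilibrium stand-in; allele frequencies are Uniform(0.05,
0.5).  Traits are additive: a random QTL subset (10% of markers in the
defaults) receives Gaussian effects; genetic values are centered and
rescaled to sample mean 0 / variance 1 and noise is added with
σ_e² = (1−h²)/h², so the realized genetic-variance share equals the
target heritability exactly on the generated sample (sharp calibration
matters for the stochastic recovery tests at these n).  The intercept
defaults to μ = 10, keeping the phenotype mean well away from zero the
way measured agronomic traits do — without this the NRMSE denominator is
meaningless.  The generator does **not** model population structure,
dominance/epistasis, genotype missingness, or realistic LD block
structure; passing benchmarks here demonstrate protocol correctness and
the directional grid comparison, not absolute accuracy levels on real
panels.

Benchmark scenarios (fixed seeds): n=100/p=500/h²=0.3, n=300/p=2000/h²=0.5,
and a null (h²=0) scenario with zero QTL effects.  The evaluation sizes
used by the acceptance script — n=100, p=500, 10×10 nested folds, five
replicate seeds per heritability — were chosen as the smallest regime in
which the directional comparison is stable across seeds.

## Numerical choices

- Ridge paths are solved by one thin SVD of the standardized training
  matrix and closed-form evaluation at every λ; the economy SVD has rank
  min(n,p), so the p ≫ n dual route is automatic.  Coordinate descent
  (soft-thresholding sweeps, warm starts down the descending path,
  default tol 1e-7 on the max coefficient change, cap 1e5 sweeps) handles
  α > 0 and serves as the cross-check route for ridge.  Non-convergence
  is a recorded warning, not an error.
- The stopping rule bounds the per-sweep change, not the distance to the
  optimum; oracle-equivalence tests therefore run CD at tol 1e-10.
- On standardized data the intercept is analytically zero; it is computed
  from the column means (and asserted ≈ 0 in tests), never estimated.
- Seeds are explicit everywhere; every derived seed is a deterministic
  function of the top-level seed, and two runs with the same
  configuration produce byte-identical outputs (floats serialized at 17
  significant digits).

## Known limitations

- The conventional-path generator always uses the ridge-surrogate recipe
  regardless of α; glmnet's α-dependent λ_max for lasso/elastic-net paths
  is not reproduced.
- No observation weights, sparse storage, or non-Gaussian families.
- The LD model is a single Markov chain; real panels have block
  structure, and absolute accuracies here should not be read as
  predictions of real-data accuracy.
- Cor is reported as missing (NaN, logged) when a fold's observed or
  predicted values are constant; such folds are excluded from averages.
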