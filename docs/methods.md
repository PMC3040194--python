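# Methods

## Model and estimators

The package fits a phylogenetic ANCOVA with parallel slopes: for n species
the trait (hematocrit, % packed cell volume) is

    y = X β + ε,   ε ~ N(0, σ² V),

with X an intercept plus 0/1 dummy columns for Habitat (levels Terrestrial,
Semi-aquatic, Aquatic, Marine; base Terrestrial) and Clade (seven snake
lineages; base Colubrinae), in the fixed report order intercept,
Semi-aquatic, Aquatic, Marine, Boidae, Acrochordidae, Viperidae,
Homalopsidae, Elapidae, Natricinae.  Three residual covariance structures
define the three estimators:

* **star** (OLS): V = I.  No phylogenetic structure.
* **bm** (PGLS): on the tree rescaled to height 1, V_ij is the depth of the
  most recent common ancestor of tips i and j (their shared root-to-tip
  path length); the diagonal is 1.
* **ou** (RegOU): with d = e^(−α) ∈ [0, 1] indexing the strength of an
  Ornstein–Uhlenbeck pull, a pair with MRCA depth s gets

      V_ij(s, d) = d^(2(1−s)) · (1 − d^(2s)) / (1 − d²),

  which is the non-stationary OU tip covariance on a height-1 tree
  normalized to unit diagonal.  d = 1 gives V_ij = s exactly (Brownian
  limit, implemented by continuity), d = 0 gives the identity.

All three matrices have unit diagonal by construction, which keeps ln|V| on
one scale and makes the twelve grid fits directly comparable.

A caution about the star limit: V_ij(s, d) → 0 as d → 0 for every fixed
s < 1, but the convergence is not uniform — a pair that diverged very
recently (s near 1) retains covariance ≈ d^(2(1−s)) ≈ 1 at any fixed small
d.  Tests of the limit therefore use reference trees whose MRCA depths are
bounded away from 1, plus exactness at d = 0.

## Likelihood and model-selection conventions

* lnML is the multivariate-normal log-likelihood profiled over the ML
  variance σ̂² = SSE_V/n:  lnML = −(n/2)(ln(2π·SSE_V/n)+1) − ½ln|V|.
  This convention is forced by the internal consistency of the published
  model-comparison table (its intercept-only MSE of 30.71 on 66 df
  reproduces its printed lnML of −209.29 only under the profiled form).
* MSE = SSE_V/(n−p) (so the intercept-only row uses 66 df at n = 67);
  SEE = √MSE; r² = 1 − SSE_V/SSE_V,0 with SSE_V,0 from the intercept-only
  GLS fit under the same V, hence r² = 0 for intercept-only models and r²
  is non-decreasing as columns are added under fixed V.  For PGLS/RegOU
  this GLS-residual r² is a convention, not the only possible definition;
  published r² values for the phylogenetic estimators may differ slightly.
* AIC = −2lnML + 2k, AICc = AIC + 2k(k+1)/(n−k−1); k = p + 1 for OLS/PGLS
  (coefficients + variance) and p + 2 for RegOU (adds d).  fit_gls reports
  AICc = NaN when n − k − 1 ≤ 0 (tiny instances); the standalone aicc()
  raises instead.
* d is estimated by **REML** — the restricted likelihood
  −((n−p)/2)(ln(2π·SSE_V/(n−p))+1) − ½ln|V| − ½ln|XᵀV⁻¹X| is maximized
  over d ∈ [0,1] by a 21-point grid warm start followed by bounded scalar
  minimization (xatol 1e-6).  The FitResult reported at d̂ carries ML
  quantities (lnML, AIC, AICc), mirroring the convention of the MATLAB
  program this estimator family comes from.  If the profile is flat within
  1e-8, the smallest maximizing d is returned (preferring the simpler,
  star-ward model).
* The likelihood-ratio test for phylogenetic signal compares RegOU against
  OLS with the same design, statistic 2·(lnML_RegOU − lnML_OLS) against
  χ²(1).  Because the REML d̂ does not maximize the ML profile, the LRT
  block re-optimizes d on the ML surface; this guarantees a non-negative
  statistic and makes it a genuine likelihood ratio.  The comparison table
  still reports the REML d̂.
* Partial F-tests compare nested GLS fits under the same V:
  F = ((SSE_red − SSE_full)/q)/(SSE_full/(n−p)) with upper-tail p-values;
  a single-column test equals the squared coefficient-to-SE ratio.  No
  multiple-testing correction is applied anywhere.
* AICc support bands (rough rules of thumb): Δ ≤ 2 "substantial",
  2–4 "weaker", 4–7 "considerably less", 7–10 "little", > 10 "virtually
  none".  Only the 2/4 and 10 edges are anchored by the source analysis;
  the 7/10 split is this package's documented choice.  AICc ties are
  broken toward fewer parameters.

## Tree conventions

Newick parsing is delegated to dendropy (underscores preserved, polytomies
retained); trees are stored as a flat node table with tips in left-to-right
Newick order.  Topologies without meaningful lengths get the node-height
convention: internal node height = number of descendant tips − 1, tips at
height 0, branch length = parent height − child height.  The result is
ultrametric with root height n − 1; zero-length branches can arise at
polytomies and are accepted downstream.  Before covariance construction
trees are rescaled to height 1, making d scale-free and likelihoods
comparable across estimators.  Tip labels are matched to the species table
exactly after trimming whitespace and unifying underscores/spaces; any
mismatch is a hard error listing the offending names.

## Numerical choices

GLS fits whiten by the Cholesky factor of V and solve by QR; rank
deficiency (smallest |R_ii| below 1e-10 of the largest) raises an error
naming the collinear columns, and a non-PD V raises rather than being
jittered.  Covariance matrices are validated as symmetric with smallest
eigenvalue ≥ −1e-10; dense linear algebra throughout (n is at most a few
hundred).  The OU transform uses expm1 so the (1−d^(2s))/(1−d²) ratio stays
stable as d → 1.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

* **Tree** — pure-birth (Yule, rate 1) with the requested number of tips,
  exponential waiting times, one extra waiting time after the last split so
  tips are contemporaneous; rescaled to height 1.
* **Clades** — monophyletic blocks obtained by repeatedly splitting the
  largest current block from the root down until the requested count is
  reached; labels from the 7-level vocabulary, largest block first.
* **Habitat** — a root-to-tip Markov walk: each branch keeps its parent's
  state with probability 1 − switch_prob, otherwise moves uniformly to one
  of the other three states; the root state is uniform.  This makes habitat
  phylogenetically clumped, as in real data, rather than i.i.d.
* **Trait** — y = Xβ + ε with ε ~ N(0, σ²·V_ou(tree, d_true)).

Defaults mirror the study conditions: 67 tips, 7 clades, fixed effects at
the empirical coefficient scale (intercept 27, Marine +5.3, Aquatic −23.5,
Acrochordidae +17.7, ... in Hct % units), σ² = 16 %² (the full model's
residual MSE scale), d_true = 0.124 (the weak signal estimated for the
trait without predictors), habitat switch probability 0.15 (chosen to give
realistically clumped habitats with all four states usually present at 67
tips).  All randomness flows from a single seed through spawned
generators, so any artifact is reproducible from its seed.

What the generator does **not** emulate: measurement error and
intraspecific variation in the trait, extinction (no birth–death trees),
correlation between habitat state and clade identity beyond what the
shared tree induces, and the physiological bounding of the trait —
Gaussian residuals are unbounded, so synthetic tables are constructed with
the (0, 100) range check disabled.  Passing tests on synthetic data
therefore demonstrate the estimators' correctness under the assumed model,
not robustness to the ways real comparative data violate it.

A level of a factor that never occurs in a simulated table would produce an
all-zero, inestimable dummy column; pipeline entry points therefore build
designs with `drop_unobserved=True`, while the default keeps the full fixed
column set.

## Monte-Carlo test design

Coefficient-unbiasedness checks use antithetic residual pairs (ε, −ε): GLS
estimators are exactly symmetric in the residuals (and the REML d̂ is an
even function of them), so the paired mean isolates systematic bias —
misalignment between tree and table, wrong design construction — from
sampling noise.  Calibrated statistical assertions (iid-residual check,
cherry-count check, F-test size) use fixed seeds and 2-standard-error
bands; the expected pure-birth cherry count is derived from the recursion
E[C₂] = 1, E[C_{m+1}] = E[C_m](1 − 2/m) + 1 (equal to n/3 for n ≥ 5).
Recovery experiments use 100–256 replicates at 67–128 tips; these sizes
keep the full suite fast while leaving Monte-Carlo error well below the
asserted margins.

## Known limitations

* Continuous covariates, interaction terms (non-parallel slopes), robust
  standard errors and model averaging are out of scope.
* The OU transform formula used by the original MATLAB implementation is
  unpublished; this package's parameterization satisfies all printed limit
  behaviors, but REML d̂ values for the original dataset may differ from
  the published ones if the parameterizations disagree, and are therefore
  checked with a widened, documented tolerance.
* Reproduction of the published coefficient and model-comparison tables
  requires the study's supplementary species table and tree, which cannot
  be redistributed here; the corresponding test runs (and passes or fails
  on its merits) only when those files are placed under `data/`.
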