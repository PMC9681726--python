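# Methods

This note records the models the package implements, the numerical choices
behind them, what the synthetic-data generator does and does not emulate,
and the known limitations.  It is the design record; empirical behaviour is
established by the test suite, not asserted here.

## Morphometrics

Wing area uses the two-panel approximation
`area = (wingspan − 2H)·S + 2·(H·S/2) = S·(wingspan − H)` (hand length H,
first secondary length S, all in mm).  Published wingspans usually come as
ranges; the midpoint is used.  Subspecies rows are collapsed into species by
field-wise means with pairwise exclusion of missing values.

**Wing loading is mass/area (g·mm⁻²), not area/mass.**  The conventional
definition, the unit, and the plausible range for gull-scale inputs
(e.g. 1000 g / 200 000 mm² = 0.005) all point the same way, and the package
fixes this orientation as an explicit assumption.  Units are fixed (mm, g,
degrees, tree-time units); no auto-detection.

Wing loading enters regressions as a full z-score (mean 0, SD 1, population
divisor n), so coefficients read "per SD of wing loading".  With the
sample-SD convention coefficients would differ by √(n/(n−1)) ≈ 1% at n=50.
Standardization is computed on each analysis' complete-case set, so the
mean-zero property holds exactly on the species actually analysed.
Absolute latitude enters unstandardized — its coefficient reads "per degree
from the equator".

## Trees and covariance structures

Trees are Newick with mandatory branch lengths; tip labels are matched to
table species exactly after underscore/space normalization.  Branch-length
units are treated as opaque tree units and never rescaled.  Pruning keeps
the original root position (a root that becomes unary is retained), so
root-to-MRCA depths of retained tips — hence all covariance structures —
equal sub-blocks of the full-tree matrices.  Multifurcations are handled by
the path-length definitions directly.

Structures, with t_ij = root-to-MRCA depth and d_ij = patristic distance:

* BM: C_ij = t_ij.
* OU (fixed-root variant): V_ij = σ²/(2α) · e^{−α d_ij} · (1 − e^{−2α t_ij}).
  Several OU variants circulate (fixed vs stationary root); the fixed-root
  form is implemented and exposed here so the choice is auditable.  `expm1`
  keeps the small-α limit accurate.  Non-ultrametric trees are accepted with
  a warning (t_ij is still the MRCA depth).
* Pagel's λ: off-diagonal entries of the BM structure multiplied by λ ∈ [0, 1].

All solves go through Cholesky; a failed factorization raises a diagnostic
error naming the structure — no silent jitter is ever added.

## PGLS and model selection

All four models are fit by maximum likelihood (not REML): the
likelihood-ratio tests between NP/BM and OU/λ require comparable full
likelihoods.  β and σ² have closed forms given the structure; σ̂²_ML = rᵀC⁻¹r/n
enters the likelihood, while reported SEs use the n−p denominator and
t-distributed p-values with n−p df.  AIC = 2k − 2ℓ with k = fixed effects
+ 1 (σ²) + 1 if α or λ is estimated.

OU's α is profiled on a log scale over [1e-8/height, 1e3/height] and λ over
[0, 1], each by a deterministic coarse grid (61 and 41 points) followed by
bounded scalar refinement — more robust than a few multistarts and exactly
reproducible.  The small-α floor makes BM numerically nested in the OU
search space (relative deviation O(1e-8)), which guarantees
ℓ_OU ≥ ℓ_BM − 1e-6 per fit; boundary MLEs are flagged.  λ's 95% CI is
profile-likelihood based (drop of χ²₁(0.95)/2 = 1.92), clipped to [0, 1]; a
profile flat to within the drop yields (0, 1) with a warning.

LRTs at a boundary (α → 0, λ at 0 or 1) use the plain χ²₁ tail without a
boundary-mixture correction; this is conservative for the λ-vs-NP test (the
type-I-error test asserts size in [0.02, 0.09] at nominal 0.05).

Degenerate perfect fits (σ̂² ≈ 0) are flagged and reported with infinite
log-likelihood rather than an arbitrary large number.

## Phylogenetic beta regression

Model: y_i | u_i ~ Beta(μ_i φ, (1−μ_i) φ), logit(μ_i) = x_iᵀβ + u_i,
u ~ MVN(0, σ²_p C̃).  C̃ is the BM structure scaled to unit diagonal (MRCA
depths / tree height), so σ²_p is a logit-scale variance — the scaling
common in phylogenetic random-effect practice.

Estimation is Laplace-approximate ML: an inner Fisher-scoring Newton (with
backtracking) finds the conditional mode û; the marginal likelihood uses the
observed negative Hessian at the mode.  The outer search is Nelder–Mead over
(β, log φ, s) with σ²_p = s², which makes the σ²_p = 0 boundary an interior
point of the search; at σ²_p = 0 the Laplace expression reduces *exactly* to
the plain beta log-likelihood (no approximation), and `fix_sigma2=0` fits
that plain model directly.  log φ is soft-bounded at 14: as φ → ∞ with the
random effect absorbing all dispersion the beta model degenerates to
logit-normal and the profile log-likelihood flattens into a ridge, so an
unbounded search can crawl indefinitely (and the all-responses-equal
degenerate case is genuinely unbounded in φ); the ceiling terminates both
at a finite, flagged value far above any realistic precision for proportion
data.  The outer search is also capped at 1600 function evaluations across
its two passes.  Wald SEs and z p-values come from a central
finite-difference observed-information matrix at the optimum (Table-style
outputs report Z); if flat nuisance directions (the φ ridge, a σ²_p
boundary) make that matrix singular, the β-block information at the fitted
nuisance values is used instead.  Fitted σ²_p below 1e-8 carries a boundary
flag.

Wald intervals from the Laplace fit are well calibrated for the slope
coefficients but slightly anti-conservative for the intercept when the
phylogenetic effect is strong — the deep shared component of u leaves
roughly one effective observation for the overall level, a generic
random-effect phenomenon rather than an approximation artifact.  The
recovery experiments therefore tally ±2·SE coverage per coefficient
(marginal ~95% intervals; measured ≈86–94% at the study conditions), not as
a joint all-coefficients event, whose nominal rate would be ≈87% even with
perfect calibration.

Boundary proportions are squeezed before fitting: 0 → 1e-4, 1 → 0.9999.
Exponentiated coefficients are black/non-black ratios; population-level
predictions use the inverse logit of the fixed-effect linear predictor
(random effect at 0).

**Residual diagnostics.**  `quantile_residuals` produces simulation-based
quantile residuals: each observation's randomized empirical quantile among
n_sim = 250 (default) draws from the fitted predictive distribution, with
the random effect integrated by sampling whole correlated u vectors; a
pooled Kolmogorov–Smirnov uniformity p-value is attached.  Caveat: with a
strong phylogenetic random effect the observed data share one correlated u
realization, which clusters the residual quantiles to one side; the
quantiles remain *marginally* uniform but the pooled KS test is
anti-conservative.  This is a generic property of unconditional
simulation-based residuals in mixed models, not specific to this
implementation; the test suite verifies nominal behaviour in the
independent regime and marginal uniformity in the correlated one.  Treat a
small KS p-value under a large σ̂²_p as a prompt for inspection, not proof
of misfit.

## Ancestral states

Joint-ML reconstruction under BM: the internal states minimize
Σ_edges (Δx)²/length with tips fixed, solved as one weighted-Laplacian
linear system.  (The common alternative interpolates marginal
reconstructions; the joint definition is adopted because it has a clean
optimality contract — every state is the inverse-branch-length weighted
average of its neighbours, all states obey the maximum principle, and the
map is affine-equivariant.)  Zero-length edges are rejected; whether to
jitter them is the caller's decision.  Branch values are linear
interpolations between endpoint states, 20 segments per edge by default in
exports (node-state CSV + annotated Newick with `[&state=...]` comments).

## Adequacy check

Traits are simulated from both fitted models (BM and OU, fitted parameter
values) as exact MVN draws, both models are refit per replicate, and
ΔAIC = AIC_BM − AIC_OU is recorded; 500 replicates by default (tests and
examples use 100 to keep runtimes modest — the statistic stabilises well
before that).  The result reports the observed ΔAIC's quantile within each
simulated distribution — a calibrated descriptive comparison; no formal
p-value is computed because none is well defined for this two-reference
design.  Failed refits are recorded as missing with a warning above 2%.
Identical seeds give bit-identical results.

## Synthetic-data generator

The generator defines the study conditions for all tests: a 50-tip
pure-birth ultrametric tree of height 0.21; log-uniform masses on
[90, 2000] g; wingspan ∝ mass^(1/3) (coefficient 140 mm·g^(−1/3), mild
clipped lognormal noise); H ∈ [0.30, 0.40]·wingspan and
S ∈ [0.35, 0.50]·H, which pins derived wing loading inside [0.001, 0.010]
g·mm⁻² with the bulk in 0.002–0.007; latitudes uniform on [−70, 70],
independent of the tree (latitude is a fixed covariate, not an evolving
trait).  Mantle KGS is drawn from the OU regression with β = (10.38, 1.22,
−0.07), α = 27.13 and σ² = 595.77 — so the stationary SD is ≈ 3.3 KGS and
simulated values rarely clip at the [0, 19] scale limits.  Wingtip
proportions come from the logit-beta model with β = (1.65, 0.34, −0.05),
φ = 30, σ²_p = 0.5, then pass through the observation process (values
beyond 1e-4 / 0.9999 are recorded as exact 0/1, as field scores would be).

The tree simulator appends one extra exponential waiting time to all tips
before rescaling (the upstream simulator stops exactly at the n-th
speciation, which would leave zero-length terminal branches).

Trait simulation is an exact Cholesky MVN draw of the model covariance —
identical in distribution to branch-wise recursion, with a simpler
contract.

What the generator does *not* emulate: real gull taxonomy and tree shape
(an empirical time-calibrated phylogeny is not a pure-birth tree), measurement error
in H/S/wingspan, correlated missingness, latitude–clade association, or
any mantle–wingtip residual dependence beyond their shared predictors.
Tests passing on synthetic data therefore validate the estimators and the
pipeline, not field conclusions about gulls; real species tables and trees
are accepted as drop-in CSV/Newick inputs for that purpose.

## Problem sizes and determinism

Recovery experiments run 200 replicates at the study's sample sizes
(n = 50 PGLS, n = 49 beta regression); the type-I-error experiment runs 500
replicates; adequacy examples run 100.  These sizes give Monte-Carlo
standard errors comfortably inside the asserted bands while keeping the
full suite in the minutes range.  Every stochastic component takes an
explicit seed; pipeline outputs are byte-identical under a fixed seed and
carry the package version and a config hash.

## Known limitations

* One trait, one optimum OU; no multi-optimum or measurement-error models,
  no AICc or model averaging.
* The beta model's Laplace approximation is accurate at these φ values but
  is still an approximation whenever σ²_p > 0; no adaptive quadrature.
* No uncertainty intervals on ancestral states; BM-based reconstruction
  only.
* Printed-table reproduction from real deposits depends on the original
  software's unstated conventions (OU root treatment, covariance scaling),
  so exact equality with published coefficient tables is a goal, not a
  guarantee.
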