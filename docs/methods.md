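# Methods

## Model

For gene *j*, cell line (or condition) *i* and time *t*, the expression
`y_ijt` is modelled on the observation scale (Gaussian family) or through a
log link (negative-binomial family) as

```
E[y_ijt]  (or log-mean)  =  α_ij + β_j x_ijt + Z(t) γ_j
```

* `α_ij` — per-line intercepts. They are confounders, not inference targets;
  each gets an independent Gaussian prior with gene-specific variance
  `100 × var(y_j)` (weakly informative, no information borrowing), so the
  estimates stay essentially unbiased.
* `β_j` — gene-dosage effect of the segmented copy number `x_ijt`. Prior:
  Dirac–Gaussian mixture `π₀ δ₀ + (1−π₀) N(0, τ²)` with `(π₀, τ²)` shared by
  all genes. A single slab variance is used for all aberration patterns.
* `γ_j` — coefficients of a low-rank thin-plate spline in time. Raw basis
  `|t − κ_k|³` at `K` equally spaced interior knots
  `κ_k = t_min + k (t_max − t_min)/(K+1)`; penalty matrix
  `Ω_{kl} = |κ_k − κ_l|³`. Multiplying the raw basis by `Ω^{-1/2}` (SVD-based
  inverse square root, relative singular-value cutoff 1e-10, dropped — not
  amplified — below it) makes the coefficients exchangeable iid
  `N(0, σ²_γ)`; the equivalence with the correlated-prior formulation is
  verified by a dense-algebra oracle test. `K = 1` would give a singular 1×1
  penalty; it is replaced by `[[1]]` so the single column is the raw profile.
* `ε_ijt ~ N(0, σ²_ε)` for the Gaussian family. For counts the observation
  model is negative binomial with per-gene size `r_j` (optionally
  zero-inflated with a fixed mixing weight), and there is no `σ²_ε`.

The precisions `1/σ²_γ` and `1/σ²_ε` carry conjugate Gamma(a, b) priors whose
parameters are shared across genes. Samples are ordered line-major (all
samples of line 1 by time, then line 2, …), the ordering the per-gene
likelihood assumes.

### Per-line splines and orthogonalization

A block-diagonal (Kronecker) expansion gives each line its own copy of the
spline (`n·K` random effects); comparing the per-line and common fits tests
for differences in temporal behaviour between lines. Because the spline and
copy number compete to explain expression, the spline design can be
projected onto the orthocomplement of `[line indicators, x_j]` (per gene)
so variation attributable to copy number is credited to `β_j`; the span of
the full design — and hence the saturated fit — is unchanged. When copy
number is absent the projection is against the line indicators only.

## Fitting

Per gene, posteriors are computed on a small grid over the variance
hyperparameters (a simplified INLA scheme):

1. A coarse log-spaced lattice over `(log σ²_γ, log σ²_ε)` (scaled by
   `var(y_j)`; 13×12 points) locates the joint mode of
   `evidence × hyperprior`.
2. A fine grid (default 7×7; 1-d for count fits, over `σ²_γ` only) is centred
   on the mode with spacing from the local curvature (±3 "posterior sd" per
   axis, sd clipped to [0.2, 2.5] in log units).
3. At each node the latent field `(α, β|slab, γ)` posterior is exact
   (Gaussian family, Woodbury-form conjugate algebra on the d×d information
   matrix) or a Laplace approximation at the damped-Newton mode (counts;
   convergence on step size 1e-9, hard cap 100 iterations, warm-started
   across nodes). Spike/slab configurations are separate components with
   their own evidences.
4. Reported posteriors are mixtures over (node, component) weighted by
   `prior-weight × evidence × hyperprior density`; the log marginal
   likelihood adds the grid cell area (trapezoid quadrature in the
   log-variance parameterization). Pinning `variances=(σ²_γ, σ²_ε)` gives a
   single-node conditional fit used by the oracle tests.

The linear predictor is clipped to |η| ≤ 30 in the count likelihood —
consistently in the likelihood, gradient and curvature — which bounds the
objective and keeps Newton stable for extreme counts.

An optional point mass on `σ²_γ = 0` ("Dirac–Gamma" hyperprior,
`gamma_spike_mass`) adds an exactly-flat-spline component, strictly
increasing temporal shrinkage.

### Count dispersions

`r_j` is estimated once by method of moments on residuals from a spline-free
Poisson fit of the fixed effects (line indicators plus the copy-number
covariate — omitting the covariate would count dosage signal as
overdispersion), with a residual-df correction, then held fixed. Because a
moments estimate from a dozen observations is extremely noisy, the per-gene
sizes are shrunk 50% in log space toward the across-gene median (moderated
tagwise dispersions). Estimates are clipped to [0.05, 1e6]; non-positive
excess variance maps to the Poisson-like upper end.

## Empirical Bayes

Shared hyperparameters maximize the product of per-gene marginal
likelihoods. The maximization alternates per-gene fits with:

* **Mixture update.** E-step inclusion probabilities from the spike/slab
  evidences at the current `(π₀, τ²)`; the inner weight problem is iterated
  to its fixed point (a single mean-rule step converges only geometrically
  near `π₀ = 1`). M-step: `τ²` maximizes the inclusion-weighted slab
  log-evidence by bounded 1-d search on `log τ²` over [1e-6, 1e3]; at a
  fixed hyperparameter grid the slab evidence is an exact closed form in
  `τ²` (Gaussian profile of β per node), so the search is cheap. The lower
  bound is raised to half the median likelihood variance of β̂: a slab
  narrower than the measurement noise is unidentifiable from the spike, and
  letting `τ²` collapse there freezes `π₀` at an arbitrary value.
* **Precision-prior updates.** Each Gamma prior is moment-matched to the
  across-gene distribution of posterior precision means
  (`shape = m²/v`, `rate = m/v`; floors shape ≥ 0.01, rate ≥ 1e-6, cap
  shape ≤ 1e4). The raw fixed-point iteration oscillates, so successive
  values are damped by 50% geometric interpolation.

Initialization: `π₀ = 0.5`, `τ² = 1`, Gamma(0.01, 0.01) on both precisions —
a very flat precision prior, i.e. splines start flat and gain flexibility
only if the data ask for it. Convergence: relative change of the summed log
marginal likelihood < 1e-4 (default cap 25 iterations). The objective is
monitored and decreases are logged; small non-monotonicities (≲0.3%
relative) near the fixed point are expected from the approximation and the
grid re-centring. If the loop stops at the iteration cap, one extra fitting
pass is made so the returned fits are consistent with the returned priors.

## Testing

LRT statistics are `2[ℓ(full) − ℓ(reduced)]`, with `ℓ` the data
log-likelihood at the posterior-mean parameters (each fit's own posterior
mean σ²_ε; NB likelihood at the fitted means for counts), clipped at zero —
shrinkage can make the ratio slightly negative. Dosage test: reduced model
drops the copy-number column, 1 df. Temporal test: reduced model drops the
spline, df = trace of the spline block of the smoother matrix (grid- and
component-averaged), floored at 0.5; the reduced model *retains* copy
number, so the test concerns the spline only. Line-difference test:
per-line vs common spline, df = difference of spline traces, floored at
0.5. Because the likelihoods are evaluated at shrunken estimates the tests
are conservative (confirmed by null calibration tests); the 50:50
chi-square boundary mixture for variance components is deliberately *not*
applied — plain chi-square with trace-based df is the prescribed procedure.
BH step-up FDR control by default, Benjamini–Yekutieli behind a flag; NaN
p-values pass through and do not count toward m.

## Spatial prior

Dosage effects along a chromosome follow `β_j = ρ β_{j−1} + e_j`. `ρ` is the
pooled OLS slope of consecutive pairs (per-chromosome centring, pairs never
straddle a boundary; clamped to ±0.99) computed from the univariate
posterior means — no iteration between `ρ` and the refits. Each interior
gene is then refitted jointly with its two neighbours under a trivariate
`N(0, τ² R)`, `R_ab = ρ^{|a−b|}`, keeping only the middle gene; chromosome
edges use the doublet analogue, chromosomes with fewer than three usable
genes keep univariate estimates. The joint refit conditions on each gene's
posterior-mean `σ²_ε` and `σ²_γ` and drops the spike inside the joint prior
(pure Gaussian AR(1) slab) — a fidelity approximation, as is the exclusion
of the count family from the refit. Significance of the dosage effect can
be re-evaluated at the refitted parameters; on AR(1)-simulated data the
refit raises the lag-1 correlation of the estimates while changing under 1%
of calls.

## Knot selection

Per gene, DIC = D̄ + p_D with D̄ the deviance averaged over 200 draws of the
latent field from its grid-mixture posterior (seeded per gene as
`seed + gene index`) and p_D = D̄ − D(posterior mean). NB deviance is
conditional on the fixed dispersion. One K is chosen for all genes: minimal
summed DIC over the candidate grid, ties toward the smaller K. Small
negative p_D from Monte-Carlo noise is tolerated (warned below −0.5).

## Synthetic data

The generator emulates the matched four-line × eight-time-point design and
the two-condition × six-time-point count design. Copy number is piecewise
constant along a synthetic genome: geometric segment lengths (mean 10
genes), per (segment, line) an aberration level appears at a uniformly drawn
change-point in time, levels AR(1)-correlated across adjacent segments
(ρ = 0.3); all genes in a segment share the signature, which is what gives
the spatial prior a true signal. Dosage effects are spike-and-slab
(default 10% nonzero, slab sd 1) or an explicit AR(1) series; temporal
curves come from the model's own K=2 basis (amplitude sd 1; out-of-family
sinusoids behind a flag), per line when requested; Gaussian noise sd 0.5 or
NB size 3 around a log-baseline N(4, 0.7²). What it does **not** emulate:
probe-level microarray noise, read-level sequencing, normalization
artefacts, missing data, unbalanced designs — passing tests show the
estimator works under the model's assumptions plus segment-structured CN,
not that preprocessing of real arrays is handled.

## Validation-study sizes and choices

The test suite establishes: exactness of the Gaussian path against dense
conjugate algebra (100 random instances, 1e-8); reparameterization and
orthogonalization identities; hyperparameter recovery (1000 genes, three
seeds); conservative null calibration and FDR control (2000 genes); BH
against a brute-force oracle; spatial-prior recovery and stability (ρ̂ at
p = 5000, refits at p = 400); knot recovery (10 replicates); count-path
coefficient recovery (200 genes, per-sample-varying covariate — with a
step-profile covariate the per-gene information is so low that zero-centred
shrinkage dominates any estimator property) and the Poisson limit at size
1e6; shrinkage benefit (EB vs least-squares MSE); and split-half
reproducibility with borrowing on vs off. These sizes keep each study to a
few minutes on one CPU while leaving Monte-Carlo margins well inside the
asserted bounds.

## Known limitations

* The hyperparameter grid is re-centred each EB iteration; the marginal
  likelihood surface is approximated, not nested-corrected, so EB objective
  monotonicity holds only approximately.
* `π₀`/`τ²` estimates are mildly attenuated when many genes carry weakly
  identified covariates (low within-line CN variance).
* The zero-inflation weight is fixed per fit (profile it externally over
  {0, 0.05, …, 0.5} by evidence if needed); it is not estimated jointly.
* Unmatched expression features are analysed with β ≡ 0 and flagged rather
  than dropped.
* The spatial refit conditions on univariate variance components instead of
  re-integrating them.
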