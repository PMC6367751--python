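# Methods

## Analytic theory

The data-generating model is Y = β₀ + β₁X₁ + β₂X₂ + ε with
(X₁, X₂) standard bivariate normal with correlation ρ, ε ~ N(0, σ²)
independent of the exposures, and no product term. Both exposures are
dichotomized at a common cut point c on the standard-normal scale
(unequal cuts are supported only through the numerical oracle). The
saturated model in the 0/1 indicators is exactly identified by the four
cell means, so the analysis never needs an explicit least-squares
derivation: β̃₀ = μ₀₀, β̃₁ = μ₁₀ − μ₀₀, β̃₂ = μ₀₁ − μ₀₀ and
β̃₃ = μ₁₁ − μ₀₁ − μ₁₀ + μ₀₀.

Cell means reduce to truncated bivariate-normal conditional means. The
upper quadrant uses the product identity
F₁₁E₁₁ = φ(c)[1 − Φ(a)](1+ρ) with a = (c − ρc)/√(1−ρ²); the side
quadrants follow from marginalization (F₁₀E₁₀ = φ(c) − F₁₁E₁₁ and
F₀₁E₀₁ = ρφ(c) − F₁₁E₁₁); the lower quadrant uses the cancellation-free
product F₀₀E₀₀ = −φ(c)Φ(a)(1+ρ), which is algebraically identical to
the subtraction route via E(X₁) = 0 but keeps full relative accuracy
when F₀₀ is tiny. Conditional means of X₂ come from the exchange
symmetry E(X₂ | quadrant ij) = E(X₁ | quadrant ji), valid for equal
cuts.

An equivalent explicit form of the interaction contrast,

β̃₃ = (β₁+β₂)(1+ρ)φ(c)[(1−Φ(a))/F₁₁ − Φ(a)/F₀₀ − (2Φ(a)−1)/F₀₁],

is implemented separately and used for root-finding; the two routes
agreeing to 1e−9 across the parameter grid is a standing regression
check. The zero set of β̃₃ is {c = 0} ∪ {ρ = 0} ∪ {β₁ = −β₂}; ρ = −1
also solves the equation but is excluded as degenerate.

## Numerical choices

- Orthant probabilities use the scipy bivariate-normal CDF (absolute
  accuracy ≈ 1e−15). Because that accuracy is absolute, any orthant
  below 1e−8 is recomputed by the 1-D reduction
  ∫ φ(x)Φ((c−ρx)/√(1−ρ²))dx with relative tolerance 1e−12, which is
  relatively accurate for arbitrarily small masses.
- Quadrant probabilities below 1e−12 raise an underflow error rather
  than return noise: conditional means divide by them. With this guard
  the closed forms agree with the quadrature oracle to 1e−6 everywhere
  tested (|ρ| ≤ 0.9, |c| ≤ 2).
- The independent oracle integrates the bivariate density (and x₁ times
  it) over each quadrant with adaptive 2-D quadrature (`dblquad`,
  absolute tolerance 1e−10, bounds ±9 ≈ ∞ on the standard-normal
  scale); it also serves unequal cut points.
- Root-finding for the zero-interaction condition scans a 400-point cut
  grid for sign changes and polishes each bracket with Brent's method to
  1e−8. If |β̃₃| < 1e−10 over the whole scan the function is flagged
  identically zero (ρ = 0 or β₁ = −β₂) instead of reporting every grid
  point as a root.
- ρ = ±1 is rejected at construction; (c − ρc)/√(1−ρ²) is well defined
  for every |ρ| < 1, so ρ = 0 and c = 0 take no special code path.

## Simulation study

The engine reproduces a 3 × 3 × 2 design — marginal family
{normal, uniform[0,1], χ²(2)} × target correlation {0.2, 0.5, 0.7} ×
cut percentile {60th, 80th} — plus two modified-slope scenarios
(β₁ = 1, β₂ = 0 and β₁ = β₂ = 2, both at ρ = 0.7, 80th percentile), in
all three families: 24 cells. Defaults are 1000 replicates of
n = 10,000, the scale at which the reference coefficient tables are
quoted; the whole design runs in well under a minute on one CPU.

Design constants:

- β₀ = 0, β₁ = β₂ = 1 in the base design.
- σ² is set once per marginal family so that corr(Y, Xᵢ) = 0.3 at
  ρ = 0.5 and β = 1, giving σ² = 22 (normal), 22/12 (uniform), 88
  (χ²(2)); it is *not* re-calibrated when ρ or the slopes change, so
  coefficient means — which do not involve σ² — stay comparable across
  cells.
- Exposures are dichotomized at **theoretical** marginal quantiles
  (Φ⁻¹(p); p; −2ln(1−p)), not per-sample empirical percentiles. This
  keeps the estimand identical across replicates; at n = 10,000 the
  difference from empirical cuts is far below the Monte-Carlo noise.

### Gaussian copula and calibration

Correlated non-normal pairs come from a Gaussian copula: latent
(Z₁, Z₂) with correlation ρ_latent, uniforms via Φ, and χ²(2) as
X = −2ln(V). Monotone transforms attenuate Pearson correlation, so
ρ_latent is calibrated to hit the target on the observed scale:
exactly for normal marginals (identity), in closed form for uniform
(latent = 2 sin(πρ/6), inverting ρ = (6/π)arcsin(latent/2)), and by
Brent root-finding of the sample correlation on a fixed
common-random-numbers sample of 10⁶ pairs for χ²(2), to tolerance
0.002. The calibration uses a fixed internal seed: the latent
correlation is a design constant shared by all cells and runs, while
the scenario seed drives replicate streams. Each replicate draws from
an independent child stream (`SeedSequence([seed, replicate, attempt])`),
so any cell is reproducible in isolation and identical scenarios give
bit-identical results.

A replicate whose 2×2 indicator table has an empty cell is retried on a
fresh sub-stream and counted; more than 1% failures aborts the cell. At
the default n the smallest cell probability in the design (normal,
ρ = 0.7, 80th percentile) is ≈ 0.11, so retries essentially never
occur; the path matters only for user-supplied small-n scenarios.

### Scenario options beyond double dichotomization

Two scenario switches demonstrate that the artefact does not require
categorizing both variables into two groups: `dichotomize_x2=False`
keeps X₂ continuous in the fitted model (the product term remains
clearly non-null), and `n_categories=k` splits both exposures at
equal-probability quantiles with a full dummy-by-dummy interaction
block. Both are demonstrations by simulation only; no analytic forms
are provided for them.

## Reliability diagnostics

For a normal exposure the point-biserial reliability of the indicator
is φ(c)/√(Φ(c)(1−Φ(c))), maximal at the median cut. Stratified
reliabilities (within X̃₂ = 0 and X̃₂ = 1) always use the empirical
Pearson estimator, even under normality: within a stratum of X̃₂ the
distribution of X₁ is no longer normal, so the marginal closed form
does not apply. The diagnostics reproduce the sign logic of the induced
interaction: for normal and uniform marginals reliability is worse in
the *lower* stratum of the partner variable (negative induced
interaction), for the right-skewed χ²(2) it is worse in the *upper*
stratum (positive induced interaction), and the cut percentile with
more measurement error (80th for normal/uniform, 60th for χ²(2)) is the
one with the stronger induced interaction.

## Collapsing categorical exposures

The contingency-table module is deterministic arithmetic: risks are
exact integer-count ratios, RRs are computed per stratum against the
lowest-labelled reference category, and rounding happens only at
display (two decimals). The homogeneity check flags any non-reference
category whose max/min RR ratio across strata exceeds 1 + 1e−9, i.e.
any inhomogeneity beyond floating noise; no significance test is
attached because the demonstration is about the point values, not
sampling error. The bundled fixture is the two-stratum, four-category
table with RRs 1:2:3:4 in both strata whose {1,2}/{3,4} merge yields
stratum RRs 7/3 and 15/7.

## What the generator does and does not emulate

The synthetic exposures emulate the three stated marginal families with
exactly the stated observed correlations and a homoskedastic normal
residual. Real exposure data differ in ways that are deliberately out
of scope: measurement error in the continuous originals, non-linear
exposure–outcome relationships, heteroskedastic or non-normal
residuals, more than two exposures, and non-linear link functions
(logistic-scale behaviour is qualitatively similar but is not treated
analytically here). Passing tests therefore certify the categorization
artefact under the stated sampling model, not the magnitude of the
artefact in any particular real data set.

## Known limitations

- Closed forms require equal cut points and standard-normal marginals;
  everything else is simulation or the quadrature oracle.
- The underflow guard means cut points beyond |c| ≈ 7 (or extreme |ρ|
  combined with |c| ≈ 2 in the opposing tail) raise rather than
  degrade silently.
- Relative-risk homogeneity is assessed on point values only.
- The k-category and one-sided scenarios report full coefficient
  vectors; no attempt is made to summarize them into a single
  interaction magnitude.
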