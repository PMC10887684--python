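# Methods

## The quantity

For a positive random variable X with density f, the weighted extropy is

    Jw(X) = -1/2 ∫₀^∞ x f(x)² dx.

It is non-positive, dimensionless, and — unlike the unweighted extropy
J(X) = -1/2 ∫ f² — shift-dependent: large outcomes carry more weight.
It is also *scale-invariant*: substituting x = cu shows Jw(cX) = Jw(X).
Two consequences matter in practice. First, the exponential family has a
single value, Jw = -1/8, for every rate, which makes it a convenient
calibration point. Second, ranking systems by Jw compares the *shapes* of
their lifetime distributions, not their time scales; systems that differ
only by a change of units are equally ranked.

Closed forms used by the catalogue (each verified against quadrature in
the tests): exponential -1/8; lognormal(μ, σ) -1/(4σ√π) (free of μ);
uniform(0,1) -1/4; the density 2x on (0,1) -1/2; Rayleigh(1) -1/4.

## Estimators

Let X₁,…,Xₙ be the sample and K the Gaussian kernel (density, zero mean,
unit second moment, roughness C_k = ∫K² = 1/(2√π)).

1. **Log-kernel (L-KDE) estimator.** The log kernel
   L(x, z, h) = K((log x - log z)/h)/(xh) is an ordinary kernel placed in
   log space; for every z, h > 0 it is itself a density on (0,∞). The
   density estimate f̂_log(x) = (1/n) Σ L(x, Xᵢ, h) is plugged into the
   integral: Ĵ = -1/2 ∫ x f̂_log(x)² dx. Because the smoothing happens on
   the log scale, the estimator keeps all mass on (0,∞) and compresses
   heavy right tails. Its leading pointwise bias is
   (h²/2)[f + 3xf' + x²f''] and its variance (C_k/nh) f(x)/x.

2. **Ordinary kernel (KDE) estimator.** Ĵ = -1/2 ∫₀^∞ x f̂(x)² dx with
   the plain Rosenblatt–Parzen f̂. No boundary correction or truncation
   is applied; the integral simply starts at zero. Near a support
   endpoint the KDE spills mass outside, so this estimator carries a
   boundary bias on compactly supported distributions (visible in the
   uniform results, and discussed under Limitations).

3. **Empirical spacing estimator.** Integrating x f̂² piecewise between
   consecutive order statistics and freezing f̂ at the lower endpoint of
   each spacing gives
   Ĵ = -1/4 Σ_{i=1}^{n-1} (X²_{i+1:n} - X²_{i:n}) f̂²(X_{i:n}),
   a left-endpoint Riemann sum of the same integral. The half-spacings
   of the squared order statistics, Z = (X²_{i+1:n} - X²_{i:n})/2, have
   tractable laws for two catalogue families — beta (mean 1/(2(n+1)))
   when X² is uniform, exponential (mean 1/(2(n-i))) when X² is
   exponential — which yields sample-conditional mean/variance formulas
   that the moment engine can average as an alternative reading
   (`moment_mode="formula"`).

4. **Parametric plug-in.** Exponential or lognormal maximum likelihood,
   then the closed form at the fitted parameters. The exponential value
   is -1/8 regardless of the fitted rate; the lognormal value depends
   only on σ̂, the ML standard deviation of the log data.

All three non-parametric estimators are exactly scale-equivariant once
the bandwidth is selected by a scale-equivariant rule (ours are), so
their sampling distribution does not depend on the unit of time.

## Bandwidth selection

- **Data-driven (default):** the Sheather–Jones solve-the-equation
  plug-in. The pairwise Gaussian-derivative functionals use pilot
  bandwidths a = 1.24 λ n^{-1/7} and b = 1.23 λ n^{-1/9} with
  λ = min(sd, IQR/1.349), include the diagonal terms, and the fixed-point
  equation h = [C_k/(n Ŝ(α₂(h)))]^{1/5} with
  α₂(h) = 1.357 (Ŝ(a)/T̂(b))^{1/7} h^{5/7} is solved by Brent's method
  (bracket centred on the Silverman reference value, expanded when
  needed; h resolved to six significant digits). When the number of
  pairs exceeds 10⁴, pairwise distances are binned into 1000 counts,
  which changes h at the 0.1% level and makes the selector O(n log n).
  For the L-KDE the rule is applied to the log-transformed sample, since
  the log kernel is an ordinary kernel in log space.
- **Theoretical:** for a known distribution, minimising the asymptotic
  risk AMISE(h) = (h⁴/4)A + B/(nh) with
  A = (∬_{x>y} [f + 3xf' + x²f'']f)² and B = C_k ∬_{x>y} f³/x gives
  h_opt = (B/(An))^{1/5}, the usual n^{-1/5} rate. For Exp(1) at n = 100
  this evaluates to h_opt ≈ 0.570.

## Numerical choices

- Estimator integrals use composite Simpson on a 1024-point grid —
  geometric spacing for the L-KDE (natural in log space, resolves heavy
  right tails), linear for the KDE — refined fourfold until the value
  moves by less than 1e-6 (at most three refinements). Integration
  ranges extend 8 bandwidths beyond the extreme observations (log
  bandwidths for the L-KDE); the kernel mass beyond is below 1e-10.
- The Fubini form of the L-KDE estimator,
  -1/2 ∫₀^∞ dy ∫_y^∞ f̂_log², is implemented as an independent code path
  (cumulative trapezoid of f̂² on a 2¹⁶-point linear grid) and asserted
  equal to the direct form to 1e-6.
- True-value and theory functionals use adaptive quadrature (relative
  tolerance 1e-8), truncating infinite supports at the 1 - 1e-9
  quantile, with quantile breakpoints passed to the integrator so that
  concentrated mass on very wide ranges is not overlooked. The wedge
  double integrals are nested adaptive quadratures; a result whose error
  estimate exceeds 1e-4 of the value raises a numerics error.
- Catalogue densities ship analytic first and second derivatives (the
  bias functional needs them); the uniform and 2x densities use their
  interior derivatives and are not differentiable at the support
  endpoints, so theory functionals for them should be read as formal.
- Degenerate inputs: constant samples have no plug-in bandwidth
  (estimation error); samples with non-positive values are rejected at
  construction; a tied sample makes the spacing estimator exactly zero.

## Monte Carlo engine

Replication uses `numpy.random.SeedSequence` spawning: one master seed
spawns a child per sample size and grandchildren per replicate, so
tables are bit-for-bit reproducible and all estimators in a run are
evaluated on identical samples (paired comparison). The bandwidth is
re-selected on every replicate, as it would be in practice. Replicates
on which an estimator fails are redrawn from fresh streams, counted, and
capped at 1% of the requested replications. Every emitted row satisfies
RMSE ≥ |bias| by construction of the summaries; the engine treats a
violation as an internal error. The default replication count is 1000,
which puts the Monte Carlo standard error of a table mean near 2e-4 for
the smooth estimators — an order of magnitude below the differences the
tables are meant to show. Samplers for the 2x and Rayleigh families use
the inverse transforms X = √U and X = √(-2 log U); the squares of such
draws are uniform and exponential respectively, which the tests check
distributionally.

## What the synthetic conditions do and do not show

The five sampling distributions cover a skewed unbounded case
(exponential), a heavy-tailed case (lognormal), two compactly supported
cases (uniform, 2x) and a light-tailed transformable case (Rayleigh).
They are all smooth, uncensored, independent draws. Passing tests under
these conditions say nothing about censored data, dependent observations
(repairable-system failure times are often a point process, not an iid
sample), measurement rounding, or densities with interior modes at 0.
The reliability ranking workflow inherits the scale-invariance of Jw:
it distinguishes shape, not scale, of competing lifetime distributions.

## Known limitations

- **Boundary bias.** The plain KDE underestimates a density near a
  support endpoint by up to half its value. For the uniform
  distribution this keeps the kernel-based estimates of Jw above the
  true -0.25 by ~0.02 at n = 500 (the L-KDE mean is ≈ -0.227). For the
  2x density, whose mass peaks exactly at the endpoint, the effect on
  the spacing estimator is larger: its Monte Carlo mean at n = 500 is
  ≈ -0.45 against a true value of -0.5, and neither the raw-moment nor
  the formula-moment reading removes the gap. Boundary-corrected kernels
  would; they are deliberately out of scope because the estimators are
  defined with the uncorrected forms.
- **Pre-asymptotic bandwidth rates.** The SJ plug-in approaches its
  n^{-1/5} rate slowly on skewed data; between n = 100 and n = 1600 on
  exponential samples the realised ratio corresponds to a faster decay
  (R's bw.SJ behaves identically).
- The parametric route supports the exponential and lognormal families
  only; other families raise an unsupported-family error rather than
  silently falling back to quadrature of a fitted density.
- The leading-term bias/variance expressions are asymptotic; at nh ≈ 500
  the omitted centering term of the variance is still a double-digit
  percentage of the leading term (the tests account for it explicitly).
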