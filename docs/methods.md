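# Methods

## Model and coordinates

Progression of an embryo through a developmental interval is treated as a
pseudo-reaction with rate k = 1/duration (min⁻¹). In Arrhenius coordinates
x = 1/T (T in Kelvin, obtained by adding exactly 273.15 to the measured
Celsius temperature) and y = ln k, the Arrhenius equation
k = A·exp(−Ea/(R T)) is the line y = lnA − (Ea·1000/R)·x, with
R = 8.314 J·mol⁻¹·K⁻¹ held as a package constant, Ea stored in kJ/mol and
A in min⁻¹. The apparent activation energy of a composite process is an
effective quantity: −R/1000 times the fitted slope, not an elementary
barrier.

All downstream fits consume one point per embryo-interval observation at
its measured temperature (no binning; nominal-temperature grouping exists
only for display summaries and the CV analysis). Per-temperature means and
standard errors of ln k are computed replicate-first (log before mean).

## Interval extraction and score selection

Timing tables are long-format CSV (embryo, organism, measured temperature,
score code, absolute time in minutes). Interval durations are differences
of two scored times within one embryo; embryos lacking either score are
skipped and counted, and non-positive durations are treated as scoring
errors and excluded with a diagnostic, never clamped. Re-zeroing at an
origin score subtracts that score's time, so earlier events become
negative; it changes no interval.

The reproducibility screen computes, for each ordered score pair, the
coefficient of variation of replicate durations at each temperature
(sample standard deviation, n−1 denominator — replicate counts are small)
and averages the per-temperature CVs without weighting. Temperatures with
a single replicate are skipped rather than scored as zero CV: a singleton
carries no reproducibility information, and counting it as perfect would
bias selection toward sparsely sampled events. Selection then drops, one
at a time, the score whose adjacent-interval mean CV (against its current
neighbours) is largest, ties broken in favour of the developmentally
earlier score, until k scores remain; the procedure is deterministic.

## Regression, confidence intervals, model selection

Linear fits are ordinary least squares of y on x restricted to a closed
core temperature range (defaults: 14.3–27 °C fly, 12.2–25.7 °C frog, where
the Arrhenius plot is treated as linear; the viable regimes 14.3–30.1 °C
and 12.2–28.5 °C are available as a configuration switch). The 68%
confidence half-width on Ea uses the Student-t quantile at the residual
degrees of freedom (t ≈ 1 SE for large n); two points determine the line
exactly and get no CI. Quadratic fits (ln k = c₂x² + c₁x + c₀) use all
temperatures by default and at least four points; x is centred and scaled
internally for conditioning and the coefficients mapped back.

Model selection uses the Gaussian BIC with the variance profiled out,
BIC = n·ln(RSS/n) + k·ln n, k = 2 (line) or 3 (parabola), reported as the
log penalized-likelihood ratio Λ = (BIC_lin − BIC_quad)/2; Λ > 0 prefers
the quadratic. Degenerate residuals follow limiting rules: when both
models interpolate (RSS at the numerical noise floor, n·(10⁻¹²·scale)²),
the penalty decides and Λ = −ln(n)/2 exactly; when only the quadratic
interpolates, Λ is capped at a sentinel of 10⁶.

Slope equality between two intervals is an ANCOVA F-test of the group×x
interaction (full model: separate slopes and intercepts; reduced: common
slope), df = (1, n−4), computed in closed form and cross-checked against
statsmodels in the test suite. Post-hoc power is the noncentral-F tail
beyond the α = 0.05 critical value with noncentrality λ = F_observed·df₁,
the standard observed-power convention; it is declared as such because it
is a function of the observed statistic. The all-pairs pipeline reports
raw pairwise p-values and, as a clearly labelled extension, a
Holm-adjusted column.

## Sequential reaction networks

A chain of n irreversible Arrhenius steps has relaxation time
τ(T) = Σᵢ exp(+Eaᵢ·1000/(R T))/Aᵢ — the sum of per-step times 1/kᵢ (the
positive exponent is required for τᵢ = 1/kᵢ; the composite rate is
ln k = −ln τ). All sums are evaluated with log-sum-exp, so chains whose
per-step times overflow doubles remain finite. Writing bᵢ = Eaᵢ·1000/R and
time-fraction weights wᵢ = τᵢ/τ, the curve y(x) = −ln Σ exp(bᵢx − ln Aᵢ)
has y′ = −⟨b⟩_w and y″ = −Var_w(b) ≤ 0: a sequential chain is always
concave down in Arrhenius coordinates, and exactly linear only when all
steps share one Ea, in which case the chain collapses exactly to a single
reaction with A_eff = (Σ 1/Aᵢ)⁻¹. The weighted variance is computed in
two-pass form (Σ wᵢ(bᵢ−⟨b⟩)²); the E[b²]−E[b]² form loses all significant
digits when one step dominates the chain, and the derivative identities
are validated in the tests against 60-digit symbolic differentiation.

Composite predictions chain empirical sub-interval fits: each fitted
(Ea, lnA) becomes one reaction, and the prediction's tangent Ea is
−R/1000 times the least-squares slope of the composite curve over the
core range (tangent Ea is invariant to the rate units; the curve itself is
computed in min⁻¹ throughout). Non-contiguous sub-intervals warn but
compute. Expanding a reaction into m identical steps subtracts
R·T_ref·ln(m)/1000 from its Ea (natural log — required for the exact
collapse identity) while keeping A, so the m-chain reproduces the original
time exactly at T_ref and only there.

## Random networks and the worst-case curvature search

Random feasible chains draw Ea uniformly from 20–100 kJ/mol (literature
range of enzyme activation energies) and per-step times 1/k at the
reference temperature 295.15 K log-uniformly from 1 s to 3 days (a
biologically implausibly short state at one end, the whole duration of
fly embryogenesis at the other), back-solving each prefactor. The time
bound is interpreted as applying to 1/kᵢ evaluated at the target
temperature; this choice is normative for the optimization. A 1,000-step
random chain is nearly perfectly linear over 14–28 °C (residual standard
deviation of ln k about its fitted line < 0.01).

The worst case maximizes the standard curvature
κ = |y″|/(1+y′²)^{3/2} of y = ln k vs x = 1/T at 295.15 K — curvature is
not invariant to axis rescaling, so these axes (K⁻¹, natural log) are
normative — over 2-reaction chains parameterized as (Ea₁, Ea₂, ln t₁,
ln t₂), with 64 seeded uniform multi-starts of bounded L-BFGS-B. The
optimizer works on log-curvature, which spans orders of magnitude across
the feasible box and would otherwise stall the quasi-Newton line search;
constraint satisfaction at the returned optimum is re-verified
independently of the optimizer. The optimum is then expanded to a
1,000-reaction equivalent by splitting the lower-Ea reaction into 999
identical steps.

Under these constraints the curvature maximum sits on the boundary of the
feasible box: the lower activation energy runs to the 20 kJ/mol bound and
the higher to 100 kJ/mol, with the slow, low-Ea step holding ~90% of the
relaxation time (κ ≈ 2.2×10⁻⁴ at 295.15 K, reproducible across seeds).
Intuitively, κ ≈ Var_w(b)/|⟨b⟩_w|³ at these slopes, so widening the Ea gap
helps the numerator while weighting the low-Ea step shrinks the
denominator; both press against the bounds. Even this boundary worst case
deviates from its tangent line by far less over the core range than a
concave quadratic of the magnitude seen in embryonic data — the package's
quantitative form of the conclusion that sequential coupling alone cannot
produce the observed non-linearity.

## Synthetic data generator

The generator emulates the statistical structure of staged-timing
experiments, not their biology: per adjacent interval a true temperature
law (Arrhenius, optionally with a concave quadratic term in x), replicate
noise as a unit-mean multiplicative lognormal with chosen CV (keeps
durations positive and CV scale-free; an additive Gaussian would not),
optional clutch factors shared by all embryos at a temperature
(frog-style shared mothers; off by default for fly-style designs),
optional measured-temperature jitter, and viability-window truncation that
withholds scores beyond a cutoff ordinal at extreme temperatures.
Defaults are 8 temperatures spanning ~10–33 °C with 5 replicates each and
5% duration CV, matching the replication scale of the timing experiments.
Absolute times are cumulative sums from the origin score, so generated
timelines satisfy the monotonicity invariant by construction, and every
draw is reproducible from the design seed.

What passing tests on this generator show: the pipeline recovers known
parameters at realistic noise and sample sizes, the 68% CI covers the
truth at its nominal rate (0.68 ± 0.06 over 500 studies), and the slope
test holds its size (type-I error 0.05 ± 0.02 over 2,000 equal-slope
replicates). What they do not show: robustness to features of real data
the generator omits — scorer drift, non-lognormal outliers, temperature
drift within a time-lapse, correlated errors between overlapping
intervals of one embryo, and death mechanisms beyond score truncation.

## Numerical choices and limitations

* Temperatures convert to Kelvin by adding exactly 273.15; zero-variance
  abscissae, rank-deficient designs and singular ANCOVA designs raise
  errors rather than returning NaN.
* Score-selection ties break by developmental ordinal; BIC ties (Λ = 0)
  count as linear preference.
* Test problem sizes (500-study coverage runs, 2,000-replicate
  calibrations, 1,000-network concavity sweeps, 10,000 Monte-Carlo
  curvature competitors) were chosen so the full suite completes in well
  under a minute while keeping binomial noise far below the asserted
  margins.
* Only strictly sequential irreversible chains are modelled; branched or
  parallel topologies and reversible steps are out of scope, as are
  Arrhenius variants with explicit heat-capacity terms. A chain of
  Arrhenius steps can never produce rates that *decrease* with
  temperature, so the high-temperature downturn seen in enzyme assays and
  embryonic data is outside this model class by construction.
* The worst-case search optimizes 2 distinct-parameter reactions and
  expands the optimum; optimizing 1,000 free reactions directly is not
  attempted (the collapse identity makes the 2-reaction family the
  effective parameterization of one-slow-block-plus-one-fast-block
  chains).
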