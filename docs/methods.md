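# Methods

## Model and procedure

The package treats a family of S p-values as a sample whose distribution
carries information about how many null hypotheses are false. Under the
complete null the p-values are i.i.d. Uniform(0, 1), so the ECDF value
K_γ = #{pᵢ ≤ γ}/S has expectation γ. A surplus of small p-values shows up
as K_γ > γ, and a single goodness-of-fit test on the count S·K_γ — the
*metatest* — decides whether any surplus is real.

**SGoF** runs the metatest at a fixed γ (= α by default). **SGoF+** first
maximizes K_γ − γ over the distinct observed p-values; this discriminant
threshold γ₀ is the Youden-index point of the ECDF against the uniform,
i.e. the rejection region with maximal separation between observed and
expected rejection rates. Because the maximized distance is exactly the
one-sided Kolmogorov–Smirnov statistic D⁺ = sup_t (F̂(t) − t), comparing
it with the level-α one-sided KS critical value before running the
metatest restores weak FWER control: under the complete null,
P(D⁺ ≥ ks_α) = α, and a discovery additionally requires the binomial
metatest to reject, so the probability of any false declaration is ≤ α.

On rejection the *excess of significants* S·K_γ₀ − b_α(γ₀) + 1 smallest
p-values are declared, capped at S·K_α so that no p-value above α is ever
a discovery. The declared count is read as a lower bound on the number of
true effects among the tests below γ₀, not as a per-test significance
statement; the per-test uncertainty is delegated to the q-values.

## Key conventions and numerical choices

- **Counting convention.** K_γ uses the closed inequality #{pᵢ ≤ γ}/S.
  The ECDF only jumps at observed values, so with this convention the
  supremum of K_γ − γ is attained on the candidate set (the distinct
  observed p-values) and the argmax is well defined. Ties break toward
  the smallest maximizing γ (the more conservative region).
- **Degenerate thresholds.** γ candidates 0 and 1 are excluded (the
  binomial metatest is undefined there). A family consisting entirely of
  0s and 1s yields zero discoveries with a logged warning.
- **Critical count b_α(γ₀).** Default is the verbatim percentile rule:
  the smallest k with P(Binomial(S, γ₀) ≤ k) ≥ 1 − α. For a discrete
  distribution the achieved level of "reject when count ≥ b" can slightly
  exceed α; a strictly conservative rule (smallest k with
  P(X ≥ k) ≤ α, always the percentile + 1) sits behind
  `conservative=True`.
- **Binomial vs chi-squared.** `gof="auto"` uses the exact binomial test
  for S < 10 and the one-sided χ²₁ two-cell test for S ≥ 10, expressed as
  the equivalent count threshold ⌈Sγ₀ + z₁₋α·√(Sγ₀(1−γ₀))⌉ (the χ² form
  is applied only in the direction observed > expected, hence z₁₋α, not
  z₁₋α/₂). Either test can be forced.
- **KS critical value.** Exact (the one-sided KS sampling distribution)
  for S ≤ 1,000, the asymptotic √(ln(1/α)/(2S)) beyond — exact at desk
  scale, cheap at screen scale; the two differ by < 0.002 already at
  S = 1,000.
- **Ties at the discovery boundary** are resolved by stable input order:
  the N smallest p-values with earlier input positions win. All metatest
  operations are deterministic.

## π₀ estimation

All four estimators exploit the fact that p-values above a point λ are
(almost) purely null, via the raw curve π̂₀(λ) = #{pᵢ > λ}/(S(1−λ)),
which is deliberately left unclipped; final estimates are clipped to
[0, 1].

1. **Smoothing**: a natural cubic regression spline through
   (λ_r, π̂₀(λ_r)) on the default grid λ_r = 0, 0.05, …, 0.95, evaluated
   at λ = 1 (linear extrapolation beyond the boundary knot, a property of
   natural splines). Default flexibility df = 3 (knots at grid
   quantiles); `df="gcv"` picks df ∈ {3,…,6} by generalized
   cross-validation. The basis is the truncated-power natural-spline
   construction fit by least squares — no installed library exposes an
   R-style df-parameterized natural spline, so the ~20-line basis is
   built here.
2. **Bootstrap**: λ chosen to minimize the bootstrap MSE of π̂₀(λ)
   around the plug-in minimum min_λ′ π̂₀(λ′); default 100 resamples,
   reproducible under a seed; MSE ties break to the smallest λ.
3. **LBE**: (1/(S·m!))·Σ(−ln(1−pᵢ))^m with the moment order m a step
   function of S (m = 1 for S < 2000, 2 for S < 7500, else 3 — the
   breakpoints implied by the variance bound 0.05²). Under uniformity
   E[(−ln(1−P))^m] = m!, so the estimator is centered at 1 on the
   complete null. p-values equal to 1 are clamped at 1 − 10⁻⁸ (the log
   diverges) with a warning.
4. **SDPB**: the bounding-function estimate of the fraction L of false
   nulls, L̂ = sup_t (F̂(t) − t − β_{S,α}√(t(1−t)))/(1−t) clipped at 0,
   with π₀ = 1 − L̂. The bounding sequence β_{S,α} is calibrated by Monte
   Carlo under the complete null (2,000 uniform replicates of size S,
   fixed internal seed, (1−α) quantile of the normalized KS-type
   supremum), cached per (S, α); the asymptotic rate √(2 ln ln S/S) is
   available as a fast alternative. The supremum is evaluated at the
   observed p-values plus the default λ grid — F̂ is a step function, so
   this candidate set suffices. Finite-sample calibration makes the
   estimator conservative by construction: on the complete null L̂ = 0
   with probability ≥ 1 − α.

Multiple estimates are aggregated by the **modal interval**: half-open
bins [kw, (k+1)w) of width w = 0.05 anchored at 0; the most populated
bin's members are averaged; ties between bins go to the bin with the
larger values (higher π₀ → more conservative downstream FDR estimates).

## pFDR, q-values, baselines

epFDR(p) = min(1, π₀·S·p/(R(p)·C)) with R(p) = #{pᵢ ≤ p} and
C = 1 − (1−p)^S (robust; C estimates the probability of at least one
rejection, the event pFDR conditions on) or C = 1 (standard). Thresholds
are evaluated at observed p-values only — R changes nowhere else — and a
threshold rejecting nothing raises rather than returning 0, honouring the
conditional definition. q-values are the running minimum of epFDR from
the largest threshold down; estimates are clipped at 1 (rates above 1 are
uninformative). The robust variant is the right default when sample sizes
are small and effects weak, which is precisely the regime the metatests
target.

BH (step-up, FDR α) and Holm (step-down, strong FWER α) adjusted
p-values are computed by statsmodels behind the package's interface;
brute-force step-up/step-down oracles in the test suite pin the
behaviour.

## Simulation design

`simulate` reproduces the mixture design used in all experiments: each of
S tests draws n deviates from N(0, 1) (null) or N(x, 1) (effect), with
x = 0.36 by default — calibrated so that a single test at the 5% level
has power about 0.10 asymptotically; at n = 5/10/20/100 the exact
noncentral-t powers are 0.10/0.18/0.33/0.95. The two-tailed one-sample
t-test p-value is computed through the regularized incomplete beta
identity p = I_{df/(df+t²)}(df/2, ½). The variance is estimated, not
assumed known (the usual t-test), even though the generating variance
is 1. Effect counts are fixed at round(S·fraction) per family —
deterministic composition, matching the fixed-percentage design — and
effect positions are the leading indices (no adjustment method sees the
order, only the values). Randomness follows a counter-based protocol:
replicate r of a scenario with root seed s uses the generator keyed by
(s, r), so replicates are independent and individually reproducible.

What the generator does **not** emulate: dependence between tests
(block-correlated genes/proteins), non-normal or heteroscedastic data,
composite or one-sided alternatives, and discreteness of p-values from
rank tests. Passing tests therefore certify the methods' behaviour under
independent, continuously distributed test statistics; on strongly
correlated data the weak FWER guarantee of SGoF+ can fail, and a more
conservative baseline (BH) is the prudent companion.

## Evaluation metrics and problem sizes

Per replicate, rejection sets are scored against truth labels; across
replicates: power = mean TP/(TP+FN); FPR = mean FP/(FP+TN);
pFDR = mean FP/(TP+FP) **only over replicates with ≥ 1 discovery**
(reported as missing, never 0, when no replicate discovers); FWER =
fraction of replicates with ≥ 1 false discovery; the power/pFDR ratio;
and the estimation bias mean(epFDR) − pFDR (positive = conservative).
Monte-Carlo standard errors accompany every aggregate.

The default test-suite problem sizes are chosen to make every check
sharp yet quick on a single core: 1,000 replicates of S = 1,000 for the
weak-FWER check; 10⁵ pooled tests per sample size for the power-grid
cross-check; 200 replicates of S = 1,000, n = 20 at effect fractions
5/20/80% for the trend checks (power ordering, pFDR decreasing in the
effect fraction, |epFDR − pFDR| ≤ 0.05 for the metatests). Exact
replication of published power/pFDR curves is out of scope; the trend
checks are property-level.

## Known limitations

- Weak (complete-null) FWER control only; SGoF+ makes no strong FWER or
  FDR guarantee — the q-values quantify, rather than control, the FDR.
- The discrete percentile rule for b_α can make the metatest operate
  slightly above level α; the conservative flag trades power for strict
  level.
- SDPB calibration costs a few seconds the first time a new family size
  is seen (cached afterwards); the asymptotic bounding sequence is
  anticonservative at small S.
- The bootstrap π₀ estimator inherits the plug-in minimum's downward
  bias on families with very few tests.
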