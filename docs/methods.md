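# Methods

## Problem and estimands

Given a pair of equally sampled series y₁,ₜ, y₂,ₜ (t = 1..T, both centered
at their means before model-based analysis), the estimand is the dynamic
correlation path ρ(t). All three estimators return a `CorrelationPath`:
values in [−1, 1] over a defined range (t = ws..T for the windowed methods,
t = 1..T for DCC), with NaN marking time points where the estimate does not
exist (a zero-variance window or a constant median profile — possible for
discrete or artifact data, impossible for continuous distributions).
Metrics (`mean_abs`, `max_abs`, `mse`) skip undefined points.

## Sliding window

ρ̂ₜ is the Pearson correlation over the window [t−ws+1, t]; the first
defined estimate sits at t = ws, with no padding or tapering. Correlation
is normalization-free (the n vs n−1 variance convention cancels), so no
convention needs choosing. Degenerate windows are detected exactly
(max = min within the window), not by a tolerance.

## DCC-GARCH

Two-step Gaussian QMLE.

- **Step 1 (volatility).** GARCH(1,1) per centered series, recursion
  σ²ₜ = ω + α y²ₜ₋₁ + β σ²ₜ₋₁ with σ²₁ pinned to the sample variance (a
  common targeting convention; the likelihood is insensitive to it at these
  lengths). Optimization is unconstrained L-BFGS-B after transforming
  parameters (log ω; logistic persistence α+β ∈ (0, 1−10⁻⁶) and a logistic
  share splitting it between α and β), so the stationarity constraints hold
  by construction. Additional starting points and a Nelder-Mead polish are
  used only if the first start fails; persistent failure raises an explicit
  `ConvergenceError` — never silent defaults. Constant series are rejected.
- **Step 2 (correlation).** Residuals rₜ = yₜ/σₜ; the targeting matrix Ŝ is
  the sample correlation matrix of the residuals (the sample second-moment
  matrix rescaled to unit diagonal). The quasi-correlation recursion
  Qₜ = (1−a−b)Ŝ + a rₜ₋₁r′ₜ₋₁ + b Qₜ₋₁ starts at Q₁ = Ŝ and uses the lagged
  residual outer product exactly; (a, b) maximize the correlation
  log-likelihood L₂ = −½Σ[log|Rₜ| + r′ₜRₜ⁻¹rₜ − r′ₜrₜ] via Nelder-Mead on
  the same logistic transform (parameter tolerance 10⁻⁸). No bias
  correction of the targeting is applied: for two series the targeting bias
  is negligible. An integrated variant Qₜ = λrₜ₋₁r′ₜ₋₁ + (1−λ)Qₜ₋₁ (no mean
  reversion) is available with λ either fixed or estimated.
- **Numerical guards.** Inside L₂, |ρₜ| is clamped at 1−10⁻¹⁰ and
  det Rₜ = 1−ρₜ² floored at 10⁻¹²; activation counts are returned in
  `diagnostics` rather than hidden, because persistent clamping is exactly
  the flat-|ρ̂|≈1 instability that heavy-tailed inputs provoke in DCC —
  users should see it. Both recursions (variance and quasi-correlation) run
  through `scipy.signal.lfilter`, which makes a full two-step fit ~50 ms at
  T = 300.
- The reported path is the off-diagonal of the rescaled
  Rₜ = diag(Qₜ)⁻¹ᐟ² Qₜ diag(Qₜ)⁻¹ᐟ², so |ρ̂ₜ| ≤ 1 by construction
  (Qₜ is PSD as a convex-like combination of PSD terms).

## Weighted graph algorithm

Each series maps to a complete graph on its T time points; the edge between
times a and b carries wₐᵦ = arctan((x(t_b) − x(t_a)) / (t_b − t_a)), with
time measured in sample units and self-weight zero. Row i of the (symmetric,
zero-diagonal) weight matrix is the node-i weight vector. At each i ≥ ws the
element-wise median of rows i−ws+1..i gives a length-T median profile per
series, and ρ̂ᵢ is the Pearson correlation of the two profiles — all T
elements, including positions outside the window; this mix of a local window
with global slope information is what distinguishes the method from a plain
sliding window. The arctan caps each weight in (−π/2, π/2), so a single
extreme observation cannot dominate — the same capping idea as Huber- or
bisquare-type robust estimators.

Implementation notes: the kth profile element includes k itself when k lies
inside the window (the self-weight 0 enters that median) — the defining
formula is followed verbatim. For odd ws the per-time medians run through a
running median filter that is bit-identical to naive per-window
`np.median` (asserted against an explicit all-pairs brute-force oracle in
the tests); even ws uses the midpoint-of-central-order-statistics
convention directly. Translation invariance (slopes are shift-free) holds
up to the roundoff of (x+c)−(y+c).

## Synthetic scenarios

At each t the pair is drawn independently across time with zero location
and correlation p(t):

- `D1`: p(t) = 0 (static null; spurious-dynamics yardstick). Default
  T = 300; the benchmark grid uses T ∈ {150, 300, 600, 1000}.
- `D2a`/`D2b`: p(t) = sin(t/Δ), Δ = 1024/2ᵏ, k = 3/4; T = 600.
- `D3a`/`D3b`: p(t) = exp(−(t−250)²/(2(15k)²)), k = 3/4; T = 600. The
  Gaussian bump is **unit-amplitude** (peak correlation 1 at t = 250): a
  normalized density would peak below 0.01 and represent no "rapid change"
  at all, so unit amplitude is the only sensible reading; the bump width
  uses sd = 15·k as printed.

Normal draws use the covariance [[2, √6 p(t)], [√6 p(t), 3]] (the implied
correlation is exactly p(t)). Cauchy draws use the elliptical bivariate
Cauchy — a Gaussian pair divided by an independent half-normal scalar,
i.e. bivariate t with 1 df — with the **unit** scale matrix
[[1, p(t)], [p(t), 1]], the convention of the standard bivariate-Cauchy
generators, then element-wise clipping to ±50. The clip bound interacts
with the scale (it sets the maximum relative extremeness of an outlier at
clip/scale), so the scale convention is load-bearing for the heavy-tail
benchmark numbers; the unit-scale choice reproduces them, the
Gaussian-covariance scaling does not. Replicate streams derive from one
master seed via `SeedSequence.spawn`, so identical seeds give bit-identical
studies.

What the generator does *not* emulate: serial dependence within each series
(draws are independent across t; real fMRI/LFP series are autocorrelated),
measurement trends, or shared artifacts. Passing benchmarks here shows
correct behavior under the designed correlation dynamics and tail regimes,
not performance on autocorrelated recordings.

## Uncertainty quantification

**MLPB.** The stacked pair (series 1 then series 2, length 2T) is centered
per series; its covariance is estimated by the tapered block estimator with
(i, j) time-block κ(i−j)·C(i−j), where C(h) is the lag-h cross/auto-
covariance (1/T normalization) and κ is the trapezoid taper keeping lags 0
and ±1 (a flat κ ≡ 1, the naive inconsistent estimator, is available for
diagnostics). Assembly happens in time-interleaved (block-Toeplitz) order
and is permuted to the concatenated layout; the two layouts are related by
a fixed permutation, verified by a unit test. Positive definiteness: first
a ridge δ·I with δ = 10⁻¹⁰·trace/(2T), escalated ×10 up to six times; if
that fails — it genuinely can, since tapering may produce negative
eigenvalues far larger than any small ridge, especially for short blocks —
the spectrum is clipped at a small positive floor via an
eigendecomposition. Which repair ran is exposed (`ridge_`,
`eig_repaired_`). Resampling whitens with the Cholesky factor, standardizes
by the global mean/SD, resamples i.i.d., re-colors, and restores the
per-series means.

**BootCI.** The pair is cut into K adjacent blocks (size ⌊T/K⌋, the last
absorbing the remainder; default K gives ≥ 50 points per block), each block
is MLPB-resampled, the blocks are recombined, and the WGA path of the
recombined pair is computed; B repetitions give pointwise 2.5/97.5
percentiles (nearest-rank convention). The Fisher z band
tanh(arctanh ρ̂ₜ ± z₀.₉₇₅/√(T−3)) is the closed-form alternative (estimates
at ±1 clamped to ±(1−10⁻¹²)).

**Pointwise significance.** A permuted copy of the pair (each series
permuted independently — a joint single permutation would preserve
contemporaneous pairing and is exposed only as an exploratory flag) has
true correlation zero; time points where the BootCI bands of the original
and permuted pairs are strictly disjoint (touching counts as overlap) are
flagged as significantly nonzero at the 5% level.

**Known limitation — band coverage under strong dynamics.** The bootstrap
band is centered on the *estimate* and calibrated for its sampling noise
(measured: bootstrap mean tracks the original path with slope ≈ 0.98, and
coverage ≈ 0.96 where |ρ| < 0.33). It cannot absorb the estimator's own
smoothing bias: near correlation peaks the WGA estimate is attenuated
(arctan compression plus the ws-point median lag), while the band *narrows*
(correlation variance scales like (1−ρ²)²). On the sinusoidal design with
peaks at |ρ| = 1, average pointwise coverage of the truth is therefore
~0.55–0.6, not the nominal 0.95, and this is insensitive to the number of
blocks. The bands quantify uncertainty, not total error. Relatedly, band
width does not shrink as T grows: the estimate at a time point is dominated
by its local window (and blocks keep a fixed ~50-point length), so its
pointwise variability is not a global 1/√T statistic.

## Hypothesis tests

For H₀: η² = 0 (static) vs η² > 0, over the path points t = ws+1..T (the
first point is excluded; divisor T−ws−1, per the defining formulas):

- κ² (variance around the path mean) and κ²_med (around the path median;
  the robust default).
- The excursion statistic S = Σⱼ Iⱼ^α Hⱼ^β over median-crossing segments.
  A segment is a maximal run of points on one side of the path median;
  points exactly at the median attach to the preceding segment; Iⱼ is the
  segment's point count (so Σ Iⱼ = T − ws, conserving time) and Hⱼ its peak
  absolute deviation. Defaults α = 0.9, β = 1; alternatively (α, β) is
  tuned on a 0.05..1.50 grid (step 0.05) by minimizing
  Σ_b (S_b(α,β) − S(α,β))² over the bootstrap paths (ties → smallest α,
  then β). A variance-based tuning criterion is exposed behind a flag.
- Significance: the statistic on the original WGA path vs B blockwise-MLPB
  bootstrap paths. The default interval is the **basic bootstrap**
  [stat − q₉₇.₅(d), stat − q₂.₅(d)] with d_b = stat_b − stat; the literal
  "subtract the 2.5th / add the 97.5th percentile" construction is exposed
  as `interval="literal"` but essentially never contains zero for a
  nonnegative statistic. Reject when the interval excludes 0.

**Known limitation — size.** Under a *static* truth the statistics estimate
the sampling noise of the path, which is positive, and the bootstrap
reproduces that positive value; the test therefore over-rejects a static
null (measured ≈ 40% at T = 300, constant ρ = 0.3) and should be read as a
screen with good power under real dynamics (rejection ≈ 100% on the
sinusoidal designs), not as a calibrated 5% test. The power *ordering*
(dynamic ≫ static) is what the test suite asserts.

## Problem sizes used in the checks

Benchmark reproduction uses R = 200 replicates per scenario (the
Monte-Carlo SE of each summary is SD/√200, and agreement is asserted within
4 SE); qualitative orderings use R = 100; the bootstrap coverage study uses
10 replicates × B = 100; recovery experiments use T = 2000. These sizes
make each summary's Monte-Carlo error small relative to the differences
being tested while keeping the full suite around six minutes.
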