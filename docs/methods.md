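# Methods

## Model and procedure

`phaspasto` interpolates a univariate series by conditioned fractional
Brownian motion and selects among stochastic interpolations by the
smoothness of the delay-embedded trajectory.

**Bridge construction.** For a Hurst exponent `H ∈ (0,1)` the fBm
covariance is `C(t,t') = ½(t^2H + t'^2H − |t−t'|^2H)`; the process is
pinned to zero at `t = 0`. Conditioning a sampled path on the observed
points is the linear (kriging) correction
`X_B(t) = X(t) − (X(t_i) − X_i)[σ⁻¹]_ij C(t,t_j)`, which reproduces every
prescribed point exactly, is affine in the path (the zero path maps to the
conditional mean) and is idempotent on paths that already satisfy the
constraints. For `H = ½` the conditional mean between consecutive
constraints is piecewise linear; these properties anchor the test suite.

**Sampling.** Exact, by Cholesky factorization of the full-grid covariance.
The `t = 0` row/column is removed before factorization and the pinned zero
reinstated. If factorization fails, a single jitter of `1e−12 ×` the
largest diagonal entry is added; a second failure raises — the sampler
never regularizes silently. Cubic cost restricts grids to a few thousand
points, which covers every benchmark in scope.

**Origin and time conventions.** Observed series neither start at zero nor
at `t = 0`, so the first observation is made the pinned origin: its value
is subtracted from all constraint values and added back after conditioning.
The bridge lives on the *index* grid of the refined series — consecutive
refined samples are one abstract time unit apart regardless of real
spacing; with `k` new points per gap, consecutive observations sit `k + 1`
index units apart. Real-sampling units would tie the fluctuation amplitude
to the (arbitrary) time scale of the input; the index convention makes the
fluctuation size depend only on the refinement factor. The residual
amplitude freedom is exposed as the `scale` multiplier (default 1.0)
applied to the sampled fBm before conditioning. New samples are placed
uniformly in real time inside each gap, so non-equidistant observations are
supported; for the uniform grids of the benchmarks the new samples coincide
with the deleted ones.

**Embedding and loss.** Candidates are delay-embedded with
`d_E = 3, τ = 1` by default — a deliberately fixed, low-dimensional
embedding that behaves well across data sets; the autocorrelation,
mutual-information and false-nearest-neighbour estimators are provided as
advisory tools, not as defaults. The loss is the population variance
(divide by count, so results are reproducible without a sample-size
convention) of per-point curvature magnitudes, where each magnitude
combines the second central differences of all embedding components.
Because the published description can be read either as the variance of
the *squared* Euclidean curvature norm or of the norm itself, both modes
are implemented (`squared_norm`, `norm`); `norm` is the default. The two
modes agree on all zero-loss cases but can rank candidates differently.
Curvature is computed only where every component's central difference
exists — no boundary padding. The loss annihilates affine trends exactly
and scales as `c⁴` (`squared_norm`) or `c²` (`norm`) under `x → cx`.

**Genetic algorithm.** Population default 1000 (benchmarks here use 100 or
less); each member draws `H ~ U(0,1)`. Draws whose covariance defeats
double-precision factorization (H extremely close to 1 on long grids) are
redrawn, up to a bounded number of attempts. Selection is generational
elitism: the top `mating_fraction` (default ½) survive unchanged, the rest
are replaced by children of two distinct elite parents chosen uniformly;
each gene — the interpolated segment strictly between two observed
anchors — is inherited from either parent with probability ½, so every
child still passes exactly through all observations. Child losses are
recomputed from the assembled series (the loss is not gene-separable).
Mutation is a single event per generation with probability 0.2: one
uniformly chosen candidate of any rank is replaced by a fresh random-`H`
interpolation. Termination: the population mean loss unchanged (relative
change `< 1e−10`; exact float equality would be fragile) for 10 consecutive
generations, or 1000 generations. The returned optimum is the best
candidate over the whole run, tracked separately so mutation of the
incumbent cannot lose it. All randomness flows from one seeded generator,
making runs bit-reproducible.

## Lorenz benchmark conventions

The ground truth is the x-component of the Lorenz system
(`σ = 10, ρ = 28, β = 8/3`) integrated by classical RK4 from
`(−8, 8, 27)` with the coupling `dt = 0.1/(n_I + 1)`, `L = 200(n_I + 1)`
(total time 20; kept-sample spacing 0.1 for every `n_I`). Three
conventions were fixed by requiring that the pipeline reproduce the
published baseline table across `n_I = 1..10`, where most entries then
agree to about 0.1 %:

- the series consists of the `L` states *after* the initial condition
  (samples at `t = dt, …, L·dt`); the initial state is not a sample;
- the deletion split keeps the stride-`(n_I+1)` pattern *and* the final
  sample as closing anchor (no truncation; the last gap may be shorter);
- the reported error sums squared errors over the deleted samples but
  normalizes by the full signal length `L` before taking the root. Kept
  samples are exact for every method here, so this equals the RMSE of the
  full reconstruction against the full truth.

Because the system is chaotic, trajectories at different `dt` decorrelate
within a few time units (the test suite asserts both early-time
consistency and late-time divergence between step sizes); the linear
baseline is a self-averaging statistic reproducible to a fraction of a
percent, while the spline error is dominated by a few sharp attractor
turns and intrinsically fluctuates by ~10–20 % across integration details.

Scaled-down GA benchmark: population 100 (vs 1000 in the published study),
`n_I = 8`, fixed seed — chosen to keep the full suite within minutes on one
CPU. The qualitative ordering (GA below the population-mean series and the
linear baseline, and within 25 % of the best random candidate) is asserted,
not the population-level numbers, which depend on the fBm amplitude
normalization that the index-grid convention fixes only up to `scale`.

## Embedding estimators

- *Autocorrelation delay:* biased ACF normalized by lag 0; the estimate is
  the first lag no longer significantly positive (at or below the standard
  white-noise band `1.96/√n`). A sharp `≤ 0` cutoff would overshoot the
  intended lag on finite samples of periodic signals, where the ACF at the
  quarter period is a small positive truncation residue.
- *Mutual-information delay:* 2-d histogram estimate (default 16 bins per
  axis), first local minimum over lags up to `n/4`; lag 1 qualifies when
  the curve does not descend past it. Falls back to 1 with a warning when
  no minimum exists.
- *False nearest neighbours:* Kennel criterion with `r_tol = 10`,
  `a_tol = 2`, threshold 1 %, searched up to dimension 10. Pairs of
  numerically coincident vectors (exact repeats of periodic data, distance
  below `1e−10 ×` the series standard deviation) are judged by the extra
  coordinate alone, since round-off noise defeats the distance-ratio test
  there.

## Synthetic fixtures

`make_fixture` generates `x_k = a·k + A·|sin(πk/period)|^p + ε_k` with
Gaussian noise — a seeded, seasonal-plus-trend-plus-noise family that
emulates the shapes of the non-model validation sets (large `p` gives the
sharp repetitive peaks of epidemic counts; `p = 1` smooth seasonal sales
or temperature records). What the fixtures do *not* emulate: regime
changes, multiplicative noise, missing-not-at-random gaps and measurement
quantization of real archives; green tests on fixtures therefore establish
the pipeline's mechanics and statistical contracts, not performance claims
for any particular real data set.

## Degenerate inputs and numerical choices

Constraints at `t = 0`, duplicate constraint times, constant series (for
rescaling, autocorrelation or the FNN estimator) and too-short series all
raise informative errors rather than being silently repaired. Rescaling
after detrending a perfect line is rejected as numerically constant. CSV
output uses 17 significant digits and input parsing uses round-trip float
precision, so write/read cycles are lossless.

## Known limitations

- Exact Cholesky sampling is `O(n³)`; grids beyond ~5000 points are out of
  scope by design (no Davies–Harte or wavelet synthesis).
- The loss requires a minimum trajectory density to discriminate
  smoothness; with a single interpolated point per gap the optimizer can
  prefer candidates that score worse on deleted points than the random
  population average — the published benchmark shows the same behaviour.
- Population-level error magnitudes depend on the fluctuation amplitude
  (`scale`); only ordering properties are asserted.
- The GA is serial; no island models or adaptive mutation.
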