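# Methods

## Measurement model

The analysis operates on region-mean time–intensity curves, one sample per
heartbeat (frame index = heartbeat index; physical seconds are never
needed because every reported quantity is a ratio or a slope ratio).

For each curve:

1. **Baseline and foot.** The pre-contrast baseline is the mean and sample
   sd of the first `k_baseline` frames (default 5, the typical
   pre-contrast duration at a 4 mL/s antecubital injection). Contrast
   arrival (the "foot") is the frame before the first frame exceeding
   `baseline + threshold_sd·sd` (default 2 sd), clamped to frame 0. A
   curve that never crosses the threshold raises a no-enhancement error
   rather than returning a slope.
2. **Maximum up-slope.** Every contiguous window of `window_len` frames
   (default 3 — the smallest window leaving a residual degree of freedom)
   with start ≥ foot and end ≤ the curve's global maximum is fit by
   ordinary least squares of value against frame; the steepest window
   wins, ties going to the earliest. Restricting the search to
   [foot, peak] excludes the recirculation phase. No temporal smoothing is
   applied by default; an optional 3-point moving average exists for very
   noisy curves.
3. **Normalization.** Sector up-slopes are divided by the LV-cavity
   up-slope and scaled ×100, the convention that puts healthy resting
   values near 8–10. Because all sectors share the denominator,
   normalize-then-average and average-then-normalize are identical; the
   ×100 scale can be disabled (`times100=False`) for pure ratios.

Per subject, MPRi-rest = mean normalized stress up-slope / mean normalized
rest up-slope, and MPRi-recov uses the recovery acquisition as baseline.
The segment-averaged up-slope is ratioed (not per-sector ratios averaged);
per-sector MPRi values are emitted as diagnostics only. A subject whose
recovery up-slope exceeds the stress up-slope is flagged as delayed
maximal hyperemia; the flag implies MPRi-recov < 1 identically. Cohort
percent reduction (MPRi-recov vs MPRi-rest) is the mean of per-subject
percent reductions, which is why it carries an SD; it is not the percent
reduction of the group means.

## Phantom

The phantom exists to make the pipeline's accuracy measurable against
known truth. Its generative model:

- **Arterial input**: gamma-variate
  `c_a(t) = A·((t−t0)/(αβ))^α · exp(α − (t−t0)/β)` for `t > t0`, zero
  before onset, peaking at exactly `A` at `t = t0 + αβ`. Defaults
  `t0 = 5` heartbeats, `α = 3`, `β = 2`, `A = 100` signal units — a
  compact bolus peaking 6 beats after arrival, typical of a 4 mL/s
  injection. The published studies this emulates report no arterial curve
  shapes or absolute signal scales, so these are chosen, not matched.
- **Tissue kinetics**: one-compartment Kety model
  `dc_m/dt = F·c_a − (F/λ)·c_m`, integrated with an exact exponential
  update for a piecewise-linear input on 20 sub-steps per heartbeat (the
  result is exact for the linear interpolant of the input; the λ→∞ limit
  reproduces `F·∫c_a` to machine precision). Rest flow default
  `F = 0.025`/heartbeat puts the rest normalized up-slope at 8.85, on the
  measured ~8 scale. Partition coefficient default `λ = 2.0`: washout rate
  is `F/λ`, and this value keeps the up-slope surrogate's washout bias
  below 8% over flow multipliers 1–3, preserving the near-linear
  flow→up-slope mapping that the semi-quantitative method presumes
  (λ = 1 would push the bias past 13% at multiplier 3).
- **States**: identical arterial input across rest/stress/recovery; only
  tissue flow changes. Default multipliers: stress 2.0 (near the measured
  mean stress/rest up-slope ratio in healthy adults), recovery 1.68
  without aminophylline and 1.34 with (from the reported mean recovery
  elevations of 68% and 34%). Delayed-hyperemia subjects use stress 1.4 /
  recovery 1.8 so recovery exceeds stress. Per-state `signal_gain`
  emulates the two contrast-dose dialects (0.05 vs 0.025 mmol/kg); the
  analysis is verifiably invariant to it. An optional exponential
  saturation gain `S·(1 − exp(−x/S))` exists but is off by default, so
  signal is linear in concentration.
- **Geometry**: a 64×64 grid, concentric cavity (radius 10 px) and
  myocardial ring (14–22 px), partitioned into four equal angular sectors
  (anterior, lateral, inferior, septal) counter-clockwise from a free
  anterior reference angle (real protocols anchor it at the RV insertion;
  the phantom has none, so 0 rad is used). Noise is additive Gaussian per
  pixel per frame — region means over hundreds of pixels are
  near-Gaussian regardless of the underlying magnitude statistics, and
  the additive model keeps the oracle math exact.
- **Cohorts**: between-subject variability is log-normal, σ = 0.25 on
  rest flow and σ = 0.30 on flow multipliers, matching the coefficients
  of variation of reported healthy-cohort up-slopes (≈0.29) and reserve
  indices (≈0.34). Assigned delayed counts are guaranteed exactly: a
  subject whose jittered stress/recovery draws contradict the assigned
  flag has the two multipliers swapped.

What the phantom does **not** emulate: cardiac or respiratory motion,
coil-sensitivity shading, arrhythmic gating errors, Rician magnitude
noise, multi-slice coverage, signal saturation (unless enabled), or any
diseased-territory heterogeneity. Passing recovery tests therefore shows
the *measurement chain* is unbiased under the stated kinetic model; it
does not certify performance on real, motion-corrupted acquisitions where
per-frame contouring and saturation correction matter.

## Statistics

- **Welch t** from group moments (`t = Δmean/√(s²/n + s²/n)`,
  Welch–Satterthwaite df), callable on raw samples or printed summaries.
  Note that t-tests recomputed from 2-significant-figure published
  summaries can differ from the p-values computed on raw data (e.g. a
  heart-rate comparison printed as p = 0.03 reproduces as 0.021 from the
  rounded summaries); such values are scale checks, not equalities.
- **Paired t** is the one-sample t on per-subject differences; zero
  variance raises an undefined-statistic error which the cohort table
  renders "n/a" (this happens in jitter-free synthetic cohorts).
- **Fisher's exact test** uses the two-sided point-probability rule (sum
  of hypergeometric probabilities ≤ the observed table's), computed in
  exact integer arithmetic so no floating tolerance enters the tail
  comparison. Mid-p and tail-doubling variants are deliberately not
  offered; the point-probability rule is what standard packages report.
- **Sample size** defaults to the two-sided normal-approximation formula
  `n/group = ⌈2σ²(z_{1−α/2} + z_{power})²/Δ²⌉` with equal allocation,
  where Δ is the relative difference times the reference mean — the
  convention that reproduces the published 58-subject design for a 25%
  difference in a reserve of 1.78 ± 0.60. An exact noncentral-t mode
  (statsmodels) is available and returns 60 for the same design; the
  normal approximation undershoots true power slightly (empirical power
  of the 29-per-group design is ≈0.79 rather than 0.80), which the
  calibration run quantifies.

## Numerical and interface choices

- Frame indices and pixel indices are 0-based; angles increase
  counter-clockwise in the displayed image.
- Degenerate inputs raise typed exceptions (no NaN propagation): empty
  regions and rings are geometry errors, flat curves no-enhancement,
  rises shorter than the window insufficient-rise, non-positive blood
  slopes normalization errors. The CLI maps input errors to exit 2 and
  configuration/parameter errors to exit 3.
- All outputs embed the tool version, a configuration hash and the seed;
  identical inputs give bit-identical CSV/JSON outputs. NIfTI is used for
  image series and label masks (0 background, 1 cavity, 11–14 sectors);
  everything else is CSV/JSON/YAML.
- Problem sizes in the validation runs — 100 seeds for noisy recovery,
  10,000 replicates for test calibration, a 20-subject cohort — were
  chosen so Monte-Carlo error is well below the decision thresholds they
  feed (e.g. binomial sd of a 5% rejection rate at 10,000 reps is 0.2
  percentage points).

## Known limitations

- The up-slope surrogate carries a washout-dependent negative bias that
  grows with flow (≈4% at reserve 2.0 with default kinetics); MPRi is
  therefore slightly compressed toward 1. This is a property of the
  method, not of the implementation, and is quantified by the phantom.
- Foot detection assumes ≥ `k_baseline` clean pre-contrast frames; very
  early bolus arrival would bias the baseline.
- The exact up-slope algorithm inside commercial analysis packages
  (window length, smoothing) is unpublished; defaults here are stated and
  configurable, but numeric agreement with any particular vendor is not
  claimed.
- Only one mid-ventricular slice is modeled and analyzed.
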