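# Methods

This note documents the models and procedures implemented in `lipdecode`,
the parameters that matter, the numerical conventions, and the design
decisions taken where the analysis definition was genuinely open.

## Generative model of the synthetic cohort

Each synthetic neuron fires as an inhomogeneous Poisson process with rate

    r(e, t) = b + (p − b) · exp(−‖e' − c‖² / 2σ_s²) · exp(−(t − t_p')² / 2σ_t²)

where `e` is the saccade end-position (deg), `t` the time relative to
saccade onset (ms), `b`/`p` the baseline/peak rates (spikes/s), `c` the
spatial tuning center, `σ_s` the spatial width (deg) and `σ_t` the temporal
width (ms). The rate is bounded in `[b, p]` by construction, so spike
generation by thinning against `b + (p − b)·G_space` is exact.

**Snapshot offset τ (ms).** For regular saccades `e' = e` and `t_p' = t_p`.
For interceptive saccades a neuron with snapshot offset τ references the
target's position τ ms from the saccade *landing*:

    e' = e + u(α) · v · τ / 1000,      t_p' = t_p − τ

with `u(α)` the unit vector of the target-motion direction and `v` the
target speed. τ = 0 therefore reproduces the regular-condition rates
exactly for saccades landing at the same point — the neuron encodes the
actual landing position. A negative τ both displaces the interceptive
spatial reference toward the center (by `v·|τ|/1000` deg) and delays the
interceptive response by |τ| ms ("delayed snapshot": a neuron relying on
older target information responds correspondingly later). This single knob
is what the decoding analysis must recover: a −50 ms snapshot at 10°/s is
0.5° of center bias in the ±100 ms window and one 50 ms step of delay in
the sliding-window bias minimum. A known, accepted side effect of the
temporal delay is that the interceptive response mass inside the fixed
±100 ms window is slightly smaller than the regular one (~12% for
σ_t ≈ 60 ms), which can add a small shrink-toward-center component on top
of the geometric 0.5°; empirically the recovered bias stays well inside
0.5 ± 0.15°.

**Behavioral model.** Trials start with fixation at an eccentric point
(default (0, 7)°). Latencies are Normal(134, 44) ms and durations
Normal(36, 8.9) ms (redrawn below physiological floors of 50/12 ms).
Regular endpoints are the stepped target plus isotropic Gaussian noise;
interceptive endpoints are the target's position at saccade end plus the
same noise, so the intercept grows with saccade-end time at exactly the
target speed. The endpoint noise SD defaults to 0.8°, chosen to reproduce
the observed intercept-residual spread (~0.8°) and, with the ~45 ms spread
of saccade-end times, an intercept–time correlation of ~0.4. Eye traces are
fixation + a minimum-jerk saccade profile + post-saccadic pursuit at the
target velocity (interceptive) or fixation (regular), plus white positional
noise (SD 0.05°), sampled at 1 kHz; the minimum-jerk profile crosses the
detector's velocity thresholds realistically (peak speed `1.875·amp/dur`).

**What the generator does not emulate:** pursuit gain dynamics and catch-up
saccades, eye-tracker artifacts (blinks, drift, dropouts), latency–endpoint
correlations (independent draws), non-Poisson spiking (bursting,
refractoriness), and session-to-session heterogeneity of preferred vectors.
Passing recovery tests therefore demonstrates that the *pipeline* is
correct and unbiased under its own assumptions, not that real recordings
satisfy those assumptions.

**Seeding** is hierarchical (session seed → per-trial → per-neuron
substreams via `SeedSequence([seed, stream, trial, neuron])`), so enlarging
the cohort leaves existing trials' behavior and spike trains unchanged.

## Oculomotor processing

Traces are smoothed by a centered 15 ms moving average (window truncated at
the edges); velocity is computed by central differences (symmetric,
low-bias; the analysis definition leaves the differentiator open). The
detector finds the first sample above 100°/s, walks backward to the last
sample below 30°/s (onset) and forward to the first sample below 30°/s
(offset); pre/post positions are means over [onset−16, onset−6] and
[offset+2, offset+4] ms (the short post window avoids pursuit
contamination). Only the first saccade per trial is analyzed; a trace with
no supra-threshold window yields an explicit no-event result. Threshold
crossings sit within a few ms of the true (zero-velocity) endpoints — later
for small/slow movements, slightly earlier through the smoothing — which is
immaterial downstream because spikes are aligned to the *detected* onset in
exactly the way the rates were generated around the true one.

The intercept regression is OLS of intercept (deg) on saccade-end time (s);
confidence intervals are percentile intervals (0.5/99.5 for p = 0.01) over
2000 trial-level bootstrap resamples (count chosen as a round number giving
stable 99% quantiles; the analysis definition specifies the bootstrap but
not the count). Degenerate resamples with zero time variance are dropped.
Endpoint clouds are summarized by the sample mean and covariance; a
covariance with a near-zero eigenvalue (e.g. collinear points) is flagged
singular rather than raised. The inclusion test is a two-sample equal-
variance t-test on ±100 ms spike counts, preferred vs anti-preferred, with
p < 0.01; zero variance on both sides is flagged degenerate and excluded.

## Tuning fields

Response functions convolve onset-aligned spike times with a unit-area
Gaussian (σ = 20 ms, truncated at 4σ — < 10⁻⁴ of mass lost), scaled to
spikes/s and trial-averaged, evaluated on the −400…+350 ms grid (10 ms
steps). Spatial interpolation is staged after temporal smoothing (the
two-step reading of the procedure): per time slice, piecewise-linear
interpolation on the Delaunay triangulation of the anchor set inside its
convex hull and nearest-anchor extrapolation outside (deliberately not
overestimating activity beyond the sampled area). Anchors are the *measured*
mean end-positions of each trial group, which keeps the anchor coordinates
self-consistent with the trials that produced the anchor's rates. Window
averages are means over the inclusive grid samples in `[t_lo, t_hi]`;
expected spike counts are this mean rate times the window duration in
seconds (for a ±100 ms window: rate × 0.2 s). This sampled-mean convention
differs from the continuous time integral by a few percent for sharply
peaked responses and is applied identically in training and evaluation.

Because interpolating anchor values and window-averaging are both linear,
the pipeline computes window-averaged anchor responses first and
interpolates once per subset (verified equal to window-averaging the full
interpolated field); one triangulation is shared by all neurons of a
subset.

## Similarity index

`SI = 1 − ‖z(R) − z(I)‖_F / (‖z(R)‖_F + ‖z(I)‖_F)` with z(·) the entrywise
standardization (map mean subtracted, divided by the population SD). Under
this convention `‖z‖_F = √N`, `SI = 1 − √((1 − r)/2)` for correlation r,
SI ∈ [0, 1], SI = 1 only for identical z-maps and SI = 0 for sign-flipped
ones; SI is symmetric and invariant to positive affine rescaling of either
map. The z-transform is not defined in the source analysis; full
standardization is the default here, and a scale-only variant
(`standardize="scale"`), which retains mean-rate differences in the index,
is exposed for the alternative reading. Constant maps make the z-transform
undefined and raise. Maps are compared inside a central disk of radius 1.5°
— the region actually covered by interceptive saccades — because outside
the 8-anchor hull the interceptive field is nearest-extrapolated and a
full-grid comparison would penalize even identical tuning. Subpopulation
selection uses strict inequalities (r > 0.5 AND SI > 0.3).

## Decoder

Stratified splits put `round(0.7·n)` of each anchor's trials in training
(10 trials → 7/3). Pseudo-trial end-positions are uniform over the ±4°
square; counts are independent Poisson draws per neuron. The network has
two tanh hidden layers of 20 units and a linear 2-unit output; inputs are
standardized by training mean/SD (zero-SD inputs pass through unscaled).
Training minimizes MSE with lbfgs (a quasi-Newton least-squares trainer
with the same contract as Levenberg–Marquardt at this scale), max 400
iterations, tol 1e-6; convergence state is recorded on the model.
Raw-count vs normalized-rate inputs was an open choice: counts are used,
with standardization absorbed into the model.

Evaluation assigns each single-trial prediction to the nearest of the 8
tested positions (Euclidean; ties — a measure-zero event — break to the
lowest index). Tested positions are the cohort-level mean interceptive
end-positions per motion direction. "Direct neighbors" are the two
angularly adjacent ring positions, the only reading under which the
neighbor chance level is 3/8 = 37.5%. Per-position means/SDs and confusion
rows are computed per split and averaged across splits; the reported mean
Euclidean error and center bias are then computed from the across-split
mean predictions (the combined-networks reading), so independent per-split
field noise averages down. Confusion rows always sum to 1.

The sliding-window analysis retrains the decoder per 100 ms window (50 ms
steps, 14 windows spanning −400…+350 ms), evaluates both conditions at the
8 tested positions, and flags windows where a paired t-test across the 8
positions (on split-averaged biases) gives p < 0.01. The per-window
training-set size is configurable; the defaults (8000 pseudo-trials, 3
splits, 100 evaluation draws per position) keep a 2 × 14-window recovery
experiment at the 20-neuron profile within a few minutes while leaving the
bias minima well resolved.

## Problem sizes used by the tests and acceptance script

Unit tests run on reduced sessions (e.g. 12 neurons, 6 regular trials per
position). The recovery experiments use: 105 neurons / τ = −50 ms / 5
splits / 20 000 pseudo-trials for the center-bias and error-field recovery;
100 repeated 320-trial behavioral sessions for the regression-coverage
check; and 20 neurons / 3 splits / 8000 pseudo-trials per window for the
sliding-window profiles. These sizes were chosen so each experiment's
Monte-Carlo error is small against the effect it measures (e.g. ±0.05° on
a 0.5° bias) while the full suite remains desk-runnable.

## Known limitations

- The decoder evaluation draws Poisson counts from the *estimated* fields;
  with very few validation trials per anchor the field noise, not the
  decoder, can dominate single-split errors (mitigated by the across-split
  aggregation).
- The sliding-window minimum is resolved only to the 50 ms step.
- The maximum-likelihood decoding alternative is not implemented; the
  pipeline is committed to the fixed 20-20 network architecture.
- Interceptive fields rest on 8 anchors, so structure finer than the ring
  spacing is invisible to them; comparisons are restricted to the central
  disk for this reason.
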