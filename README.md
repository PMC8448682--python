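# lipdecode

Population decoding of saccade end-positions from peri-saccadic spiking
activity, for the comparison of **regular saccades** (to stationary targets)
with **interceptive saccades** (to moving targets).

Interceptive saccades are remarkably accurate even though the oculomotor
system must extrapolate the target's motion across its own processing delay
and the saccade duration. A central question for any saccade-related brain
area is therefore whether its neurons encode the *actual landing position* of
an interceptive saccade, or merely a *snapshot* of the target position taken
some time earlier. `lipdecode` implements the population-decoding analysis
that addresses this question, together with a ground-truthed synthetic cohort
generator, so that every stage — and the snapshot inference itself — can be
validated as a parameter-recovery experiment.

## The analysis

1. **Oculomotor processing.** Eye traces (1 kHz) are smoothed with a 15 ms
   moving average; saccades are detected with a double velocity criterion
   (trigger > 100°/s, onset/offset where the speed last/first falls below
   30°/s). The motion-related component of each endpoint is the *intercept*

   `intercept = x·cos(α) + y·sin(α)`

   (α = target-motion direction), regressed on the saccade-end time with a
   trial-level bootstrap CI; 2-D Gaussians are fitted to the endpoint
   clouds per direction.

2. **Tuning fields.** Per neuron and condition, spike trains aligned to the
   saccade onset are convolved with a Gaussian (σ = 20 ms), trial-averaged
   per anchor (the measured mean end-position of each target group), and
   interpolated over a grid of ±4° (0.1° steps) × −400…+350 ms (10 ms
   steps): piecewise-linear inside the anchor hull, nearest-anchor outside.

3. **Similarity screening.** Window-averaged (±100 ms) regular and
   interceptive maps are compared (within the central ~1.5° actually covered
   by interceptive saccades) by their Pearson correlation and a similarity
   index

   `SI = 1 − ‖z(R) − z(I)‖_F / (‖z(R)‖_F + ‖z(I)‖_F)  ∈ [0, 1]`,

   with z(·) the entrywise standardization. A "matched" subpopulation is
   selected by r > 0.5 and SI > 0.3.

4. **Pseudo-population decoding.** Regular trials are split 70/30
   (stratified, repeated); expected spike counts at random end-positions are
   read off the training fields and Poisson-resampled into a large
   pseudo-trial set that trains a shallow network (inputs = neurons, two
   tanh hidden layers of 20, linear (x, y) output, quasi-Newton MSE
   training). The decoder is validated on regular validation fields and
   applied to interceptive fields at the 8 mean interceptive end-positions:
   nearest-position confusion matrices (chance 12.5% correct, 37.5%
   correct-or-neighbor), the **center bias** (intercept of the tested
   position minus intercept of the prediction; positive = compressed toward
   the screen center), continuous error fields, and sliding-window
   (100 ms / 50 ms steps) time courses. A center bias *b* at target speed
   *v* corresponds to a snapshot time lag `1000·b/v` ms.

The synthetic cohort emulates the study conditions (17 stationary target
positions at 2° and 4°; 8 motion directions at 10°/s; latency 134 ± 44 ms;
duration 36 ± 8.9 ms; endpoint scatter 0.8°; Poisson spiking with 2-D
Gaussian spatial tuning peaking near saccade onset) and exposes a per-neuron
**snapshot offset τ**: a τ = −50 ms neuron encodes the target position 50 ms
before landing, which at 10°/s must be recovered by the decoder as a 0.5°
center bias and a 50 ms sliding-window shift.

## Worked example

```python
import lipdecode as L

cohort = L.make_cohort(n_neurons=40, seed=0, tau=-50.0)   # snapshot cohort
trials = L.simulate_session(cohort, L.SessionConfig(n_neurons=40, seed=0))

model = L.SaccadeDecodingModel(trials)        # smoothing + saccade detection
print(model.behavioral_regression(seed=0).summary())

res = model.fit(n_splits=5, n_pseudo=10_000, n_eval=200, seed=0)
print(res.summary())
```

prints

```
intercept ~ t_end OLS (n=120)
  slope     11.727 deg/s   CI99 [7.475, 16.579]
  offset    -0.182 deg     CI99 [-1.067, 0.583]
  pearson r = 0.554

Saccade end-position decoding
================================================================
neurons: 40   splits: 5   pseudo-trials: 10000   window: [-100, 100] ms

                             regular  interceptive
% correct                       76.4          62.6
% correct/neighbor              98.7          95.7
mean error (deg)               0.120         0.412
center bias (deg)             -0.041         0.395

interceptive bias as target-motion lag: 39.5 ms
```

The regression slope tracks the 10°/s target speed (the CI covers it; at 120
trials the estimate is noisy). The decoder localizes regular saccade
endpoints to ~0.1° with essentially no center bias, while the same decoder
applied to the τ = −50 ms cohort's interceptive activity shows a positive
center bias — here ~0.4°, i.e. a recovered snapshot lag of ~40 ms against
the generating 50 ms at this reduced cohort size. With the full 105-neuron
cohort the recovery is tighter (see below). Sliding-window time courses come
from `model.sliding_window(...)`, and `lipdecode run --config cfg.yaml`
executes the whole pipeline reproducibly from a YAML config.

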