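"""Synthetic cohort generator: neurons, behavioral trials, and spike trains.

Emulates the statistical structure of a peri-saccadic single-unit dataset
recorded while a subject makes visually guided saccades either to stationary
targets (17 positions around the screen center: the center itself plus the
four cardinal and four oblique directions at 2 and 4 deg) or to targets that
step to the center and move in one of 8 directions at constant speed
("interceptive" saccades).  Every downstream analysis stage of the package is
testable against this generator because the ground truth (tuning centers,
snapshot offsets, saccade events) is known by construction.

Coordinates are in degrees of visual angle, screen-centered, x rightward and
y upward positive; directions are degrees counter-clockwise from +x.  Eye
traces are sampled at 1 kHz.

The "snapshot offset" ``tau`` of a neuron implements a controllable continuum
between a neuron that faithfully encodes the landing position of an
interceptive saccade (tau = 0: regular and interceptive tuning agree) and one
that encodes where the target was |tau| ms before landing (tau < 0).  Two
consequences follow for the interceptive condition: the spatial tuning is
referenced to ``endpoint + u(alpha) * speed * tau / 1000`` (the target's
position tau ms from landing, keeping the saccade's direction-independent
scatter), and the temporal activation profile is delayed by ``-tau`` (a
neuron relying on older target information responds correspondingly later).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .oculomotor import SaccadeEvent

__all__ = [
    "NeuronSpec",
    "SessionConfig",
    "TrialRecord",
    "stationary_target_layout",
    "interceptive_directions",
    "neuron_rate",
    "simulate_session",
    "make_cohort",
]

#: direction angles (deg CCW from +x) of the 8 motion / layout directions
RING_DIRECTIONS = tuple(float(d) for d in range(0, 360, 45))


def _unit(direction_deg: float) -> np.ndarray:
    a = math.radians(direction_deg)
    return np.array([math.cos(a), math.sin(a)])


@dataclass(frozen=True)
class NeuronSpec:
    """Generative parameters of one synthetic neuron.

    The spatial tuning is a unit-peak 2-D isotropic Gaussian over saccade
    end-positions, the temporal tuning a unit-peak Gaussian over time relative
    to saccade onset; the rate is

    ``baseline + (peak - baseline) * G_space(endpoint) * G_time(t)``

    so the rate is bounded by ``[baseline_rate, peak_rate]`` by construction.
    """

    neuron_id: str
    preferred_vector: tuple[float, float]  # (amplitude deg, direction deg)
    spatial_center: tuple[float, float]    # (x, y) deg
    spatial_sigma: float                   # deg
    peak_rate: float                       # spikes/s
    baseline_rate: float                   # spikes/s
    temporal_peak: float                   # ms relative to saccade onset
    temporal_sigma: float                  # ms
    snapshot_offset: float = 0.0           # tau, ms relative to saccade landing

    def __post_init__(self) -> None:
        if self.spatial_sigma <= 0:
            raise ValueError("spatial_sigma must be > 0")
        if self.temporal_sigma <= 0:
            raise ValueError("temporal_sigma must be > 0")
        if not (self.peak_rate >= self.baseline_rate >= 0):
            raise ValueError("need peak_rate >= baseline_rate >= 0")


@dataclass(frozen=True)
class SessionConfig:
    """Conditions of one simulated recording session.

    Defaults reproduce the study conditions: 105 neurons, 10 trials per
    stationary target position, 15 per motion direction, 10 deg/s targets,
    saccade latency 134 +/- 44 ms and duration 36 +/- 8.9 ms, and endpoint
    scatter of 0.8 deg (matching the observed intercept-residual spread).
    """

    n_neurons: int = 105
    n_regular_per_position: int = 10
    n_interceptive_per_direction: int = 15
    target_speed: float = 10.0        # deg/s
    latency_mean: float = 134.0       # ms
    latency_sd: float = 44.0
    duration_mean: float = 36.0       # ms
    duration_sd: float = 8.9
    endpoint_noise_sd: float = 0.8    # deg, isotropic
    fixation_point: tuple[float, float] = (0.0, 7.0)
    trace_noise_sd: float = 0.05      # deg, white positional noise on the eye trace
    seed: int = 0

    def validate(self) -> list[str]:
        issues = []
        for name in ("n_neurons", "n_regular_per_position", "n_interceptive_per_direction"):
            if getattr(self, name) < 0:
                issues.append(f"{name} must be >= 0")
        if self.n_regular_per_position < 1 and self.n_interceptive_per_direction < 1:
            issues.append("need at least one trial type with >= 1 trials")
        if self.target_speed <= 0:
            issues.append("target_speed must be > 0")
        if self.latency_mean <= 0 or self.latency_sd < 0:
            issues.append("latency parameters must be positive")
        if self.duration_mean <= 0 or self.duration_sd < 0:
            issues.append("duration parameters must be positive")
        if self.endpoint_noise_sd < 0 or self.trace_noise_sd < 0:
            issues.append("noise SDs must be >= 0")
        return issues


@dataclass
class TrialRecord:
    """One behavioral trial with eye trace, target path and spike trains.

    Times are ms relative to the target step (= motion onset for interceptive
    trials).  ``eye_trace[i]`` is the eye position at ``trace_t0 + i`` ms.
    ``spike_times[j]`` lists spike times of neuron j on this trial.
    ``ground_truth`` carries the generating saccade event for oracle tests.
    """

    trial_id: str
    condition: str                      # "regular" | "interceptive"
    target_position: tuple[float, float] | None   # regular trials
    motion_direction: float | None      # deg, interceptive trials
    target_speed: float
    fixation_point: tuple[float, float]
    trace_t0: float                     # ms of eye_trace[0]
    eye_trace: np.ndarray               # (n_samples, 2) deg, 1 ms sampling
    spike_times: list[np.ndarray] = field(default_factory=list)
    ground_truth: SaccadeEvent | None = None

    def target_path(self, t: np.ndarray | float) -> np.ndarray:
        """Target position (deg) at time(s) t (ms from target step)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        pos = np.empty((t.size, 2))
        pre = t < 0
        pos[pre] = self.fixation_point
        if self.condition == "regular":
            pos[~pre] = self.target_position
        else:
            u = _unit(self.motion_direction)
            pos[~pre] = u * (self.target_speed * t[~pre, None] / 1000.0)
        return pos if pos.shape[0] > 1 else pos[0]


def stationary_target_layout() -> np.ndarray:
    """The 17 stationary target positions: center plus 8 directions x {2, 4} deg.

    Returns an array of shape (17, 2); the center (0, 0) comes first, then the
    2-deg ring and the 4-deg ring in counter-clockwise order from +x.
    """
    pts = [(0.0, 0.0)]
    for r in (2.0, 4.0):
        for d in RING_DIRECTIONS:
            u = _unit(d)
            pts.append((r * u[0], r * u[1]))
    return np.array(pts)


def interceptive_directions() -> tuple[float, ...]:
    """The 8 target-motion directions (deg CCW from +x)."""
    return RING_DIRECTIONS


def neuron_rate(
    spec: NeuronSpec,
    endpoint: Sequence[float],
    t: float | np.ndarray,
    condition: str = "regular",
    *,
    motion_direction: float | None = None,
    target_speed: float | None = None,
) -> np.ndarray | float:
    """Instantaneous firing rate (spikes/s) for a saccade landing at ``endpoint``.

    ``t`` is ms relative to saccade onset.  For the interceptive condition the
    motion direction and target speed must be given; the neuron's spatial
    tuning is then referenced to the target's position ``tau`` ms from the
    saccade landing and its temporal profile is delayed by ``-tau`` (see
    module docstring).
    """
    endpoint = np.asarray(endpoint, dtype=float)
    t = np.asarray(t, dtype=float)
    t_peak = spec.temporal_peak
    if condition == "interceptive":
        if motion_direction is None or target_speed is None:
            raise ValueError("interceptive condition needs motion_direction and target_speed")
        shift = _unit(motion_direction) * (target_speed * spec.snapshot_offset / 1000.0)
        endpoint = endpoint + shift
        t_peak = spec.temporal_peak - spec.snapshot_offset
    elif condition != "regular":
        raise ValueError(f"unknown condition {condition!r}")
    d2 = float(np.sum((endpoint - np.asarray(spec.spatial_center)) ** 2))
    g_space = math.exp(-d2 / (2.0 * spec.spatial_sigma**2))
    g_time = np.exp(-((t - t_peak) ** 2) / (2.0 * spec.temporal_sigma**2))
    rate = spec.baseline_rate + (spec.peak_rate - spec.baseline_rate) * g_space * g_time
    return rate if rate.ndim else float(rate)


def _min_jerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1] (0 at 0, 1 at 1, zero end velocity)."""
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _draw_positive(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    """Normal draw redrawn until above ``lo`` (keeps the stated mean/sd scale)."""
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > lo:
            return float(v)
    return float(lo + sd)  # pragma: no cover - pathological configs only


def _synth_trace(
    fp: np.ndarray,
    endpoint: np.ndarray,
    onset: float,
    offset: float,
    t0: float,
    t1: float,
    pursuit_vel: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    t = np.arange(t0, t1 + 1.0)
    trace = np.empty((t.size, 2))
    pre = t < onset
    dur = offset - onset
    sacc = (~pre) & (t <= offset)
    post = t > offset
    trace[pre] = fp
    u = (t[sacc] - onset) / dur
    trace[sacc] = fp + _min_jerk(u)[:, None] * (endpoint - fp)
    trace[post] = endpoint + pursuit_vel * ((t[post] - offset)[:, None] / 1000.0)
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, trace.shape)
    return trace


def _spike_train(
    spec: NeuronSpec,
    endpoint: np.ndarray,
    onset: float,
    t0: float,
    t1: float,
    condition: str,
    motion_direction: float | None,
    target_speed: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous Poisson spike times (ms, trial clock) by thinning.

    Thinning against the per-trial rate bound (baseline + spatial-gain
    amplitude) is exact for the generative rate model.
    """
    # spatial gain is constant within a trial, so precompute the bound
    amp_probe = neuron_rate(
        spec, endpoint, spec.temporal_peak - (spec.snapshot_offset if condition == "interceptive" else 0.0),
        condition, motion_direction=motion_direction, target_speed=target_speed,
    )
    bound = max(float(amp_probe), spec.baseline_rate, 1e-12)
    span_s = (t1 - t0) / 1000.0
    n = rng.poisson(bound * span_s)
    if n == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(t0, t1, n))
    rate = neuron_rate(
        spec, endpoint, cand - onset, condition,
        motion_direction=motion_direction, target_speed=target_speed,
    )
    keep = rng.uniform(0.0, 1.0, n) < np.asarray(rate) / bound
    return cand[keep]


def simulate_session(cohort: Sequence[NeuronSpec], cfg: SessionConfig) -> list[TrialRecord]:
    """Simulate a full session of regular and interceptive trials.

    Regular trials land at the stepped target plus isotropic endpoint noise;
    interceptive trials land at the target's position at saccade end plus the
    same noise, so the intercept grows with saccade-end time at a slope equal
    to the target speed by construction.  Randomness is hierarchically seeded
    (session seed -> per-trial -> per-neuron substreams), so the behavior of
    trial i is unchanged when neurons are added to the cohort.
    """
    issues = cfg.validate()
    if issues:
        raise ValueError("invalid SessionConfig: " + "; ".join(issues))
    fp = np.asarray(cfg.fixation_point, dtype=float)
    trials: list[TrialRecord] = []
    schedule: list[tuple[str, object]] = []
    for pos in stationary_target_layout():
        schedule.extend(("regular", tuple(pos)) for _ in range(cfg.n_regular_per_position))
    for d in interceptive_directions():
        schedule.extend(("interceptive", d) for _ in range(cfg.n_interceptive_per_direction))

    for idx, (condition, info) in enumerate(schedule):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1, idx]))
        latency = _draw_positive(rng, cfg.latency_mean, cfg.latency_sd, 50.0)
        duration = _draw_positive(rng, cfg.duration_mean, cfg.duration_sd, 12.0)
        onset, offset = latency, latency + duration
        noise = rng.normal(0.0, cfg.endpoint_noise_sd, 2)
        if condition == "regular":
            target = np.asarray(info, dtype=float)
            endpoint = target + noise
            pursuit = np.zeros(2)
            motion_dir = None
        else:
            motion_dir = float(info)
            u = _unit(motion_dir)
            endpoint = u * (cfg.target_speed * offset / 1000.0) + noise
            pursuit = u * cfg.target_speed
            target = None
        t0 = -500.0
        t1 = math.ceil(offset + 500.0)
        trace = _synth_trace(fp, endpoint, onset, offset, t0, t1, pursuit,
                             cfg.trace_noise_sd, rng)
        gt = SaccadeEvent(
            onset=onset, offset=offset,
            pre_position=tuple(fp), post_position=tuple(endpoint),
            latency=latency, duration=duration, end_time=offset,
        )
        spikes = [
            _spike_train(
                spec, endpoint, onset, t0, t1, condition, motion_dir, cfg.target_speed,
                np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, idx, j])),
            )
            for j, spec in enumerate(cohort)
        ]
        trials.append(TrialRecord(
            trial_id=f"t{idx:05d}", condition=condition,
            target_position=None if target is None else tuple(target),
            motion_direction=motion_dir, target_speed=cfg.target_speed,
            fixation_point=tuple(fp), trace_t0=t0, eye_trace=trace,
            spike_times=spikes, ground_truth=gt,
        ))
    return trials


def make_cohort(
    n_neurons: int = 105,
    seed: int = 0,
    tau: float = 0.0,
    *,
    extent: float = 4.0,
    fixation_point: tuple[float, float] = (0.0, 7.0),
) -> list[NeuronSpec]:
    """Draw a cohort of spatially tuned neurons covering the +/-``extent`` area.

    Tuning centers are uniform over the square, widths and rates span the
    range typical of peri-saccadic parietal responses (peaks tens of spikes/s
    over a few-spikes/s baseline, activation peaking near saccade onset).  All
    neurons share the snapshot offset ``tau`` (ms relative to landing); pass
    per-neuron values by calling :func:`dataclasses.replace` afterwards.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    fp = np.asarray(fixation_point, dtype=float)
    cohort = []
    for j in range(n_neurons):
        center = rng.uniform(-extent, extent, 2)
        amp_vec = center - fp
        cohort.append(NeuronSpec(
            neuron_id=f"n{j:03d}",
            preferred_vector=(float(np.hypot(*amp_vec)),
                              float(math.degrees(math.atan2(amp_vec[1], amp_vec[0])) % 360.0)),
            spatial_center=(float(center[0]), float(center[1])),
            spatial_sigma=float(rng.uniform(1.2, 2.2)),
            peak_rate=float(rng.uniform(25.0, 70.0)),
            baseline_rate=float(rng.uniform(2.0, 8.0)),
            temporal_peak=float(rng.normal(0.0, 15.0)),
            temporal_sigma=float(rng.uniform(45.0, 75.0)),
            snapshot_offset=float(tau),
        ))
    return cohort
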