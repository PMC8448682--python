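"""Saccade detection and behavioral statistics.

Implements the oculomotor processing chain: a 15 ms moving-average smoother,
a double velocity-criterion saccade detector (100 deg/s trigger, 30 deg/s
onset/offset bounds), the intercept statistic (projection of the saccade
end-position onto the target-motion direction), its regression on saccade-end
time with a bootstrap confidence interval, 2-D Gaussian endpoint fits, and
the preferred-vs-anti-preferred selectivity t-test used for neuron inclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SaccadeEvent",
    "InterceptSample",
    "RegressionResult",
    "EndpointEllipse",
    "SelectivityResult",
    "smooth_trace",
    "trace_speed",
    "detect_saccade",
    "intercept",
    "intercept_samples",
    "intercept_time_regression",
    "fit_endpoint_gaussian",
    "selectivity_test",
]


@dataclass(frozen=True)
class SaccadeEvent:
    """A detected (or generated) saccade.

    Times are ms on the trial clock (0 = target step / motion onset);
    ``latency`` is onset time from the target step, ``end_time`` the offset
    time from motion onset.  ``pre_position`` / ``post_position`` are the
    fixation estimates in the windows 6-16 ms before onset and 2-4 ms after
    offset.
    """

    onset: float
    offset: float
    pre_position: tuple[float, float]
    post_position: tuple[float, float]
    latency: float
    duration: float
    end_time: float

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must be > onset")


@dataclass(frozen=True)
class InterceptSample:
    """Post-saccadic position projected on the target-motion direction.

    ``intercept = x*cos(alpha) + y*sin(alpha)`` with alpha the motion
    direction in degrees; ``t_end`` is the saccade-end time in ms from motion
    onset.
    """

    x: float
    y: float
    alpha: float
    t_end: float

    @property
    def intercept(self) -> float:
        return intercept(self.x, self.y, self.alpha)


def smooth_trace(trace: np.ndarray, span: int = 15) -> np.ndarray:
    """Centered moving average with the window truncated at the trace edges.

    ``trace`` is (n, 2) at uniform 1 ms sampling (a 1-D array is treated as a
    single channel).  The output has the same length as the input.
    """
    span = int(span)
    if span < 1:
        raise ValueError("span must be >= 1 ms")
    x = np.asarray(trace, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    kernel = np.ones(span)
    counts = np.convolve(np.ones(x.shape[0]), kernel, mode="same")
    out = np.empty_like(x)
    for c in range(x.shape[1]):
        out[:, c] = np.convolve(x[:, c], kernel, mode="same") / counts
    return out[:, 0] if squeeze else out


def trace_speed(trace: np.ndarray) -> np.ndarray:
    """2-D eye speed (deg/s) by central differences on a 1 ms-sampled trace."""
    x = np.asarray(trace, dtype=float)
    vel = np.gradient(x, axis=0) * 1000.0  # deg/ms -> deg/s
    return np.hypot(vel[:, 0], vel[:, 1])


def detect_saccade(
    trace: np.ndarray,
    t0: float = 0.0,
    *,
    trigger: float = 100.0,
    bound: float = 30.0,
) -> SaccadeEvent | None:
    """Detect the first saccade in a smoothed eye trace.

    The double velocity criterion: find the first sample whose speed exceeds
    ``trigger``; the onset is the last preceding sample with speed below
    ``bound`` (walking backward), the offset the first subsequent sample with
    speed below ``bound``.  Returns None if no saccade is found or the
    position windows fall outside the trace.  ``t0`` is the time (ms, trial
    clock) of the first trace sample; latency is the onset time relative to
    the target step at t = 0.
    """
    speed = trace_speed(trace)
    above = np.nonzero(speed > trigger)[0]
    if above.size == 0:
        return None
    i_hi = int(above[0])
    below_before = np.nonzero(speed[:i_hi] < bound)[0]
    if below_before.size == 0:
        return None
    onset = int(below_before[-1])
    below_after = np.nonzero(speed[i_hi:] < bound)[0]
    if below_after.size == 0:
        return None
    offset = i_hi + int(below_after[0])
    if onset - 16 < 0 or offset + 4 >= trace.shape[0]:
        return None
    pre = trace[onset - 16 : onset - 5].mean(axis=0)
    post = trace[offset + 2 : offset + 5].mean(axis=0)
    onset_t = t0 + onset
    offset_t = t0 + offset
    return SaccadeEvent(
        onset=onset_t,
        offset=offset_t,
        pre_position=(float(pre[0]), float(pre[1])),
        post_position=(float(post[0]), float(post[1])),
        latency=onset_t,
        duration=offset_t - onset_t,
        end_time=offset_t,
    )


def intercept(x: float, y: float, alpha: float) -> float:
    """Orthogonal projection of (x, y) onto the direction ``alpha`` (deg)."""
    a = math.radians(alpha)
    return x * math.cos(a) + y * math.sin(a)


def intercept_samples(events, alphas) -> list[InterceptSample]:
    """Build intercept samples from saccade events and their motion directions."""
    return [
        InterceptSample(x=ev.post_position[0], y=ev.post_position[1],
                        alpha=float(a), t_end=ev.end_time)
        for ev, a in zip(events, alphas)
    ]


@dataclass(frozen=True)
class RegressionResult:
    """OLS of intercept on saccade-end time with bootstrap confidence bands.

    ``slope`` is in deg/s (time regressor in seconds), ``offset`` in deg; the
    confidence intervals are percentile intervals (0.5 / 99.5 by default,
    i.e. p = 0.01) over trial-level bootstrap resamples.
    """

    slope: float
    offset: float
    pearson_r: float
    ci_slope: tuple[float, float]
    ci_offset: tuple[float, float]
    n: int
    n_boot: int

    def summary(self) -> str:
        return (
            f"intercept ~ t_end OLS (n={self.n})\n"
            f"  slope   {self.slope:8.3f} deg/s   CI99 [{self.ci_slope[0]:.3f}, {self.ci_slope[1]:.3f}]\n"
            f"  offset  {self.offset:8.3f} deg     CI99 [{self.ci_offset[0]:.3f}, {self.ci_offset[1]:.3f}]\n"
            f"  pearson r = {self.pearson_r:.3f}"
        )


def _ols_line(t_s: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    tm, ym = t_s.mean(), y.mean()
    dt = t_s - tm
    slope = float(dt @ (y - ym) / (dt @ dt))
    return slope, float(ym - slope * tm)


def intercept_time_regression(
    samples,
    n_boot: int = 2000,
    seed: int = 0,
    ci_percentiles: tuple[float, float] = (0.5, 99.5),
) -> RegressionResult:
    """Regress the intercept on the saccade-end time.

    ``samples`` is a sequence of :class:`InterceptSample` (or any objects with
    ``intercept`` and ``t_end``).  Returns slope (deg/s), offset (deg), the
    Pearson correlation, and percentile bootstrap CIs from trial-level
    resampling.
    """
    y = np.array([s.intercept for s in samples], dtype=float)
    t = np.array([s.t_end for s in samples], dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(t) == 0:
        raise ValueError("t_end has no variance")
    t_s = t / 1000.0
    slope, offset = _ols_line(t_s, y)
    r = float(np.corrcoef(t_s, y)[0, 1])

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, y.size, size=(n_boot, y.size))
    tb, yb = t_s[idx], y[idx]
    tbm = tb.mean(axis=1, keepdims=True)
    ybm = yb.mean(axis=1, keepdims=True)
    dt = tb - tbm
    denom = np.einsum("ij,ij->i", dt, dt)
    ok = denom > 0  # degenerate resamples (all-equal t) are dropped
    slopes = np.einsum("ij,ij->i", dt, yb - ybm)[ok] / denom[ok]
    offsets = (ybm[ok, 0] - slopes * tbm[ok, 0])
    lo, hi = ci_percentiles
    return RegressionResult(
        slope=slope, offset=offset, pearson_r=r,
        ci_slope=tuple(np.percentile(slopes, [lo, hi])),
        ci_offset=tuple(np.percentile(offsets, [lo, hi])),
        n=int(y.size), n_boot=int(n_boot),
    )


@dataclass(frozen=True)
class EndpointEllipse:
    """Sample mean and covariance of saccade endpoints, with the 1-SD ellipse."""

    mean: tuple[float, float]
    cov: np.ndarray
    sd_major: float
    sd_minor: float
    angle_deg: float   # orientation of the major axis, CCW from +x
    singular: bool
    n: int


def fit_endpoint_gaussian(endpoints: np.ndarray) -> EndpointEllipse:
    """Fit a 2-D Gaussian (mean + covariance) to saccade endpoints.

    The 1-SD contour of the fitted Gaussian is reported via its principal-axis
    standard deviations and orientation.  A (near-)singular covariance, e.g.
    from collinear points, is flagged rather than raised.
    """
    pts = np.asarray(endpoints, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) endpoints")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    singular = bool(evals[0] <= 1e-10 * max(evals[1], 1e-30))
    major = evecs[:, 1]
    return EndpointEllipse(
        mean=(float(mean[0]), float(mean[1])),
        cov=cov,
        sd_major=float(np.sqrt(evals[1])),
        sd_minor=float(np.sqrt(evals[0])),
        angle_deg=float(math.degrees(math.atan2(major[1], major[0])) % 180.0),
        singular=singular,
        n=pts.shape[0],
    )


@dataclass(frozen=True)
class SelectivityResult:
    p_value: float
    include: bool
    degenerate: bool = False


def selectivity_test(
    counts_pref,
    counts_anti,
    alpha: float = 0.01,
) -> SelectivityResult:
    """Two-sample t-test of peri-saccadic spike counts, preferred vs anti-preferred.

    A neuron is included when p < ``alpha`` (0.01).  Zero variance on both
    sides makes the test undefined: the neuron is excluded with the
    ``degenerate`` flag set.
    """
    a = np.asarray(counts_pref, dtype=float)
    b = np.asarray(counts_anti, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 trials per side")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return SelectivityResult(p_value=float("nan"), include=False, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return SelectivityResult(p_value=float(p), include=bool(p < alpha))
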