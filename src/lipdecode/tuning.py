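"""Spatio-temporal tuning fields and regular/interceptive similarity.

Each neuron's trial-averaged, Gaussian-smoothed (sigma = 20 ms) firing rate
is anchored at the measured saccade end-positions of its trial groups and
interpolated over a fixed spatial grid (+/-4 deg in 0.1 deg steps) and a
peri-saccadic time grid (-400 ... +350 ms in 10 ms steps): piecewise-linear
interpolation inside the convex hull of the anchors, nearest-anchor value
outside it.  Activity maps averaged over a peri-saccadic window are compared
between conditions with a Pearson correlation and a similarity index

    SI = 1 - ||z(R) - z(I)||_F / (||z(R)||_F + ||z(I)||_F)

where z(.) standardizes a map entrywise and ||.||_F is the Frobenius norm.
SI lies in [0, 1] and equals 1 only for identical standardized maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError

__all__ = [
    "GRID_X",
    "GRID_Y",
    "GRID_T",
    "TuningField",
    "SimilarityResult",
    "response_function",
    "build_tuning_field",
    "window_average",
    "window_maps",
    "similarity_index",
    "select_subpopulation",
    "disk_mask",
]

GRID_X = np.round(np.arange(-40, 41) * 0.1, 10)          # -4 ... +4 deg, 81 samples
GRID_Y = GRID_X.copy()
GRID_T = np.arange(-400.0, 351.0, 10.0)                  # 76 samples

#: radius (deg) of the central comparison disk for similarity maps; the
#: interceptive saccades only cover ~1.5 deg around the center, so profile
#: comparisons are restricted to this region.
SIMILARITY_RADIUS = 1.5


def response_function(
    spike_times_per_trial,
    sigma: float = 20.0,
    grid_t: np.ndarray = GRID_T,
) -> np.ndarray:
    """Trial-averaged smoothed firing rate (spikes/s) on ``grid_t``.

    Spike times are ms relative to saccade onset.  Each spike contributes a
    unit-area Gaussian (sigma in ms, truncated at 4 sigma, spikes/ms), the
    per-trial sums are scaled by 1000 to spikes/s and averaged over trials.
    """
    n_trials = len(spike_times_per_trial)
    if n_trials == 0:
        raise ValueError("need at least one trial")
    spikes = [np.asarray(s, dtype=float) for s in spike_times_per_trial]
    all_spikes = np.concatenate(spikes) if spikes else np.empty(0)
    out = np.zeros(len(grid_t))
    if all_spikes.size:
        dt = grid_t[None, :] - all_spikes[:, None]
        k = np.exp(-(dt**2) / (2.0 * sigma**2))
        k[np.abs(dt) > 4.0 * sigma] = 0.0
        out = k.sum(axis=0) / (sigma * np.sqrt(2.0 * np.pi))
    return out * 1000.0 / n_trials


@dataclass
class TuningField:
    """One neuron's interpolated activity over (x, y, t) for one condition.

    ``activity[i, j, k]`` is the rate (spikes/s) at ``(grid_x[i], grid_y[j],
    grid_t[k])``.  ``anchors`` are the (n, 2) saccade end-positions the field
    was interpolated from, ``n_trials_per_anchor`` the trial counts behind
    each anchor's response function.
    """

    neuron_id: str
    condition: str
    grid_x: np.ndarray
    grid_y: np.ndarray
    grid_t: np.ndarray
    activity: np.ndarray          # (nx, ny, nt)
    anchors: np.ndarray           # (n_anchors, 2)
    n_trials_per_anchor: np.ndarray


def _interpolate_anchor_values(
    anchors: np.ndarray,
    values: np.ndarray,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
) -> np.ndarray:
    """Linear-in-hull / nearest-outside interpolation of per-anchor values.

    ``values`` is (n_anchors, ...); the result is (nx, ny, ...).
    """
    anchors = np.asarray(anchors, dtype=float)
    values = np.asarray(values, dtype=float)
    if anchors.shape[0] < 3:
        raise ValueError("need at least 3 anchor positions")
    try:
        lin = LinearNDInterpolator(anchors, values)
    except QhullError as err:
        raise ValueError("anchor positions are collinear") from err
    near = NearestNDInterpolator(anchors, values)
    gx, gy = np.meshgrid(grid_x, grid_y, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    out = lin(pts)
    bad = np.isnan(out)
    if bad.any():
        fill = near(pts)
        out = np.where(bad, fill, out)
    return out.reshape(gx.shape + values.shape[1:])


def build_tuning_field(
    anchors: np.ndarray,
    anchor_responses: np.ndarray,
    *,
    neuron_id: str = "",
    condition: str = "",
    n_trials_per_anchor=None,
    grid_x: np.ndarray = GRID_X,
    grid_y: np.ndarray = GRID_Y,
    grid_t: np.ndarray = GRID_T,
) -> TuningField:
    """Interpolate per-anchor response functions into a full tuning field.

    ``anchor_responses`` has shape (n_anchors, nt) with each row the smoothed
    trial-averaged rate at that anchor.  Raises ValueError for collinear or
    too few anchors.
    """
    anchor_responses = np.asarray(anchor_responses, dtype=float)
    anchors = np.asarray(anchors, dtype=float)
    if anchor_responses.shape[0] != anchors.shape[0]:
        raise ValueError("one response function per anchor required")
    activity = _interpolate_anchor_values(anchors, anchor_responses, grid_x, grid_y)
    if n_trials_per_anchor is None:
        n_trials_per_anchor = np.ones(anchors.shape[0], dtype=int)
    return TuningField(
        neuron_id=neuron_id, condition=condition,
        grid_x=grid_x, grid_y=grid_y, grid_t=np.asarray(grid_t, dtype=float),
        activity=activity, anchors=anchors,
        n_trials_per_anchor=np.asarray(n_trials_per_anchor),
    )


def window_average(field: TuningField, t_lo: float = -100.0, t_hi: float = 100.0) -> np.ndarray:
    """Average the field activity over grid times with t_lo <= t <= t_hi (inclusive)."""
    mask = (field.grid_t >= t_lo) & (field.grid_t <= t_hi)
    if not mask.any():
        raise ValueError("empty time window")
    return field.activity[:, :, mask].mean(axis=2)


def window_maps(field: TuningField, windows) -> np.ndarray:
    """Stack of window-averaged spatial maps, shape (nx, ny, n_windows)."""
    return np.stack([window_average(field, lo, hi) for lo, hi in windows], axis=-1)


@dataclass(frozen=True)
class SimilarityResult:
    """Similarity between a regular and an interceptive activity map."""

    pearson_r: float
    si: float
    window: tuple[float, float] = (-100.0, 100.0)


def disk_mask(
    radius: float = SIMILARITY_RADIUS,
    grid_x: np.ndarray = GRID_X,
    grid_y: np.ndarray = GRID_Y,
) -> np.ndarray:
    """Boolean mask of grid nodes within ``radius`` deg of the screen center."""
    gx, gy = np.meshgrid(grid_x, grid_y, indexing="ij")
    return gx**2 + gy**2 <= radius**2


def similarity_index(
    map_regular: np.ndarray,
    map_interceptive: np.ndarray,
    *,
    mask: np.ndarray | None = None,
    window: tuple[float, float] = (-100.0, 100.0),
    standardize: str = "full",
) -> SimilarityResult:
    """Pearson correlation and similarity index between two activity maps.

    ``standardize='full'`` z-scores each map entrywise (mean removed, divided
    by the population SD) before the Frobenius-distance index; ``'scale'``
    divides by the SD only, keeping mean-rate differences visible in the
    index.  Constant maps have an undefined z-transform and raise ValueError.
    An optional boolean ``mask`` restricts the comparison region (e.g. the
    central disk actually covered by interceptive saccades).
    """
    r_map = np.asarray(map_regular, dtype=float)
    i_map = np.asarray(map_interceptive, dtype=float)
    if r_map.shape != i_map.shape:
        raise ValueError("maps must have the same shape")
    if mask is not None:
        r_map = r_map[mask]
        i_map = i_map[mask]
    r_flat = r_map.ravel()
    i_flat = i_map.ravel()
    if np.std(r_flat) == 0 or np.std(i_flat) == 0:
        raise ValueError("constant map: z-transform undefined")

    def z(v: np.ndarray) -> np.ndarray:
        if standardize == "full":
            return (v - v.mean()) / v.std()
        if standardize == "scale":
            return v / v.std()
        raise ValueError("standardize must be 'full' or 'scale'")

    zr, zi = z(r_flat), z(i_flat)
    si = 1.0 - np.linalg.norm(zr - zi) / (np.linalg.norm(zr) + np.linalg.norm(zi))
    pearson = float(np.corrcoef(r_flat, i_flat)[0, 1])
    return SimilarityResult(pearson_r=pearson, si=float(si), window=window)


def select_subpopulation(
    similarities: dict[str, SimilarityResult],
    r_min: float = 0.5,
    si_min: float = 0.3,
) -> list[str]:
    """Neurons whose profiles satisfy r > r_min AND SI > si_min (strict)."""
    return [nid for nid, s in similarities.items()
            if s.pearson_r > r_min and s.si > si_min]
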