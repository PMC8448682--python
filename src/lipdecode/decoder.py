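"""Poisson pseudo-populations and the shallow-network end-position decoder.

The decoding chain: stratified 70/30 trial splits, expected spike counts read
off each neuron's tuning field in a peri-saccadic window, pseudo-trials drawn
as independent Poisson counts at uniformly random end-positions, a shallow
feed-forward regressor (two tanh hidden layers of 20 units, linear output,
quasi-Newton least-squares training) mapping count vectors to (x, y), and the
evaluation statistics: nearest-position confusion matrices over the 8 tested
positions, center bias (intercept of the tested position minus intercept of
the prediction), continuous error fields, and sliding-window time courses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import RegularGridInterpolator
from sklearn.neural_network import MLPRegressor

from .oculomotor import intercept
from .tuning import TuningField, window_average

__all__ = [
    "PseudoTrialSet",
    "DecoderModel",
    "DecodeEvaluation",
    "SlidingWindowResult",
    "split_trials",
    "expected_count",
    "expected_count_matrix",
    "generate_pseudo_trials",
    "train_decoder",
    "predict_endpoints",
    "assign_nearest",
    "evaluate_predictions",
    "percent_correct",
    "percent_correct_or_neighbor",
    "center_bias",
    "error_field",
    "sliding_windows",
    "sliding_window_analysis",
    "bias_to_time_lag",
]


# ---------------------------------------------------------------------------
# trial splitting


def split_trials(
    anchor_labels,
    train_frac: float = 0.7,
    n_repeats: int = 50,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified train/validation index splits, repeated ``n_repeats`` times.

    ``anchor_labels`` assigns each trial to its anchor position (any hashable
    label).  Within each repeat and each anchor the trials are partitioned
    disjointly with ``round(n * train_frac)`` training trials (at least one on
    each side).  Reproducible from ``seed``.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    labels = list(anchor_labels)
    groups: dict[object, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    for lab, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"anchor {lab!r} has fewer than 2 trials")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_repeats):
        train, val = [], []
        for lab in groups:
            idx = np.array(groups[lab])
            perm = rng.permutation(idx.size)
            n_train = int(math.floor(idx.size * train_frac + 0.5))
            n_train = min(max(n_train, 1), idx.size - 1)
            train.extend(idx[perm[:n_train]])
            val.extend(idx[perm[n_train:]])
        splits.append((np.sort(np.array(train)), np.sort(np.array(val))))
    return splits


# ---------------------------------------------------------------------------
# expected counts and pseudo-trials


def _window_duration_s(window: tuple[float, float]) -> float:
    t_lo, t_hi = window
    if t_hi <= t_lo:
        raise ValueError("window must have t_hi > t_lo")
    return (t_hi - t_lo) / 1000.0


def expected_count(
    field: TuningField,
    position,
    window: tuple[float, float] = (-100.0, 100.0),
) -> float:
    """Mean expected spike count of a neuron for a saccade to ``position``.

    The mean rate over the window (inclusive grid samples) times the window
    duration in seconds.  Positions outside the field grid raise ValueError.
    """
    rate_map = window_average(field, *window)
    interp = RegularGridInterpolator(
        (field.grid_x, field.grid_y), rate_map, bounds_error=True
    )
    try:
        rate = float(interp(np.asarray(position, dtype=float))[0])
    except ValueError as err:
        raise ValueError(f"position {position} outside the field grid") from err
    return rate * _window_duration_s(window)


def expected_count_matrix(
    rate_maps: np.ndarray,
    positions: np.ndarray,
    window: tuple[float, float],
    grid_x: np.ndarray,
    grid_y: np.ndarray,
) -> np.ndarray:
    """Expected counts (n_positions, n_neurons) from stacked rate maps.

    ``rate_maps`` is (n_neurons, nx, ny), already window-averaged (spikes/s).
    """
    dur = _window_duration_s(window)
    positions = np.asarray(positions, dtype=float)
    out = np.empty((positions.shape[0], rate_maps.shape[0]))
    for j in range(rate_maps.shape[0]):
        interp = RegularGridInterpolator((grid_x, grid_y), rate_maps[j], bounds_error=True)
        out[:, j] = interp(positions)
    return out * dur


@dataclass
class PseudoTrialSet:
    """Poisson-resampled population trials with their generating positions."""

    counts: np.ndarray            # (n_trials, n_neurons) integer
    positions: np.ndarray         # (n_trials, 2) deg
    window: tuple[float, float]
    source_split: str = "train"
    seed: int = 0


def generate_pseudo_trials(
    rate_maps: np.ndarray,
    n: int = 100_000,
    window: tuple[float, float] = (-100.0, 100.0),
    seed: int = 0,
    *,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    positions: np.ndarray | None = None,
    extent: float = 4.0,
    source_split: str = "train",
) -> PseudoTrialSet:
    """Draw ``n`` Poisson pseudo-trials from window-averaged rate maps.

    End-positions are uniform over the +/-``extent`` square unless given
    explicitly; each neuron's count is an independent Poisson draw with mean
    equal to its expected count at that position.
    """
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = rng.uniform(-extent, extent, size=(n, 2))
    else:
        positions = np.asarray(positions, dtype=float)
        n = positions.shape[0]
    if n == 0:
        return PseudoTrialSet(
            counts=np.empty((0, rate_maps.shape[0]), dtype=int),
            positions=positions.reshape(0, 2), window=window,
            source_split=source_split, seed=seed,
        )
    lam = expected_count_matrix(rate_maps, positions, window, grid_x, grid_y)
    counts = rng.poisson(lam)
    return PseudoTrialSet(counts=counts, positions=positions, window=window,
                          source_split=source_split, seed=seed)


# ---------------------------------------------------------------------------
# decoder


@dataclass
class DecoderModel:
    """A trained end-position regressor with its input normalization.

    Inputs are standardized by the training-set mean/SD; the network has two
    tanh hidden layers of ``hidden`` units each and a linear 2-unit output.
    """

    net: MLPRegressor
    input_mean: np.ndarray
    input_sd: np.ndarray
    n_neurons: int
    seed: int
    n_iter: int
    converged: bool
    train_loss: float

    def predict(self, counts: np.ndarray) -> np.ndarray:
        return predict_endpoints(self, counts)


def train_decoder(
    pseudo: PseudoTrialSet,
    hidden: tuple[int, int] = (20, 20),
    seed: int = 0,
    max_iter: int = 400,
    tol: float = 1e-6,
) -> DecoderModel:
    """Train the shallow network on a pseudo-trial set (MSE loss).

    Uses a quasi-Newton least-squares trainer (lbfgs) with tanh hidden units
    and linear outputs; inputs are standardized by train-set mean/SD.
    """
    X = np.asarray(pseudo.counts, dtype=float)
    y = np.asarray(pseudo.positions, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite training inputs")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    net = MLPRegressor(
        hidden_layer_sizes=hidden,
        activation="tanh",
        solver="lbfgs",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    import warnings
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit((X - mean) / sd, y)
    return DecoderModel(
        net=net, input_mean=mean, input_sd=sd, n_neurons=X.shape[1], seed=seed,
        n_iter=int(net.n_iter_), converged=bool(net.n_iter_ < max_iter),
        train_loss=float(net.loss_),
    )


def predict_endpoints(model: DecoderModel, counts: np.ndarray) -> np.ndarray:
    """Predicted (x, y) per trial; rejects count vectors of the wrong length."""
    X = np.atleast_2d(np.asarray(counts, dtype=float))
    if X.shape[1] != model.n_neurons:
        raise ValueError(f"expected {model.n_neurons} neurons, got {X.shape[1]}")
    return model.net.predict((X - model.input_mean) / model.input_sd)


# ---------------------------------------------------------------------------
# evaluation statistics


def assign_nearest(predictions: np.ndarray, tested_positions: np.ndarray) -> np.ndarray:
    """Index of the nearest tested position per prediction (ties: lowest index)."""
    d2 = ((predictions[:, None, :] - tested_positions[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def _ring_order(tested_positions: np.ndarray) -> np.ndarray:
    """Positions sorted by polar angle; used to define direct neighbors."""
    ang = np.arctan2(tested_positions[:, 1], tested_positions[:, 0])
    return np.argsort(ang)


def _neighbor_sets(tested_positions: np.ndarray) -> list[set[int]]:
    order = _ring_order(tested_positions)
    k = len(order)
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    sets = []
    for i in range(k):
        r = rank[i]
        sets.append({i, int(order[(r - 1) % k]), int(order[(r + 1) % k])})
    return sets


def percent_correct(confusion: np.ndarray) -> float:
    """Mean of the confusion diagonal, as a percentage."""
    return float(np.mean(np.diag(confusion)) * 100.0)


def percent_correct_or_neighbor(confusion: np.ndarray, tested_positions: np.ndarray) -> float:
    """Percentage assigned to the true position or one of its two ring neighbors."""
    sets = _neighbor_sets(tested_positions)
    vals = [confusion[i, sorted(s)].sum() for i, s in enumerate(sets)]
    return float(np.mean(vals) * 100.0)


@dataclass
class DecodeEvaluation:
    """Per-position decoding statistics at the tested positions."""

    tested_positions: np.ndarray      # (k, 2)
    directions: np.ndarray            # (k,) deg, direction used for the intercept
    mean_prediction: np.ndarray       # (k, 2)
    sd_prediction: np.ndarray         # (k, 2)
    confusion: np.ndarray             # (k, k), rows sum to 1
    pct_correct: float
    pct_correct_or_neighbor: float
    center_bias_per_position: np.ndarray
    mean_center_bias: float
    mean_euclidean_error: float


def center_bias(tested_position, predicted_position, alpha: float) -> float:
    """Intercept of the tested position minus the intercept of the prediction.

    Positive values mean the prediction is compressed toward the screen
    center along the direction ``alpha`` (deg).
    """
    tx, ty = tested_position
    px, py = predicted_position
    return intercept(tx, ty, alpha) - intercept(px, py, alpha)


def evaluate_predictions(
    predictions_per_position,
    tested_positions: np.ndarray,
    directions: np.ndarray,
) -> DecodeEvaluation:
    """Summarize single-trial predictions grouped by their true tested position.

    ``predictions_per_position[i]`` is an (m_i, 2) array of predictions for
    trials whose true position is ``tested_positions[i]``; ``directions[i]``
    is the angle (deg) used for that position's intercept (the target-motion
    direction for interceptive positions).
    """
    tested_positions = np.asarray(tested_positions, dtype=float)
    directions = np.asarray(directions, dtype=float)
    k = tested_positions.shape[0]
    confusion = np.zeros((k, k))
    mean_pred = np.empty((k, 2))
    sd_pred = np.empty((k, 2))
    bias = np.empty(k)
    for i, preds in enumerate(predictions_per_position):
        preds = np.asarray(preds, dtype=float)
        assign = assign_nearest(preds, tested_positions)
        confusion[i] = np.bincount(assign, minlength=k) / preds.shape[0]
        mean_pred[i] = preds.mean(axis=0)
        sd_pred[i] = preds.std(axis=0)
        bias[i] = center_bias(tested_positions[i], mean_pred[i], directions[i])
    err = np.linalg.norm(mean_pred - tested_positions, axis=1)
    return DecodeEvaluation(
        tested_positions=tested_positions, directions=directions,
        mean_prediction=mean_pred, sd_prediction=sd_pred, confusion=confusion,
        pct_correct=percent_correct(confusion),
        pct_correct_or_neighbor=percent_correct_or_neighbor(confusion, tested_positions),
        center_bias_per_position=bias,
        mean_center_bias=float(bias.mean()),
        mean_euclidean_error=float(err.mean()),
    )


@dataclass
class ErrorField:
    """Mean prediction error vectors over a grid of tested positions.

    ``error[i] = tested[i] - mean prediction``; for predictions compressed
    toward the screen center the error vector points radially outward.
    """

    points: np.ndarray          # (k, 2)
    error: np.ndarray           # (k, 2) tested - predicted
    magnitude: np.ndarray       # (k,)
    direction_deg: np.ndarray   # (k,)
    n_draws: int

    def centripetal_mask(self) -> np.ndarray:
        """True where the prediction is displaced toward the center.

        Eccentric points only; the displacement (predicted - tested) must
        have a negative radial component, i.e. the error vector points
        outward along the position's radial direction.
        """
        r = np.linalg.norm(self.points, axis=1)
        with np.errstate(invalid="ignore"):
            radial = np.einsum("ij,ij->i", self.error, self.points) / np.where(r > 0, r, 1.0)
        return (r > 0) & (radial > 0)


def error_field(
    model: DecoderModel,
    rate_maps: np.ndarray,
    *,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    window: tuple[float, float] = (-100.0, 100.0),
    points: np.ndarray | None = None,
    extent: float = 1.5,
    step: float = 0.5,
    n_draws: int = 200,
    seed: int = 0,
) -> ErrorField:
    """Mean prediction error vectors at a grid of continuously tested positions.

    For each point, ``n_draws`` Poisson pseudo-trials are generated from the
    given rate maps and decoded; the error is tested minus mean prediction.
    """
    if points is None:
        ax = np.arange(-extent, extent + step / 2, step)
        gx, gy = np.meshgrid(ax, ax, indexing="ij")
        points = np.column_stack([gx.ravel(), gy.ravel()])
    points = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)
    lam = expected_count_matrix(rate_maps, points, window, grid_x, grid_y)
    err = np.empty_like(points)
    for i in range(points.shape[0]):
        counts = rng.poisson(lam[i], size=(n_draws, lam.shape[1]))
        preds = predict_endpoints(model, counts)
        err[i] = points[i] - preds.mean(axis=0)
    return ErrorField(
        points=points, error=err,
        magnitude=np.linalg.norm(err, axis=1),
        direction_deg=np.degrees(np.arctan2(err[:, 1], err[:, 0])) % 360.0,
        n_draws=n_draws,
    )


# ---------------------------------------------------------------------------
# sliding windows


def sliding_windows(
    t_min: float = -400.0,
    t_max: float = 350.0,
    width: float = 100.0,
    step: float = 50.0,
) -> list[tuple[float, float]]:
    """All ``width``-ms windows stepped by ``step`` inside [t_min, t_max]."""
    windows = []
    lo = t_min
    while lo + width <= t_max + 1e-9:
        windows.append((lo, lo + width))
        lo += step
    return windows


@dataclass
class SlidingWindowResult:
    """Center-bias and prediction-SD time courses for both saccade types.

    Arrays are indexed (window,) for the aggregates and (window, position)
    for the per-position values (averaged over splits); ``p_values`` holds
    the per-window paired t-test (across positions) comparing the regular and
    interceptive center bias.
    """

    windows: list[tuple[float, float]]
    centers: np.ndarray
    bias_regular: np.ndarray
    bias_interceptive: np.ndarray
    sd_regular: np.ndarray
    sd_interceptive: np.ndarray
    bias_regular_per_position: np.ndarray
    bias_interceptive_per_position: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    alpha: float = 0.01

    def minimum_lag_ms(self) -> float:
        """Time of the interceptive bias minimum minus the regular one."""
        c = self.centers
        return float(c[np.argmin(self.bias_interceptive)] - c[np.argmin(self.bias_regular)])


def sliding_window_analysis(
    train_maps_per_split,
    val_maps_per_split,
    interceptive_maps,
    *,
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    tested_positions: np.ndarray,
    directions: np.ndarray,
    windows=None,
    n_pseudo: int = 8000,
    n_eval: int = 100,
    seed: int = 0,
    hidden: tuple[int, int] = (20, 20),
    max_iter: int = 200,
    alpha: float = 0.01,
) -> SlidingWindowResult:
    """Retrain and evaluate the decoder in sliding peri-saccadic windows.

    ``train_maps_per_split`` / ``val_maps_per_split`` are lists (one entry per
    split) of arrays (n_neurons, nx, ny, n_windows) of window-averaged rates
    from the regular-condition fields; ``interceptive_maps`` has the same
    shape from the interceptive fields (no splitting).  For each window a
    decoder is trained on regular pseudo-trials and evaluated at the tested
    positions for both conditions; a paired t-test across the positions flags
    windows where the two center biases differ.
    """
    if windows is None:
        windows = sliding_windows()
    n_splits = len(train_maps_per_split)
    k = tested_positions.shape[0]
    n_w = len(windows)
    bias_r = np.empty((n_w, n_splits, k))
    bias_i = np.empty((n_w, n_splits, k))
    sd_r = np.empty((n_w, n_splits))
    sd_i = np.empty((n_w, n_splits))
    ss = np.random.SeedSequence([seed, 99])
    child = iter(ss.spawn(n_w * n_splits * 3))
    for w, window in enumerate(windows):
        for s in range(n_splits):
            train_maps = train_maps_per_split[s][..., w]
            val_maps = val_maps_per_split[s][..., w]
            int_maps = interceptive_maps[..., w]
            pseudo = generate_pseudo_trials(
                train_maps, n=n_pseudo, window=window,
                seed=next(child).generate_state(1)[0] % (2**31),
                grid_x=grid_x, grid_y=grid_y,
            )
            model = train_decoder(
                pseudo, hidden=hidden, max_iter=max_iter,
                seed=int(next(child).generate_state(1)[0] % (2**31)),
            )
            rng = np.random.default_rng(next(child))
            for cond, maps, bias_out, sd_out in (
                ("regular", val_maps, bias_r, sd_r),
                ("interceptive", int_maps, bias_i, sd_i),
            ):
                lam = expected_count_matrix(maps, tested_positions, window, grid_x, grid_y)
                sds = np.empty((k, 2))
                for i in range(k):
                    counts = rng.poisson(lam[i], size=(n_eval, lam.shape[1]))
                    preds = predict_endpoints(model, counts)
                    mp = preds.mean(axis=0)
                    sds[i] = preds.std(axis=0)
                    bias_out[w, s, i] = center_bias(tested_positions[i], mp, directions[i])
                sd_out[w, s] = float(sds.mean())
    # aggregate: mean over splits first (per-position), then over positions
    bias_r_pos = bias_r.mean(axis=1)
    bias_i_pos = bias_i.mean(axis=1)
    p_values = np.empty(n_w)
    for w in range(n_w):
        _, p = stats.ttest_rel(bias_r_pos[w], bias_i_pos[w])
        p_values[w] = p
    centers = np.array([(lo + hi) / 2.0 for lo, hi in windows])
    return SlidingWindowResult(
        windows=list(windows), centers=centers,
        bias_regular=bias_r_pos.mean(axis=1),
        bias_interceptive=bias_i_pos.mean(axis=1),
        sd_regular=sd_r.mean(axis=1),
        sd_interceptive=sd_i.mean(axis=1),
        bias_regular_per_position=bias_r_pos,
        bias_interceptive_per_position=bias_i_pos,
        p_values=p_values,
        significant=p_values < alpha,
        alpha=alpha,
    )


def bias_to_time_lag(bias: float, speed: float) -> float:
    """Convert a spatial center bias (deg) into a target-motion time lag (ms)."""
    if speed <= 0:
        raise ValueError("speed must be > 0")
    return 1000.0 * bias / speed
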