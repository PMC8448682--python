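"""Session-level model/results interface for the population decoding analysis.

:class:`SaccadeDecodingModel` is built from a list of behavioral trials with
spike trains (typically from :func:`lipdecode.synthetic.simulate_session`).
Construction runs the oculomotor stage (trace smoothing, saccade detection,
trial grouping by target position / motion direction); :meth:`fit` runs the
population-decoding stage (stratified 70/30 splits, tuning-field estimation,
Poisson pseudo-trial generation, network training, evaluation at the 8 mean
interceptive end-positions) and returns a :class:`SaccadeDecodingResults`
carrying the evaluation statistics and a ``summary()`` table.  Behavioral
statistics (intercept regression, endpoint ellipses), tuning-similarity
screening, continuous error fields and sliding-window time courses hang off
the same two objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import decoder as dec
from . import oculomotor as ocm
from . import tuning as tun

__all__ = ["SaccadeDecodingModel", "SaccadeDecodingResults"]


def _window_average_responses(responses: np.ndarray, grid_t: np.ndarray, windows) -> np.ndarray:
    """Average (..., nt) responses over each window; returns (..., n_windows)."""
    cols = []
    for lo, hi in windows:
        mask = (grid_t >= lo) & (grid_t <= hi)
        if not mask.any():
            raise ValueError("empty time window")
        cols.append(responses[..., mask].mean(axis=-1))
    return np.stack(cols, axis=-1)


class SaccadeDecodingModel:
    """Population decoding of saccade end-positions from peri-saccadic spikes.

    Parameters
    ----------
    trials
        Sequence of :class:`~lipdecode.synthetic.TrialRecord`-like objects
        (eye trace at 1 kHz, per-neuron spike times, condition and target
        metadata).
    smoothing_span
        Moving-average span (ms) applied to eye traces before detection.
    sigma
        Gaussian smoothing sigma (ms) for the spike-rate response functions.
    """

    def __init__(self, trials, *, smoothing_span: int = 15, sigma: float = 20.0,
                 grid_x=tun.GRID_X, grid_y=tun.GRID_Y, grid_t=tun.GRID_T):
        self.sigma = sigma
        self.grid_x = grid_x
        self.grid_y = grid_y
        self.grid_t = grid_t
        self.trials = []
        self.events = []
        self.n_dropped = 0
        for tr in trials:
            smoothed = ocm.smooth_trace(tr.eye_trace, smoothing_span)
            ev = ocm.detect_saccade(smoothed, t0=tr.trace_t0)
            if ev is None:
                self.n_dropped += 1
                continue
            self.trials.append(tr)
            self.events.append(ev)
        if not self.trials:
            raise ValueError("no trials with a detectable saccade")
        self.n_neurons = len(self.trials[0].spike_times)
        # spikes aligned to the detected saccade onset: aligned[i][j]
        self._aligned = [
            [np.asarray(tr.spike_times[j], dtype=float) - ev.onset
             for j in range(self.n_neurons)]
            for tr, ev in zip(self.trials, self.events)
        ]
        self._regular_idx = [i for i, t in enumerate(self.trials) if t.condition == "regular"]
        self._intercept_idx = [i for i, t in enumerate(self.trials) if t.condition == "interceptive"]
        self._regular_groups: dict[tuple, list[int]] = {}
        for i in self._regular_idx:
            self._regular_groups.setdefault(tuple(self.trials[i].target_position), []).append(i)
        self._intercept_groups: dict[float, list[int]] = {}
        for i in self._intercept_idx:
            self._intercept_groups.setdefault(float(self.trials[i].motion_direction), []).append(i)
        self.target_speed = self.trials[0].target_speed

    # -- behavioral statistics -------------------------------------------------

    def intercept_samples(self) -> list[ocm.InterceptSample]:
        events = [self.events[i] for i in self._intercept_idx]
        alphas = [self.trials[i].motion_direction for i in self._intercept_idx]
        return ocm.intercept_samples(events, alphas)

    def behavioral_regression(self, n_boot: int = 2000, seed: int = 0) -> ocm.RegressionResult:
        """Intercept-vs-saccade-end-time regression over the interceptive trials."""
        return ocm.intercept_time_regression(self.intercept_samples(), n_boot=n_boot, seed=seed)

    def endpoint_ellipses(self) -> dict[float, ocm.EndpointEllipse]:
        """2-D Gaussian endpoint fits per target-motion direction."""
        out = {}
        for d, idx in sorted(self._intercept_groups.items()):
            pts = np.array([self.events[i].post_position for i in idx])
            out[d] = ocm.fit_endpoint_gaussian(pts)
        return out

    # -- tuning fields ---------------------------------------------------------

    def _group_responses(self, trial_idx, neuron_idx) -> np.ndarray:
        """Smoothed trial-averaged response functions, shape (n_neurons, nt)."""
        return np.stack([
            tun.response_function([self._aligned[i][j] for i in trial_idx],
                                  sigma=self.sigma, grid_t=self.grid_t)
            for j in neuron_idx
        ])

    def _condition_maps(self, groups: dict, windows, neuron_idx, subset=None):
        """Window-averaged rate maps interpolated from group anchors.

        ``groups`` maps a label to trial indices; ``subset`` optionally
        restricts each group to the given global trial indices.  Returns
        (maps, anchors, labels) with maps of shape (n_neurons, nx, ny, n_w).
        Interpolating window-averaged anchor responses is equivalent to
        window-averaging the full interpolated field (both are linear).
        """
        anchors, values, labels = [], [], []
        for lab, idx in sorted(groups.items(), key=lambda kv: str(kv[0])):
            use = [i for i in idx if subset is None or i in subset]
            if not use:
                raise ValueError(f"group {lab!r} has no trials in this subset")
            anchors.append(np.mean([self.events[i].post_position for i in use], axis=0))
            resp = self._group_responses(use, neuron_idx)          # (n, nt)
            values.append(_window_average_responses(resp, self.grid_t, windows))
            labels.append(lab)
        anchors = np.array(anchors)
        vals = np.stack(values)                                    # (g, n, n_w)
        g, n, n_w = vals.shape
        interp = tun._interpolate_anchor_values(
            anchors, vals.reshape(g, n * n_w), self.grid_x, self.grid_y
        ).reshape(len(self.grid_x), len(self.grid_y), n, n_w)
        return np.moveaxis(interp, 2, 0), anchors, labels

    def tuning_field(self, neuron: int, condition: str = "regular") -> tun.TuningField:
        """Full (x, y, t) tuning field of one neuron from all trials of a condition."""
        groups = self._regular_groups if condition == "regular" else self._intercept_groups
        anchors, resp, counts = [], [], []
        for lab, idx in sorted(groups.items(), key=lambda kv: str(kv[0])):
            anchors.append(np.mean([self.events[i].post_position for i in idx], axis=0))
            resp.append(tun.response_function([self._aligned[i][neuron] for i in idx],
                                              sigma=self.sigma, grid_t=self.grid_t))
            counts.append(len(idx))
        return tun.build_tuning_field(
            np.array(anchors), np.stack(resp),
            neuron_id=f"{neuron}", condition=condition, n_trials_per_anchor=counts,
            grid_x=self.grid_x, grid_y=self.grid_y, grid_t=self.grid_t,
        )

    # -- similarity screening --------------------------------------------------

    def similarity(self, window=(-100.0, 100.0), radius: float = tun.SIMILARITY_RADIUS,
                   standardize: str = "full") -> dict[str, tun.SimilarityResult]:
        """Regular-vs-interceptive map similarity per neuron (central disk)."""
        neuron_idx = list(range(self.n_neurons))
        reg_maps, _, _ = self._condition_maps(self._regular_groups, [window], neuron_idx)
        int_maps, _, _ = self._condition_maps(self._intercept_groups, [window], neuron_idx)
        mask = tun.disk_mask(radius, self.grid_x, self.grid_y)
        out = {}
        for j in neuron_idx:
            out[str(j)] = tun.similarity_index(
                reg_maps[j, :, :, 0], int_maps[j, :, :, 0],
                mask=mask, window=window, standardize=standardize,
            )
        return out

    def select_subpopulation(self, r_min: float = 0.5, si_min: float = 0.3,
                             window=(-100.0, 100.0)) -> list[int]:
        sims = self.similarity(window=window)
        return [int(n) for n in tun.select_subpopulation(sims, r_min, si_min)]

    # -- decoding --------------------------------------------------------------

    def tested_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean interceptive end-positions per motion direction, and the directions."""
        dirs = sorted(self._intercept_groups)
        pos = np.array([
            np.mean([self.events[i].post_position for i in self._intercept_groups[d]], axis=0)
            for d in dirs
        ])
        return pos, np.array(dirs, dtype=float)

    def fit(
        self,
        n_splits: int = 50,
        n_pseudo: int = 100_000,
        n_eval: int = 200,
        window: tuple[float, float] = (-100.0, 100.0),
        seed: int = 0,
        neurons=None,
        hidden: tuple[int, int] = (20, 20),
        train_frac: float = 0.7,
        max_iter: int = 400,
    ) -> "SaccadeDecodingResults":
        """Train and validate the end-position decoder.

        For each of ``n_splits`` stratified 70/30 splits of the regular
        trials, tuning fields are estimated from the training trials,
        ``n_pseudo`` Poisson pseudo-trials train the network, and the decoder
        is evaluated with ``n_eval`` Poisson draws per tested position from
        (a) the validation-trial fields (regular) and (b) the full
        interceptive fields.  ``neurons`` optionally restricts the population
        (e.g. a similarity-selected subset).
        """
        neuron_idx = list(range(self.n_neurons)) if neurons is None else list(neurons)
        tested, dirs = self.tested_positions()
        labels = [tuple(self.trials[i].target_position) for i in self._regular_idx]
        splits = dec.split_trials(labels, train_frac=train_frac,
                                  n_repeats=n_splits, seed=seed)
        int_maps, _, _ = self._condition_maps(self._intercept_groups, [window], neuron_idx)
        int_maps = int_maps[..., 0]
        reg_idx = np.array(self._regular_idx)
        per_split_reg, per_split_int, models = [], [], []
        ss = np.random.SeedSequence([seed, 7])
        for s, (tr_loc, va_loc) in enumerate(splits):
            train_set = set(reg_idx[tr_loc])
            val_set = set(reg_idx[va_loc])
            train_maps, _, _ = self._condition_maps(
                self._regular_groups, [window], neuron_idx, subset=train_set)
            val_maps, _, _ = self._condition_maps(
                self._regular_groups, [window], neuron_idx, subset=val_set)
            train_maps, val_maps = train_maps[..., 0], val_maps[..., 0]
            s_pseudo, s_train, s_eval = ss.spawn(3)
            pseudo = dec.generate_pseudo_trials(
                train_maps, n=n_pseudo, window=window,
                seed=int(s_pseudo.generate_state(1)[0] % (2**31)),
                grid_x=self.grid_x, grid_y=self.grid_y,
            )
            model = dec.train_decoder(
                pseudo, hidden=hidden, max_iter=max_iter,
                seed=int(s_train.generate_state(1)[0] % (2**31)),
            )
            models.append(model)
            rng = np.random.default_rng(s_eval)
            for maps, store in ((val_maps, per_split_reg), (int_maps, per_split_int)):
                lam = dec.expected_count_matrix(maps, tested, window, self.grid_x, self.grid_y)
                preds = [
                    dec.predict_endpoints(model, rng.poisson(lam[i], size=(n_eval, lam.shape[1])))
                    for i in range(tested.shape[0])
                ]
                store.append(dec.evaluate_predictions(preds, tested, dirs))
        return SaccadeDecodingResults(
            model=self, per_split_regular=per_split_reg, per_split_interceptive=per_split_int,
            tested_positions=tested, directions=dirs, window=window,
            n_splits=n_splits, n_pseudo=n_pseudo, n_eval=n_eval, seed=seed,
            neurons=neuron_idx, decoders=models,
            interceptive_maps=int_maps, target_speed=self.target_speed,
        )

    def window_map_stack(self, windows, neurons=None, n_splits: int = 3,
                         seed: int = 0, train_frac: float = 0.7):
        """Per-split train/validation and interceptive multi-window map stacks.

        Returns (train_maps_per_split, val_maps_per_split, interceptive_maps)
        with arrays shaped (n_neurons, nx, ny, n_windows), for
        :func:`lipdecode.decoder.sliding_window_analysis`.
        """
        neuron_idx = list(range(self.n_neurons)) if neurons is None else list(neurons)
        labels = [tuple(self.trials[i].target_position) for i in self._regular_idx]
        splits = dec.split_trials(labels, train_frac=train_frac,
                                  n_repeats=n_splits, seed=seed)
        reg_idx = np.array(self._regular_idx)
        train_stacks, val_stacks = [], []
        for tr_loc, va_loc in splits:
            tmaps, _, _ = self._condition_maps(
                self._regular_groups, windows, neuron_idx, subset=set(reg_idx[tr_loc]))
            vmaps, _, _ = self._condition_maps(
                self._regular_groups, windows, neuron_idx, subset=set(reg_idx[va_loc]))
            train_stacks.append(tmaps)
            val_stacks.append(vmaps)
        int_maps, _, _ = self._condition_maps(self._intercept_groups, windows, neuron_idx)
        return train_stacks, val_stacks, int_maps

    def sliding_window(
        self,
        n_splits: int = 3,
        n_pseudo: int = 8000,
        n_eval: int = 100,
        seed: int = 0,
        neurons=None,
        windows=None,
        **kwargs,
    ) -> dec.SlidingWindowResult:
        """Decoding time course in 100 ms windows stepped by 50 ms."""
        if windows is None:
            windows = dec.sliding_windows()
        tested, dirs = self.tested_positions()
        train_stacks, val_stacks, int_maps = self.window_map_stack(
            windows, neurons=neurons, n_splits=n_splits, seed=seed)
        return dec.sliding_window_analysis(
            train_stacks, val_stacks, int_maps,
            grid_x=self.grid_x, grid_y=self.grid_y,
            tested_positions=tested, directions=dirs, windows=windows,
            n_pseudo=n_pseudo, n_eval=n_eval, seed=seed, **kwargs,
        )


@dataclass
class SaccadeDecodingResults:
    """Decoder validation statistics, aggregated over the trial splits.

    Per-position means are averages of the per-split statistics (predictions
    are pooled at the split level, never across trials first); the reported
    mean Euclidean error and center bias are computed from these aggregated
    means, mirroring how the combined-network figures are read.
    """

    model: SaccadeDecodingModel
    per_split_regular: list[dec.DecodeEvaluation]
    per_split_interceptive: list[dec.DecodeEvaluation]
    tested_positions: np.ndarray
    directions: np.ndarray
    window: tuple[float, float]
    n_splits: int
    n_pseudo: int
    n_eval: int
    seed: int
    neurons: list[int]
    decoders: list[dec.DecoderModel]
    interceptive_maps: np.ndarray
    target_speed: float
    regular: dec.DecodeEvaluation = field(init=False)
    interceptive: dec.DecodeEvaluation = field(init=False)

    def __post_init__(self) -> None:
        self.regular = self._aggregate(self.per_split_regular)
        self.interceptive = self._aggregate(self.per_split_interceptive)

    def _aggregate(self, evals) -> dec.DecodeEvaluation:
        mean_pred = np.mean([e.mean_prediction for e in evals], axis=0)
        sd_pred = np.mean([e.sd_prediction for e in evals], axis=0)
        confusion = np.mean([e.confusion for e in evals], axis=0)
        bias = np.array([
            dec.center_bias(self.tested_positions[i], mean_pred[i], self.directions[i])
            for i in range(len(self.directions))
        ])
        err = np.linalg.norm(mean_pred - self.tested_positions, axis=1)
        return dec.DecodeEvaluation(
            tested_positions=self.tested_positions, directions=self.directions,
            mean_prediction=mean_pred, sd_prediction=sd_pred, confusion=confusion,
            pct_correct=dec.percent_correct(confusion),
            pct_correct_or_neighbor=dec.percent_correct_or_neighbor(
                confusion, self.tested_positions),
            center_bias_per_position=bias,
            mean_center_bias=float(bias.mean()),
            mean_euclidean_error=float(err.mean()),
        )

    # convenience accessors ---------------------------------------------------

    @property
    def mean_error_regular(self) -> float:
        return self.regular.mean_euclidean_error

    @property
    def center_bias_regular(self) -> float:
        return self.regular.mean_center_bias

    @property
    def center_bias_interceptive(self) -> float:
        return self.interceptive.mean_center_bias

    @property
    def bias_lag_ms(self) -> float:
        """Interceptive center bias converted into a target-motion time lag."""
        return dec.bias_to_time_lag(self.center_bias_interceptive, self.target_speed)

    def error_field(self, condition: str = "interceptive", *, points=None,
                    extent: float = 1.5, step: float = 0.5, n_draws: int = 100,
                    seed: int = 0) -> dec.ErrorField:
        """Continuous-position error field, averaged over the split decoders.

        For the regular condition the interceptive rate maps are replaced by
        per-split validation maps only in :meth:`SaccadeDecodingModel.fit`;
        here the condition selects which maps generate the query activity.
        """
        if condition == "interceptive":
            maps_per_split = [self.interceptive_maps] * len(self.decoders)
        else:
            raise ValueError("error_field supports the interceptive condition; "
                             "regular-condition errors are in `regular`")
        fields = []
        for k, (model, maps) in enumerate(zip(self.decoders, maps_per_split)):
            fields.append(dec.error_field(
                model, maps, grid_x=self.model.grid_x, grid_y=self.model.grid_y,
                window=self.window, points=points, extent=extent, step=step,
                n_draws=n_draws, seed=seed + k,
            ))
        err = np.mean([f.error for f in fields], axis=0)
        pts = fields[0].points
        return dec.ErrorField(
            points=pts, error=err, magnitude=np.linalg.norm(err, axis=1),
            direction_deg=np.degrees(np.arctan2(err[:, 1], err[:, 0])) % 360.0,
            n_draws=n_draws * len(fields),
        )

    def summary(self) -> str:
        lines = [
            "Saccade end-position decoding",
            "=" * 64,
            f"neurons: {len(self.neurons)}   splits: {self.n_splits}   "
            f"pseudo-trials: {self.n_pseudo}   window: [{self.window[0]:g}, {self.window[1]:g}] ms",
            "",
            f"{'':24s}{'regular':>12s}{'interceptive':>14s}",
            f"{'% correct':24s}{self.regular.pct_correct:12.1f}{self.interceptive.pct_correct:14.1f}",
            f"{'% correct/neighbor':24s}{self.regular.pct_correct_or_neighbor:12.1f}"
            f"{self.interceptive.pct_correct_or_neighbor:14.1f}",
            f"{'mean error (deg)':24s}{self.regular.mean_euclidean_error:12.3f}"
            f"{self.interceptive.mean_euclidean_error:14.3f}",
            f"{'center bias (deg)':24s}{self.regular.mean_center_bias:12.3f}"
            f"{self.interceptive.mean_center_bias:14.3f}",
            "",
            f"interceptive bias as target-motion lag: {self.bias_lag_ms:.1f} ms",
        ]
        return "\n".join(lines)
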