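"""End-to-end pipeline: generate -> detect -> tune -> decode -> report.

A run is fully described by a :class:`RunConfig` (serializable to YAML); the
same config and seed reproduce every output table byte for byte.  The run
writes per-stage tables (trial metadata, detected saccades, regression
summary, similarity table, decoding evaluation and confusion matrices) plus a
manifest with the config echo and SHA-256 hashes of each output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .model import SaccadeDecodingModel
from .synthetic import SessionConfig, make_cohort, simulate_session

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("lipdecode.pipeline")


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    session: SessionConfig = field(default_factory=SessionConfig)
    tau: float = 0.0                 # snapshot offset shared by the cohort (ms)
    window: tuple[float, float] = (-100.0, 100.0)
    n_splits: int = 50
    n_pseudo: int = 100_000
    n_eval: int = 200
    train_frac: float = 0.7
    n_boot: int = 2000
    subpop_r_min: float = 0.5
    subpop_si_min: float = 0.3
    decode_subpopulation: bool = False
    sliding: bool = False
    sliding_n_splits: int = 3
    sliding_n_pseudo: int = 8000
    figures: bool = False
    seed: int = 0
    outdir: str = "run"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sess = d.pop("session", {})
        if isinstance(sess, dict):
            if "fixation_point" in sess:
                sess["fixation_point"] = tuple(sess["fixation_point"])
            sess = SessionConfig(**sess)
        if "window" in d:
            d["window"] = tuple(d["window"])
        return cls(session=sess, **d)


def validate_config(cfg: RunConfig) -> list[str]:
    """Schema and range checks; an empty list means the config is runnable."""
    issues = list(cfg.session.validate())
    if cfg.window[1] <= cfg.window[0]:
        issues.append("window must have t_hi > t_lo")
    if not (-400.0 <= cfg.window[0] and cfg.window[1] <= 350.0):
        issues.append("window must lie within the field time grid [-400, 350] ms")
    if cfg.n_splits < 1:
        issues.append("n_splits must be >= 1")
    if cfg.n_pseudo < 1:
        issues.append("n_pseudo must be >= 1")
    if cfg.n_eval < 1:
        issues.append("n_eval must be >= 1")
    if not 0.0 < cfg.train_frac < 1.0:
        issues.append("train_frac must be in (0, 1): both splits need trials")
    if cfg.session.n_regular_per_position < 2:
        issues.append("need >= 2 regular trials per position for a 70/30 split")
    return issues


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=lio.FLOAT_FMT)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    issues = validate_config(cfg)
    if issues:
        raise ValueError("[config] invalid RunConfig: " + "; ".join(issues))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}
    outputs: dict[str, Path] = {}
    summary: dict[str, object] = {}

    def stage(name):
        log.info("stage %s", name)
        return _StageTimer(name, stage_times)

    try:
        with stage("generate"):
            cohort = make_cohort(cfg.session.n_neurons, seed=cfg.seed, tau=cfg.tau,
                                 fixation_point=cfg.session.fixation_point)
            trials = simulate_session(cohort, dataclasses.replace(cfg.session, seed=cfg.seed))
            files = lio.write_session(trials, outdir / "session", cohort=cohort)
            outputs.update({f"session_{k}": v for k, v in files.items()})
    except Exception as err:
        raise RuntimeError(f"[generate] {err}") from err

    try:
        with stage("detect"):
            model = SaccadeDecodingModel(trials)
            sacc = lio.saccade_table(model.trials, model.events)
            outputs["saccades"] = outdir / "saccades.csv"
            _write_csv(sacc, outputs["saccades"])
            reg = model.behavioral_regression(n_boot=cfg.n_boot, seed=cfg.seed)
            summary["regression"] = {
                "slope_deg_per_s": reg.slope, "offset_deg": reg.offset,
                "pearson_r": reg.pearson_r,
                "ci_slope": list(reg.ci_slope), "ci_offset": list(reg.ci_offset),
                "n": reg.n,
            }
            ellipses = model.endpoint_ellipses()
            ell_rows = [{
                "direction": d, "mean_x": e.mean[0], "mean_y": e.mean[1],
                "sd_major": e.sd_major, "sd_minor": e.sd_minor,
                "angle_deg": e.angle_deg, "n": e.n,
            } for d, e in ellipses.items()]
            outputs["endpoint_ellipses"] = outdir / "endpoint_ellipses.csv"
            _write_csv(pd.DataFrame(ell_rows), outputs["endpoint_ellipses"])
    except Exception as err:
        raise RuntimeError(f"[detect] {err}") from err

    try:
        with stage("tuning"):
            sims = model.similarity(window=cfg.window)
            sim_rows = [{"neuron": n, "pearson_r": s.pearson_r, "si": s.si}
                        for n, s in sims.items()]
            outputs["similarity"] = outdir / "similarity.csv"
            _write_csv(pd.DataFrame(sim_rows), outputs["similarity"])
            subpop = model.select_subpopulation(cfg.subpop_r_min, cfg.subpop_si_min,
                                                window=cfg.window)
            summary["n_subpopulation"] = len(subpop)
    except Exception as err:
        raise RuntimeError(f"[tuning] {err}") from err

    try:
        with stage("decode"):
            neurons = subpop if cfg.decode_subpopulation else None
            res = model.fit(n_splits=cfg.n_splits, n_pseudo=cfg.n_pseudo,
                            n_eval=cfg.n_eval, window=cfg.window, seed=cfg.seed,
                            neurons=neurons, train_frac=cfg.train_frac)
            for cond, ev in (("regular", res.regular), ("interceptive", res.interceptive)):
                _write_csv(pd.DataFrame(ev.confusion), outdir / f"confusion_{cond}.csv")
                outputs[f"confusion_{cond}"] = outdir / f"confusion_{cond}.csv"
                rows = pd.DataFrame({
                    "tested_x": ev.tested_positions[:, 0],
                    "tested_y": ev.tested_positions[:, 1],
                    "direction": ev.directions,
                    "pred_x": ev.mean_prediction[:, 0],
                    "pred_y": ev.mean_prediction[:, 1],
                    "sd_x": ev.sd_prediction[:, 0],
                    "sd_y": ev.sd_prediction[:, 1],
                    "center_bias": ev.center_bias_per_position,
                })
                _write_csv(rows, outdir / f"evaluation_{cond}.csv")
                outputs[f"evaluation_{cond}"] = outdir / f"evaluation_{cond}.csv"
                summary[cond] = {
                    "pct_correct": ev.pct_correct,
                    "pct_correct_or_neighbor": ev.pct_correct_or_neighbor,
                    "mean_euclidean_error_deg": ev.mean_euclidean_error,
                    "mean_center_bias_deg": ev.mean_center_bias,
                }
            summary["bias_lag_ms"] = res.bias_lag_ms
            summary["summary_text"] = res.summary()
    except Exception as err:
        raise RuntimeError(f"[decode] {err}") from err

    if cfg.sliding:
        try:
            with stage("sliding"):
                sw = model.sliding_window(n_splits=cfg.sliding_n_splits,
                                          n_pseudo=cfg.sliding_n_pseudo, seed=cfg.seed)
                df = pd.DataFrame({
                    "t_center_ms": sw.centers,
                    "bias_regular": sw.bias_regular,
                    "bias_interceptive": sw.bias_interceptive,
                    "sd_regular": sw.sd_regular,
                    "sd_interceptive": sw.sd_interceptive,
                    "p_value": sw.p_values,
                    "significant": sw.significant,
                })
                outputs["sliding"] = outdir / "sliding_window.csv"
                _write_csv(df, outputs["sliding"])
                summary["sliding_minimum_lag_ms"] = sw.minimum_lag_ms()
        except Exception as err:
            raise RuntimeError(f"[sliding] {err}") from err

    if cfg.figures:
        with stage("figures"):
            _figures(model, res, outdir)

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True, default=float))
    outputs["summary"] = summary_path
    cfg_path = outdir / "config.yaml"
    cfg.to_yaml(cfg_path)
    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


class _StageTimer:
    def __init__(self, name: str, store: dict):
        self.name, self.store = name, store

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.store[self.name] = time.perf_counter() - self.t0
        return False


def _figures(model: SaccadeDecodingModel, res, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for d, idx in model._intercept_groups.items():
        pts = np.array([model.events[i].post_position for i in idx])
        ax.scatter(pts[:, 0], pts[:, 1], s=6, label=f"{d:g} deg")
    ax.set_xlabel("x (deg)")
    ax.set_ylabel("y (deg)")
    ax.set_title("Interceptive saccade endpoints")
    fig.savefig(outdir / "endpoints.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, (cond, ev) in zip(axes, (("regular", res.regular),
                                     ("interceptive", res.interceptive))):
        im = ax.imshow(ev.confusion, vmin=0, vmax=1, cmap="viridis")
        ax.set_title(f"{cond} (correct {ev.pct_correct:.0f}%)")
        ax.set_xlabel("assigned")
        ax.set_ylabel("tested")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(outdir / "confusion.png", dpi=120)
    plt.close(fig)
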