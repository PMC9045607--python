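"""End-to-end session orchestration and file formats.

A *session* is one specimen's full exposure experiment: design -> simulate ->
render -> track -> per-trial split -> transient fits -> shape PCA -> forward /
inverse calibration -> hysteresis diagnostic.  Video mode starts at the
tracking stage from frame directories on disk.  All tables are CSV with
``#``-prefixed header comments recording units, the seed and a config hash;
reports are JSON.  Identical seeds give byte-identical numeric outputs.
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

from . import __version__
from .calibration import (
    CalibrationModel,
    feature_ablation,
    fit_forward_model,
    hysteresis_diagnostic,
)
from .errors import TrialMismatchError
from .shape import ShapeModes, build_shape_ensemble, cumulative_variance, shape_pca
from .synthetic import (
    AngleSeries,
    ExposureDesign,
    GeneratorParams,
    generate_exposure_design,
    render_frames,
    simulate_session,
    standard_solutions,
)
from .tracking import TrackerConfig, TrackResult, compare_to_manual, track_sequence
from .transients import delta_tip_angle, fit_triple_exponential, time_to_max_deflection

logger = logging.getLogger("filmbend")

__all__ = [
    "SessionConfig",
    "SessionResult",
    "run_session",
    "split_trials",
    "derive_seeds",
    "load_frames_dir",
]

# In-sample R^2 values reported for real films of this sensor type, carried in
# the pipeline summary for context; synthetic sessions are not expected to
# reproduce them (the bending model here is a structural stand-in).
REFERENCE_REAL_FILM_R2 = {
    "inverse_f_acetone": 0.45,
    "inverse_f_ethanol": 0.30,
    "forward_delta_theta": 0.40,
    "auto_vs_manual_cubic": 0.93,
}


@dataclass(frozen=True)
class SessionConfig:
    mode: str = "synthetic"  # "synthetic" | "video"
    seed: int = 7
    n_blocks: int = 5
    exposure_s: float = 180.0
    recovery_s: float = 60.0
    specimen_id: str = "specimen"
    params: GeneratorParams = field(default_factory=GeneratorParams)
    tracker: TrackerConfig | None = None
    P: int = 100  # resampled points per shape
    n_starts: int = 10  # multi-start count for transient fits
    click_sd_px: float = 2.0
    annotate: bool = False  # synthetic mode: also emulate manual annotation
    frames_dir: str | None = None  # video mode input
    annotations_csv: str | None = None
    out_dir: str | None = None

    def tracker_config(self) -> TrackerConfig:
        if self.tracker is not None:
            return self.tracker
        return TrackerConfig(frame_rate=self.params.frame_rate)

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # where results land is not an analysis setting
        blob = json.dumps(_as_jsonable(d), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def derive_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


@dataclass
class SessionResult:
    config: SessionConfig
    design: ExposureDesign | None
    series: AngleSeries | None  # analysis series (tracked angles in synthetic mode)
    tracked: TrackResult | None
    trials: pd.DataFrame | None
    shape_modes: ShapeModes | None
    models: dict
    comparison: dict | None = None
    output_files: dict = field(default_factory=dict)


def split_trials(series: AngleSeries, design: ExposureDesign):
    """One (trial, local times, angles) segment per exposure; the clock resets
    to 0 at each trial start and recovery interludes carry no samples."""
    if series.n_trials != design.n_trials:
        raise TrialMismatchError(
            f"series has {series.n_trials} trials, design has {design.n_trials}"
        )
    out = []
    for i, trial in enumerate(design.trials):
        t, th = series.trial_segment(i)
        out.append((trial, t, th))
    return out


def _trial_table(series: AngleSeries, design: ExposureDesign,
                 n_starts: int, fit_seed: int) -> pd.DataFrame:
    rows = []
    for trial, t, th in split_trials(series, design):
        comp = design.composition(trial)
        finite = np.isfinite(th)
        fit = fit_triple_exponential(
            t[finite], th[finite], n_starts=n_starts,
            seed=(fit_seed + trial.trial_index) % 2**31,
            trial_index=trial.trial_index,
        )
        resp = time_to_max_deflection(t[finite], th[finite])
        rows.append({
            "trial_index": trial.trial_index,
            "solution_id": trial.solution_id,
            "f_acetone": comp.f_acetone,
            "f_ethanol": comp.f_ethanol,
            "f_water": comp.f_water,
            "initial_angle_deg": float(th[finite][0]),
            "delta_theta_deg": delta_tip_angle(t[finite], th[finite]),
            "t_max_s": resp.t95_s,
            "t_max_defined": resp.defined,
            "a0": fit.a0, "a1": fit.a1, "a2": fit.a2, "a3": fit.a3,
            "lambda1": fit.lambda1, "lambda2": fit.lambda2, "lambda3": fit.lambda3,
            "sse": fit.sse, "converged": fit.converged,
            "condition_number": fit.condition_number,
        })
    return pd.DataFrame(rows)


def _fit_models(trials: pd.DataFrame) -> dict:
    models: dict = {"reference_real_film_r2": REFERENCE_REAL_FILM_R2}
    try:
        fwd = fit_forward_model(trials, include_initial_angle=True)
        fwd0 = fit_forward_model(trials, include_initial_angle=False)
        models["forward"] = _model_report(fwd)
        models["forward_no_initial_angle"] = _model_report(fwd0)
    except Exception as exc:  # keep partial reports on small sessions
        models["forward_error"] = str(exc)
    try:
        abl = feature_ablation(trials)
        models["inverse_full"] = _model_report(abl["full"])
        models["inverse_reduced"] = _model_report(abl["reduced"])
        models["inverse_delta_r2"] = abl["delta_r2"]
    except Exception as exc:
        models["inverse_error"] = str(exc)
    try:
        hyst = hysteresis_diagnostic(trials["initial_angle_deg"].to_numpy())
        models["hysteresis"] = {
            "drift_slope_deg_per_trial": hyst.drift_slope_deg_per_trial,
            "lag1_autocorrelation": hyst.lag1_autocorrelation,
            "autocorrelation_defined": hyst.autocorrelation_defined,
        }
    except Exception as exc:
        models["hysteresis_error"] = str(exc)
    return models


def _model_report(model: CalibrationModel) -> dict:
    return {
        "direction": model.direction,
        "features": list(model.feature_names),
        "coefficients": model.coefficients,
        "r2_per_target": model.r2_per_target,
        "n_trials": model.n_trials,
    }


def run_session(config: SessionConfig) -> SessionResult:
    """Run the full pipeline for one session (see module docstring)."""
    t_wall = time.perf_counter()
    stage_times: dict[str, float] = {}
    tracker = config.tracker_config()

    def clock(name: str) -> None:
        nonlocal t_wall
        now = time.perf_counter()
        stage_times[name] = now - t_wall
        logger.info("stage %-12s %.2f s", name, stage_times[name])
        t_wall = now

    comparison = None
    if config.mode == "synthetic":
        s_design, s_sim, s_fit, s_click = derive_seeds(config.seed, 4)
        design = generate_exposure_design(
            config.n_blocks, standard_solutions(), s_design,
            exposure_s=config.exposure_s, recovery_s=config.recovery_s,
            specimen_id=config.specimen_id,
        )
        clock("design")
        sim = simulate_session(design, config.params, s_sim)
        clock("simulate")
        tracker = dataclasses.replace(tracker, frame_rate=config.params.frame_rate)
        tracked = track_sequence(render_frames(sim, config.params), tracker)
        clock("track")
        series = AngleSeries(
            times=sim.times, theta=tracked.theta,
            trial_starts=sim.trial_starts, frame_rate=sim.frame_rate,
        )
        if config.annotate:
            from .synthetic import arc_midline, emulate_manual_annotation

            midlines = [
                (i, arc_midline(float(th), config.params))
                for i, th in enumerate(sim.theta)
            ]
            ann = emulate_manual_annotation(
                midlines, config.params.frame_rate,
                click_sd_px=config.click_sd_px, seed=s_click,
            )
            comparison = compare_to_manual(tracked, ann, tracker)
            comparison = {
                "r_squared": comparison.r_squared,
                "cubic_coefficients": comparison.coefficients.tolist(),
                "n_annotated_frames": int(len(comparison.frame_indices)),
            }
            clock("annotate")
    elif config.mode == "video":
        if not config.frames_dir:
            raise TrialMismatchError("video mode requires frames_dir")
        design = None
        tracked, series = _track_video(Path(config.frames_dir), tracker)
        clock("track")
        if config.annotations_csv:
            ann = pd.read_csv(config.annotations_csv, comment="#")
            cmp_res = compare_to_manual(tracked, ann, tracker)
            comparison = {
                "r_squared": cmp_res.r_squared,
                "cubic_coefficients": cmp_res.coefficients.tolist(),
                "n_annotated_frames": int(len(cmp_res.frame_indices)),
            }
        else:
            logger.info("no annotation file given; manual comparison skipped")
    else:
        raise TrialMismatchError(f"unknown mode {config.mode!r}")

    trials = None
    models: dict = {}
    if design is not None and design.n_trials > 0:
        _, _, s_fit_v, _ = derive_seeds(config.seed, 4)
        trials = _trial_table(series, design, config.n_starts, s_fit_v)
        clock("transients")
        models = _fit_models(trials)
        clock("models")

    shape_modes = None
    if tracked is not None and any(p is not None for p in tracked.paths):
        nominal = config.params.filament_length_px if config.mode == "synthetic" else None
        shapes, _ = build_shape_ensemble(tracked.paths, config.P, nominal)
        shape_modes = shape_pca(shapes)
        clock("shapes")

    result = SessionResult(
        config=config, design=design, series=series, tracked=tracked,
        trials=trials, shape_modes=shape_modes, models=models,
        comparison=comparison,
    )
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir), stage_times)
    return result


def _track_video(frames_dir: Path, tracker: TrackerConfig):
    """Track one directory of numbered frames (or per-trial subdirectories)."""
    subdirs = sorted(d for d in frames_dir.iterdir() if d.is_dir())
    dirs = subdirs if subdirs else [frames_dir]
    all_theta, all_times, starts = [], [], []
    tracked_parts = []
    offset_n, offset_t = 0, 0.0
    for d in dirs:
        frames = load_frames_dir(d)
        tr = track_sequence(frames, tracker)
        tracked_parts.append(tr)
        starts.append(offset_n)
        all_theta.append(tr.theta)
        all_times.append(tr.times + offset_t)
        offset_n += tr.n_frames
        offset_t = all_times[-1][-1] + 1.0 / tracker.frame_rate
    merged = TrackResult(
        times=np.concatenate(all_times),
        theta=np.concatenate(all_theta),
        gap=np.concatenate([t.gap for t in tracked_parts]),
        broken=np.concatenate([t.broken for t in tracked_parts]),
        curled=np.concatenate([t.curled for t in tracked_parts]),
        paths=[p for t in tracked_parts for p in t.paths],
    )
    series = AngleSeries(
        times=merged.times, theta=merged.theta,
        trial_starts=np.asarray(starts, dtype=int),
        frame_rate=tracker.frame_rate,
    )
    return merged, series


def load_frames_dir(d: Path):
    """Yield grayscale arrays from a directory of numbered PNG/TIFF frames."""
    import imageio.v3 as iio

    files = sorted(
        p for p in Path(d).iterdir()
        if p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    for p in files:
        yield iio.imread(p)


# --------------------------------------------------------------------------
# Output files


def _header(config: SessionConfig, units: str) -> str:
    return (
        f"# filmbend v{__version__}\n"
        f"# seed={config.seed} config_sha={config.hash()}\n"
        f"# units: {units}\n"
    )


def _write_outputs(result: SessionResult, out_dir: Path, stage_times: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    config = result.config
    files = result.output_files

    if result.series is not None:
        trial_idx = np.zeros(len(result.series.times), dtype=int)
        for i in range(result.series.n_trials):
            trial_idx[result.series.trial_slice(i)] = i + 1
        df = pd.DataFrame({
            "time_s": result.series.times,
            "tip_angle_deg": result.series.theta,
            "trial_index": trial_idx,
            "broken": result.tracked.broken if result.tracked is not None else False,
            "curled": result.tracked.curled if result.tracked is not None else False,
        })
        path = out_dir / "angles.csv"
        with open(path, "w") as fh:
            fh.write(_header(config, "time_s in s; tip_angle_deg in degrees"))
            df.to_csv(fh, index=False)
        files["angles"] = str(path)

    if result.trials is not None:
        path = out_dir / "trials.csv"
        with open(path, "w") as fh:
            fh.write(_header(config, "angles deg; times s; lambdas 1/s"))
            result.trials.to_csv(fh, index=False)
        files["trials"] = str(path)

    if result.shape_modes is not None:
        m = result.shape_modes
        path = out_dir / "shape_modes.json"
        payload = {
            "seed": config.seed,
            "config_sha": config.hash(),
            "P": m.P,
            "mean_shape": m.mean_shape.tolist(),
            "explained_variance": m.explained_variance.tolist(),
            "cumulative_variance_2": cumulative_variance(m, min(2, m.n_components)),
            "cumulative_variance_4": cumulative_variance(m, min(4, m.n_components)),
            "components": m.components[: min(8, m.n_components)].tolist(),
        }
        path.write_text(json.dumps(payload, sort_keys=True))
        files["shape_modes"] = str(path)

    if result.models:
        path = out_dir / "models.json"
        payload = dict(result.models)
        payload["seed"] = config.seed
        payload["config_sha"] = config.hash()
        path.write_text(json.dumps(_as_jsonable(payload), sort_keys=True))
        files["models"] = str(path)

    if result.comparison is not None:
        path = out_dir / "comparison.json"
        path.write_text(json.dumps(_as_jsonable(result.comparison), sort_keys=True))
        files["comparison"] = str(path)

    log_path = out_dir / "run.log"
    with open(log_path, "w") as fh:
        fh.write(f"filmbend v{__version__}\n")
        fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
        fh.write(f"seed={config.seed} config_sha={config.hash()}\n")
        for name, dt in stage_times.items():
            fh.write(f"stage {name}: {dt:.3f} s\n")
    files["log"] = str(log_path)


def design_to_csv(design: ExposureDesign, path) -> None:
    df = pd.DataFrame(
        [
            (t.trial_index, t.solution_id, t.exposure_s, t.recovery_s)
            for t in design.trials
        ],
        columns=["trial_index", "solution_id", "exposure_s", "recovery_s"],
    )
    with open(path, "w") as fh:
        fh.write(f"# filmbend v{__version__} exposure design "
                 f"specimen={design.specimen_id} n_blocks={design.n_blocks}\n")
        df.to_csv(fh, index=False)
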