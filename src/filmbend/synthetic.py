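"""Synthetic stand-in for the bending-film exposure experiment.

Emulates the structure of a headspace exposure study on a chemo-mechanically
actuating polymer filament: a randomized block design over six
acetone/ethanol/water solutions, a hysteretic multi-exponential tip-angle
response, binary video frames of a constant-curvature filament rendered at a
fixed frame rate, and noisy manual click annotations.  Every stage carries its
ground truth so the downstream tracker and models can be validated end to end.

Conventions
-----------
Angles are in degrees, measured counterclockwise from the +x image axis with
the y axis of the *mathematical* frame pointing up (image rows grow downward,
so a plumb, straight-down filament has tip angle -90 deg).  Times are in
seconds, lengths in pixels.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import (
    DuplicateSolutionError,
    InvalidParamsError,
    RenderError,
    UnknownSolutionError,
)

__all__ = [
    "SolutionComposition",
    "Trial",
    "ExposureDesign",
    "GeneratorParams",
    "AngleSeries",
    "RenderedFrame",
    "solution_composition",
    "standard_solutions",
    "generate_exposure_design",
    "simulate_session",
    "arc_midline",
    "render_frame",
    "render_frames",
    "true_tip_angle",
    "emulate_manual_annotation",
]

# Volumes (acetone, ethanol, water) in mL poured into the 125 mL flask for
# each of the six headspace environments.
SOLUTION_VOLUMES_ML: dict[int, tuple[float, float, float]] = {
    1: (60.0, 0.0, 0.0),
    2: (0.0, 60.0, 0.0),
    3: (30.0, 30.0, 0.0),
    4: (30.0, 0.0, 30.0),
    5: (0.0, 30.0, 30.0),
    6: (20.0, 20.0, 20.0),
}


@dataclass(frozen=True)
class SolutionComposition:
    """Volume fractions of one liquid mixture defining a headspace environment."""

    solution_id: int
    f_acetone: float
    f_ethanol: float
    f_water: float
    volumes_mL: tuple[float, float, float]

    def __post_init__(self) -> None:
        fr = (self.f_acetone, self.f_ethanol, self.f_water)
        if any(f < 0 for f in fr):
            raise InvalidParamsError("volume fractions must be non-negative")
        # all-zero fractions denote an empty flask (no vapor drive)
        if sum(fr) != 0.0 and abs(sum(fr) - 1.0) > 1e-12:
            raise InvalidParamsError("volume fractions must sum to 1")


def solution_composition(solution_id: int) -> SolutionComposition:
    """Return the built-in composition for one of the six study solutions."""
    try:
        vols = SOLUTION_VOLUMES_ML[solution_id]
    except KeyError:
        raise UnknownSolutionError(
            f"unknown solution id {solution_id!r}; known ids are 1..6"
        ) from None
    total = sum(vols)
    return SolutionComposition(
        solution_id=solution_id,
        f_acetone=vols[0] / total,
        f_ethanol=vols[1] / total,
        f_water=vols[2] / total,
        volumes_mL=vols,
    )


def standard_solutions() -> list[SolutionComposition]:
    """All six built-in solutions, ordered by id."""
    return [solution_composition(i) for i in sorted(SOLUTION_VOLUMES_ML)]


@dataclass(frozen=True)
class Trial:
    trial_index: int  # 1-based position in the session
    solution_id: int
    exposure_s: float
    recovery_s: float


@dataclass(frozen=True)
class ExposureDesign:
    """Ordered exposure trials for one specimen: n_blocks random permutation
    blocks over the solution ids, each trial followed by a fixed recovery."""

    specimen_id: str
    trials: tuple[Trial, ...]
    n_blocks: int
    solutions: dict[int, SolutionComposition] = field(repr=False)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def composition(self, trial: Trial) -> SolutionComposition:
        return self.solutions[trial.solution_id]


def generate_exposure_design(
    n_blocks: int,
    solutions: Sequence[SolutionComposition],
    seed: int,
    exposure_s: float = 180.0,
    recovery_s: float = 60.0,
    specimen_id: str = "specimen",
) -> ExposureDesign:
    """Concatenate ``n_blocks`` independent uniform-random permutations of the
    solution ids into a trial sequence (deterministic for a fixed seed)."""
    if n_blocks < 0:
        raise InvalidParamsError("n_blocks must be >= 0")
    if not solutions:
        raise InvalidParamsError("need at least one solution")
    ids = [s.solution_id for s in solutions]
    if len(set(ids)) != len(ids):
        raise DuplicateSolutionError(f"duplicate solution ids in {ids}")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    for _ in range(n_blocks):
        for sid in rng.permutation(ids):
            trials.append(
                Trial(
                    trial_index=len(trials) + 1,
                    solution_id=int(sid),
                    exposure_s=float(exposure_s),
                    recovery_s=float(recovery_s),
                )
            )
    return ExposureDesign(
        specimen_id=specimen_id,
        trials=tuple(trials),
        n_blocks=n_blocks,
        solutions={s.solution_id: s for s in solutions},
    )


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the hysteretic three-mode bending model and the renderer.

    The tip angle relaxes toward a deflected target as a weighted sum of three
    first-order modes whose common rate scale ``k0 + k_acetone*f_a +
    k_ethanol*f_e`` grows with the acetone (strongly) and ethanol (weakly)
    fractions, so response *speed*, not steady state, encodes composition.
    A hidden state ``h`` integrates the water fraction with time constant
    ``tau_h`` and shifts the rest angle by ``gamma_h * h`` — a slow,
    water-driven baseline drift (hysteresis).
    """

    theta_rest0: float = -90.0  # rest tip angle, deg (plumb)
    A_deflect: float = 60.0  # maximum deflection amplitude, deg
    k0: float = 0.005  # base response rate, 1/s
    k_acetone: float = 0.15  # per-unit-acetone-fraction rate, 1/s
    k_ethanol: float = 0.03  # per-unit-ethanol-fraction rate, 1/s
    mode_ratios: tuple[float, float, float] = (1.0, 0.2, 0.05)
    mode_weights: tuple[float, float, float] = (0.7, 0.2, 0.1)
    k_recover: float = 0.05  # recovery rate, 1/s (60 s recovery ~ 3 time constants)
    tau_h: float = 600.0  # hysteresis time constant, s
    gamma_h: float = 25.0  # baseline-drift gain, deg
    sigma_theta: float = 1.0  # angle noise SD, deg
    filament_length_px: float = 200.0
    thickness_px: float = 5.0
    frame_rate: float = 30.0  # Hz
    image_width_px: int = 440
    image_height_px: int = 240
    root_margin_px: int = 12

    def validate(self) -> None:
        numbers = [
            self.theta_rest0, self.A_deflect, self.k0, self.k_acetone,
            self.k_ethanol, *self.mode_ratios, *self.mode_weights,
            self.k_recover, self.tau_h, self.gamma_h, self.sigma_theta,
            self.filament_length_px, self.thickness_px, self.frame_rate,
        ]
        if not all(math.isfinite(v) for v in numbers):
            raise InvalidParamsError("non-finite generator parameter")
        if min(self.k0, self.k_acetone, self.k_ethanol, self.k_recover,
               self.tau_h, self.frame_rate) <= 0:
            raise InvalidParamsError("rates, tau_h and frame_rate must be > 0")
        if min(self.mode_ratios) <= 0:
            raise InvalidParamsError("mode_ratios must be > 0")
        if abs(sum(self.mode_weights) - 1.0) > 1e-9:
            raise InvalidParamsError("mode_weights must sum to 1")
        if self.k_acetone <= self.k_ethanol:
            raise InvalidParamsError("k_acetone must exceed k_ethanol")
        if self.filament_length_px <= 0 or self.thickness_px <= 0:
            raise InvalidParamsError("render geometry must be positive")
        if self.sigma_theta < 0:
            raise InvalidParamsError("sigma_theta must be >= 0")

    def replace(self, **kw) -> "GeneratorParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class AngleSeries:
    """Tip-angle samples over a session; recovery interludes carry no samples."""

    times: np.ndarray  # global session clock, s, strictly increasing
    theta: np.ndarray  # tip angle, deg
    trial_starts: np.ndarray  # index of the first sample of each trial
    frame_rate: float

    def __post_init__(self) -> None:
        if len(self.times) != len(self.theta):
            raise InvalidParamsError("times and theta must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParamsError("times must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trial_starts)

    def trial_slice(self, i: int) -> slice:
        starts = self.trial_starts
        stop = starts[i + 1] if i + 1 < len(starts) else len(self.times)
        return slice(int(starts[i]), int(stop))

    def trial_segment(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Local-clock times (t=0 at exposure onset) and angles of trial i."""
        sl = self.trial_slice(i)
        t = self.times[sl]
        return t - t[0], self.theta[sl]


def simulate_session(
    design: ExposureDesign, params: GeneratorParams, seed: int
) -> AngleSeries:
    """Integrate the hysteretic three-mode bending model over a session.

    Each of the three mode states relaxes exponentially (exact per-step
    updates) toward the deflected target during exposure and toward the
    drifting rest angle at ``k_recover`` during the unrecorded recovery;
    the observable tip angle is the weight-averaged mode state plus i.i.d.
    Gaussian noise on the recorded samples.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.frame_rate
    nu = np.asarray(params.mode_ratios, dtype=float)
    w = np.asarray(params.mode_weights, dtype=float)

    x = np.full(3, params.theta_rest0)  # mode states, deg
    h = 0.0  # hidden hysteresis state (integrated water exposure)
    t_global = 0.0
    times: list[np.ndarray] = []
    thetas: list[np.ndarray] = []
    trial_starts: list[int] = []
    n_recorded = 0

    for trial in design.trials:
        comp = design.composition(trial)
        k = params.k0 + params.k_acetone * comp.f_acetone + params.k_ethanol * comp.f_ethanol
        # Deflection amplitude scales with the total vapor fraction so an
        # empty flask (all fractions zero) produces no drive; for every real
        # solution the scale is 1 and the steady state is composition-free.
        vapor = comp.f_acetone + comp.f_ethanol + comp.f_water
        decay = np.exp(-nu * k * dt)
        h_decay = math.exp(-dt / params.tau_h)

        n = int(round(trial.exposure_s * params.frame_rate))
        trial_starts.append(n_recorded)
        tt = t_global + dt * np.arange(n)
        th = np.empty(n)
        for j in range(n):
            th[j] = float(w @ x)
            h = comp.f_water + (h - comp.f_water) * h_decay
            theta_rest = params.theta_rest0 + params.gamma_h * h
            target = theta_rest - params.A_deflect * vapor
            x = target + (x - target) * decay
        if params.sigma_theta > 0:
            th = th + rng.normal(0.0, params.sigma_theta, size=n)
        times.append(tt)
        thetas.append(th)
        n_recorded += n
        t_global += n * dt

        # Unrecorded recovery: relax toward the (drifting) rest angle.
        m = int(round(trial.recovery_s * params.frame_rate))
        r_decay = math.exp(-params.k_recover * dt)
        for _ in range(m):
            h = h * h_decay
            theta_rest = params.theta_rest0 + params.gamma_h * h
            x = theta_rest + (x - theta_rest) * r_decay
        t_global += m * dt

    if times:
        times_arr = np.concatenate(times)
        theta_arr = np.concatenate(thetas)
    else:
        times_arr = np.empty(0)
        theta_arr = np.empty(0)
    return AngleSeries(
        times=times_arr,
        theta=theta_arr,
        trial_starts=np.asarray(trial_starts, dtype=int),
        frame_rate=params.frame_rate,
    )


# --------------------------------------------------------------------------
# Rendering


def _arc_tangents(tip_angle_deg: float, tip_fraction: float) -> tuple[float, float]:
    """Root and tip tangent angles (deg) of the constant-curvature arc whose
    distal-``tip_fraction`` chord direction equals ``tip_angle_deg``.

    The chord direction of a circular arc equals the mean of its end tangents,
    so the chord of the last fraction q sits at arc-length fraction 1 - q/2.
    """
    phi0 = -90.0  # clamped root: always plumb at the top
    turn = (tip_angle_deg - phi0) / (1.0 - tip_fraction / 2.0)
    return phi0, phi0 + turn


def arc_midline(
    tip_angle_deg: float,
    params: GeneratorParams,
    tip_fraction: float = 0.25,
    spacing_px: float = 1.0,
) -> np.ndarray:
    """Midline polyline (N x 2 pixel coordinates, root first) of the rendered
    constant-curvature filament for one tip angle."""
    L = params.filament_length_px
    phi0, phi1 = _arc_tangents(tip_angle_deg, tip_fraction)
    n = max(2, int(math.ceil(L / spacing_px)) + 1)
    s = np.linspace(0.0, L, n)
    x0 = params.image_width_px / 2.0
    y0 = float(params.root_margin_px)
    phi = np.deg2rad(phi0 + (phi1 - phi0) * s / L)
    if abs(phi1 - phi0) < 1e-9:
        x = x0 + np.cos(phi) * s
        y = y0 - np.sin(phi) * s
    else:
        kappa = np.deg2rad(phi1 - phi0) / L  # signed curvature, rad/px
        x = x0 + (np.sin(phi) - np.sin(phi[0])) / kappa
        y = y0 + (np.cos(phi) - np.cos(phi[0])) / kappa
    return np.column_stack([x, y])


def true_tip_angle(midline: np.ndarray, tip_fraction: float = 0.25) -> float:
    """Ground-truth tip angle of a midline polyline: direction of the chord
    spanning the distal ``tip_fraction`` of arc length (deg, CCW from +x)."""
    seg = np.diff(midline, axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    cut = (1.0 - tip_fraction) * s[-1]
    i = int(np.searchsorted(s, cut))
    i = min(max(i, 0), len(midline) - 2)
    dx = midline[-1, 0] - midline[i, 0]
    dy = midline[-1, 1] - midline[i, 1]
    return math.degrees(math.atan2(-dy, dx))


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(math.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dx * dx + dy * dy <= radius * radius
    return np.column_stack([dx[keep], dy[keep]])


@dataclass(frozen=True)
class RenderedFrame:
    frame_index: int
    time_s: float
    image: np.ndarray  # bool mask, True = filament (dark) pixels
    midline: np.ndarray  # ground-truth midline, pixel coords
    tip_angle_deg: float  # ground-truth tip angle


def render_frame(
    tip_angle_deg: float,
    params: GeneratorParams,
    frame_index: int = 0,
    time_s: float = 0.0,
    tip_fraction: float = 0.25,
    _offsets: np.ndarray | None = None,
) -> RenderedFrame:
    """Rasterize one constant-curvature filament as a binary frame."""
    if params.filament_length_px <= 0 or params.thickness_px <= 0:
        raise InvalidParamsError("filament geometry must be positive")
    mid = arc_midline(tip_angle_deg, params, tip_fraction, spacing_px=0.75)
    offs = _offsets if _offsets is not None else _disk_offsets(params.thickness_px / 2.0)
    r = params.thickness_px / 2.0
    H, W = params.image_height_px, params.image_width_px
    if (
        mid[:, 0].min() < r or mid[:, 0].max() > W - 1 - r
        or mid[:, 1].min() < r or mid[:, 1].max() > H - 1 - r
    ):
        raise RenderError(
            f"frame {frame_index}: filament (tip angle {tip_angle_deg:.1f} deg) "
            f"exceeds the {W}x{H} canvas"
        )
    img = np.zeros((H, W), dtype=bool)
    centers = np.rint(mid).astype(int)
    cols = (centers[:, 0][:, None] + offs[:, 0][None, :]).ravel()
    rows = (centers[:, 1][:, None] + offs[:, 1][None, :]).ravel()
    img[rows, cols] = True
    # Return the midline at ~1 px spacing as ground truth.
    gt = arc_midline(tip_angle_deg, params, tip_fraction, spacing_px=1.0)
    return RenderedFrame(frame_index, time_s, img, gt, float(tip_angle_deg))


def render_frames(
    series: AngleSeries,
    params: GeneratorParams,
    tip_fraction: float = 0.25,
) -> Iterator[RenderedFrame]:
    """Lazily render every sample of an angle series as a binary frame.

    Yields frames one at a time so full sessions can be tracked in a stream
    without holding the whole image stack in memory.
    """
    params.validate()
    offs = _disk_offsets(params.thickness_px / 2.0)
    for i, (t, th) in enumerate(zip(series.times, series.theta)):
        yield render_frame(
            float(th), params, frame_index=i, time_s=float(t),
            tip_fraction=tip_fraction, _offsets=offs,
        )


# --------------------------------------------------------------------------
# Manual-annotation emulation


def emulate_manual_annotation(
    midlines: Sequence[tuple[int, np.ndarray]],
    frame_rate: float,
    interval_s: float = 5.0,
    n_points: int = 7,
    click_sd_px: float = 2.0,
    seed: int = 0,
):
    """Emulate a human clicking ``n_points`` roughly equidistant points on the
    filament in one displayed frame every ``interval_s`` seconds.

    Parameters
    ----------
    midlines
        Sequence of ``(frame_index, midline polyline)`` pairs covering the
        frames to annotate (e.g. ground truth from :func:`render_frames`).
    frame_rate
        Frames per second of the source sequence.
    click_sd_px
        Isotropic Gaussian click noise SD in pixels.

    Returns
    -------
    pandas.DataFrame with columns frame_index, point_index (1-based),
    x_px, y_px.
    """
    import pandas as pd

    if n_points < 2:
        raise InvalidParamsError("need at least 2 annotation points")
    if click_sd_px < 0:
        raise InvalidParamsError("click_sd_px must be >= 0")
    step = max(1, int(round(interval_s * frame_rate)))
    rng = np.random.default_rng(seed)
    rows = []
    by_index = dict(midlines)
    for fi in sorted(by_index):
        if fi % step != 0:
            continue
        mid = np.asarray(by_index[fi], dtype=float)
        seg = np.diff(mid, axis=0)
        s = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
        targets = np.linspace(0.0, s[-1], n_points)
        px = np.interp(targets, s, mid[:, 0])
        py = np.interp(targets, s, mid[:, 1])
        if click_sd_px > 0:
            px = px + rng.normal(0.0, click_sd_px, n_points)
            py = py + rng.normal(0.0, click_sd_px, n_points)
        for j in range(n_points):
            rows.append((fi, j + 1, px[j], py[j]))
    return pd.DataFrame(rows, columns=["frame_index", "point_index", "x_px", "y_px"])
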