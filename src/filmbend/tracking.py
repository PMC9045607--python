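"""Classical row-scan tracker for a dark filament on a light background.

Pipeline per frame: threshold to a binary mask, collect per-row midline
candidates (single foreground mean, or a two-cluster split when the filament
curls and crosses a row twice), assemble the candidates into a single ordered
root-to-tip path, and report the tip angle as the principal direction of the
distal quarter of the path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .errors import (
    DegenerateTipError,
    EmptyFrameError,
    EmptySeriesError,
    TooShortPathError,
)

__all__ = [
    "TrackerConfig",
    "BinaryFrame",
    "FilamentPath",
    "TrackResult",
    "binarize",
    "row_midpoints",
    "assemble_path",
    "tip_angle",
    "track_frame",
    "track_sequence",
    "compare_to_manual",
]


@dataclass(frozen=True)
class TrackerConfig:
    """Tunable knobs of the row-scan tracker.

    ``threshold`` overrides Otsu with a fixed gray level; foreground is the
    dark side.  ``tip_fraction`` is the distal arc-length fraction that
    defines the tip.  A two-cluster row split is accepted only when both
    clusters have at least ``min_cluster_px`` pixels (default
    ``max(3, 0.5*thickness)``) and their centroids are at least
    ``cluster_sep_factor`` filament thicknesses apart.  Consecutive path
    points farther apart than ``max_gap_factor`` thicknesses truncate the
    path and set the ``broken`` flag.
    """

    threshold: float | None = None
    tip_fraction: float = 0.25
    min_cluster_px: int | None = None
    cluster_sep_factor: float = 1.5
    max_gap_factor: float = 6.0
    smooth_window: int = 5
    frame_rate: float = 30.0
    unwrap: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.tip_fraction < 1.0:
            raise ValueError("tip_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class BinaryFrame:
    mask: np.ndarray  # bool, True = filament
    frame_index: int = 0
    timestamp: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class FilamentPath:
    """Ordered root-to-tip midline of one frame."""

    points: np.ndarray  # (N, 2) pixel coords, root first
    arc_length: np.ndarray  # cumulative arc length, px
    broken: bool = False
    curled: bool = False
    thickness_px: float = float("nan")

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])


def binarize(
    frame, config: TrackerConfig | None = None, frame_index: int = 0, timestamp: float = 0.0
) -> BinaryFrame:
    """Threshold a frame to a binary mask with the dark side as foreground.

    Boolean input is taken as an already-binary mask (True = filament), so the
    operation is idempotent.  Color input is converted to luminance first.
    """
    if isinstance(frame, BinaryFrame):
        return frame
    config = config or TrackerConfig()
    arr = np.asarray(frame)
    if arr.dtype == bool:
        mask = arr
    else:
        if arr.ndim == 3:
            arr = arr[..., :3] @ np.array([0.2125, 0.7154, 0.0721])
        arr = arr.astype(float)
        if config.threshold is not None:
            thr = float(config.threshold)
        else:
            if np.ptp(arr) == 0:
                raise EmptyFrameError(
                    f"frame {frame_index}: uniform image, no foreground"
                )
            thr = float(threshold_otsu(arr))
        mask = arr <= thr
    if not mask.any():
        raise EmptyFrameError(f"frame {frame_index}: no foreground pixels")
    return BinaryFrame(mask=mask, frame_index=frame_index, timestamp=timestamp)


def _row_groups(mask: np.ndarray) -> list[tuple[int, np.ndarray]]:
    ys, xs = np.nonzero(mask)  # row-major: ys sorted, xs sorted within a row
    if ys.size == 0:
        return []
    uniq, starts = np.unique(ys, return_index=True)
    bounds = np.append(starts, ys.size)
    return [(int(uniq[i]), xs[bounds[i]: bounds[i + 1]]) for i in range(len(uniq))]


def _runs(cols: np.ndarray) -> list[np.ndarray]:
    if cols.size == 0:
        return []
    brk = np.flatnonzero(np.diff(cols) > 1) + 1
    return np.split(cols, brk)


def _two_means(cols: np.ndarray) -> tuple[float, float, int, int]:
    """Exact 1-D two-means: optimal split of sorted columns by SSE scan.

    Returns (centroid1, centroid2, n1, n2) with centroid1 < centroid2.
    """
    c = cols.astype(float)
    n = c.size
    csum = np.cumsum(c)
    csq = np.cumsum(c * c)
    k = np.arange(1, n)
    s1, q1 = csum[:-1], csq[:-1]
    s2, q2 = csum[-1] - s1, csq[-1] - q1
    sse = (q1 - s1 * s1 / k) + (q2 - s2 * s2 / (n - k))
    j = int(np.argmin(sse))
    k_best = j + 1
    return (
        float(s1[j] / k_best),
        float(s2[j] / (n - k_best)),
        k_best,
        n - k_best,
    )


def estimate_thickness(bframe: BinaryFrame) -> float:
    """Median foreground run length over single-run rows (filament thickness)."""
    groups = _row_groups(bframe.mask)
    lengths = []
    for _, cols in groups:
        runs = _runs(cols)
        if len(runs) == 1:
            lengths.append(runs[0][-1] - runs[0][0] + 1)
    if not lengths:
        lengths = [r[-1] - r[0] + 1 for _, cols in groups for r in _runs(cols)]
    return float(np.median(lengths)) if lengths else 1.0


def row_midpoints(
    bframe: BinaryFrame, config: TrackerConfig | None = None
) -> tuple[list[tuple[int, tuple[float, ...]]], float]:
    """Per-row midline candidates.

    A row crossed once yields the mean foreground column.  A row with two or
    more separated foreground runs is split by exact two-means; the pair is
    accepted when both clusters are substantial and their centroids are
    separated by the typical filament thickness, otherwise the plain mean is
    used.  Returns ``(candidates, thickness)`` where candidates is a list of
    ``(row, (x, ...))`` sorted top to bottom.
    """
    config = config or TrackerConfig()
    groups = _row_groups(bframe.mask)
    if not groups:
        raise EmptyFrameError(f"frame {bframe.frame_index}: no foreground pixels")
    thickness = estimate_thickness(bframe)
    min_px = config.min_cluster_px
    if min_px is None:
        min_px = max(3, int(round(0.5 * thickness)))
    sep = config.cluster_sep_factor * thickness

    out: list[tuple[int, tuple[float, ...]]] = []
    for y, cols in groups:
        runs = _runs(cols)
        if len(runs) >= 2:
            m1, m2, n1, n2 = _two_means(cols)
            if min(n1, n2) >= min_px and (m2 - m1) >= sep:
                out.append((y, (m1, m2)))
                continue
        out.append((y, (float(cols.mean()),)))
    return out, thickness


def assemble_path(
    candidates: Sequence[tuple[int, tuple[float, ...]]],
    config: TrackerConfig | None = None,
    thickness: float = 1.0,
) -> FilamentPath:
    """Order per-row midline candidates into a single root-to-tip path.

    Walks down from the topmost (root) row taking the nearest candidate in
    each row; when rows were split in two (curled filament) the leftover
    up-going branch is then appended bottom-to-top.  A jump larger than
    ``max_gap_factor`` thicknesses truncates the path and flags it broken.
    """
    config = config or TrackerConfig()
    if len(candidates) < 4:
        raise TooShortPathError(
            f"only {len(candidates)} usable rows; need at least 4"
        )
    rows = sorted(candidates, key=lambda rc: rc[0])
    curled = any(len(xs) > 1 for _, xs in rows)

    # Downward pass: one candidate per row, nearest continuation.
    leftovers: list[tuple[int, float]] = []
    y0, xs0 = rows[0]
    if len(xs0) == 1:
        cur_x = xs0[0]
    else:  # root row split: start at the candidate nearest the row centre
        centre = float(np.mean(xs0))
        cur_x = min(xs0, key=lambda x: abs(x - centre))
        leftovers.extend((y0, x) for x in xs0 if x != cur_x)
    down: list[tuple[float, float]] = [(cur_x, float(y0))]
    for y, xs in rows[1:]:
        pick = min(xs, key=lambda x: abs(x - cur_x))
        down.append((pick, float(y)))
        leftovers.extend((y, x) for x in xs if x != pick)
        cur_x = pick

    # Upward pass over the leftover branch, bottom to top.
    up = [(x, float(y)) for y, x in sorted(leftovers, key=lambda t: -t[0])]
    pts = np.asarray(down + up, dtype=float)

    # Gap check and truncation.
    step = np.hypot(*np.diff(pts, axis=0).T)
    max_gap = config.max_gap_factor * max(thickness, 1.0)
    broken = False
    bad = np.flatnonzero(step > max_gap)
    if bad.size:
        pts = pts[: bad[0] + 1]
        step = step[: bad[0]]
        broken = True
    if len(pts) < 4:
        raise TooShortPathError("path truncated below 4 points")
    # Per-row midpoints carry sub-pixel quantization jitter that inflates the
    # polyline length; a short moving average along the path removes it.  The
    # root point is kept exact (topmost filament row).
    if config.smooth_window > 1:
        from scipy.ndimage import uniform_filter1d

        root = pts[0].copy()
        pts[:, 0] = uniform_filter1d(pts[:, 0], size=config.smooth_window,
                                     mode="nearest")
        pts[0] = root
        step = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(step)])
    return FilamentPath(
        points=pts, arc_length=arc, broken=broken, curled=curled,
        thickness_px=thickness,
    )


def tip_angle(
    path: FilamentPath,
    config: TrackerConfig | None = None,
    mask: np.ndarray | None = None,
) -> float:
    """Tip angle: first principal direction of the points comprising the
    distal ``tip_fraction`` of the filament, sign-oriented from the segment's
    proximal end to the tip endpoint (deg, CCW from +x; straight down = -90).

    With only a path, the PCA runs over the path points of the tip segment.
    When the binary ``mask`` is supplied, it runs over all foreground pixels
    belonging to the tip segment (nearer to it than to the rest of the path),
    which is unbiased even where the tip runs nearly parallel to the scan
    rows and per-row midpoints sample it sparsely.
    """
    config = config or TrackerConfig()
    cut = (1.0 - config.tip_fraction) * path.length
    i = int(np.searchsorted(path.arc_length, cut))
    i = min(i, len(path.points) - 2)
    seg = path.points[i:]
    if len(seg) < 2:
        raise DegenerateTipError("tip segment has fewer than 2 points")
    src = seg
    if mask is not None:
        pix = _tip_pixels(path, i, mask)
        if pix is not None and len(pix) >= 3:
            src = pix
    pts = np.column_stack([src[:, 0], -src[:, 1]])  # math frame, y up
    centred = pts - pts.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] <= 1e-12:
        raise DegenerateTipError("tip-segment points are coincident")
    v = vt[0]
    chord = np.array([seg[-1, 0] - seg[0, 0], -(seg[-1, 1] - seg[0, 1])])
    if float(v @ chord) < 0:
        v = -v
    return math.degrees(math.atan2(v[1], v[0]))


def _tip_pixels(path: FilamentPath, i: int, mask: np.ndarray) -> np.ndarray | None:
    """Foreground pixels belonging to the tip segment: pixels inside the tip
    segment's bounding box (one thickness of margin) that lie nearer to the
    tip portion of the path than to the rest of it."""
    thick = path.thickness_px if np.isfinite(path.thickness_px) else 3.0
    margin = max(thick, 3.0)
    seg = path.points[i:]
    rest = path.points[:i]
    x0 = max(0, int(seg[:, 0].min() - margin))
    x1 = min(mask.shape[1] - 1, int(math.ceil(seg[:, 0].max() + margin)))
    y0 = max(0, int(seg[:, 1].min() - margin))
    y1 = min(mask.shape[0] - 1, int(math.ceil(seg[:, 1].max() + margin)))
    ys, xs = np.nonzero(mask[y0: y1 + 1, x0: x1 + 1])
    if ys.size == 0:
        return None
    pix = np.column_stack([xs + x0, ys + y0]).astype(float)
    d_tip = _min_dist(pix, seg)
    keep = d_tip <= margin
    if rest.size:
        keep &= d_tip < _min_dist(pix, rest)
    pix = pix[keep]
    return pix if len(pix) >= 3 else None


def _min_dist(pts: np.ndarray, ref: np.ndarray) -> np.ndarray:
    # subsample long references: nearest-point distance only needs ~1 px grid
    if len(ref) > 64:
        ref = ref[:: max(1, len(ref) // 64)]
    d2 = (
        (pts[:, 0, None] - ref[None, :, 0]) ** 2
        + (pts[:, 1, None] - ref[None, :, 1]) ** 2
    )
    return np.sqrt(d2.min(axis=1))


def track_frame(frame, config: TrackerConfig | None = None,
                frame_index: int = 0) -> tuple[float, FilamentPath]:
    """Binarize, extract and order the midline, and measure the tip angle."""
    config = config or TrackerConfig()
    bf = binarize(frame, config, frame_index=frame_index)
    cands, thickness = row_midpoints(bf, config)
    path = assemble_path(cands, config, thickness)
    path = _extend_to_tip(path, bf.mask)
    return tip_angle(path, config, mask=bf.mask), path


def _extend_to_tip(path: FilamentPath, mask: np.ndarray) -> FilamentPath:
    """Extend the path's final point to the farthest foreground pixel along
    the local tangent.

    Where the filament runs nearly parallel to the scan rows, the mean of the
    last foreground run sits well short of the true tip; the remaining stroke
    pixels recover it.
    """
    thick = path.thickness_px if np.isfinite(path.thickness_px) else 3.0
    pts = path.points
    k = int(np.searchsorted(path.arc_length, path.length - 3.0 * thick))
    k = min(k, len(pts) - 2)
    tangent = pts[-1] - pts[k]
    norm = float(np.hypot(*tangent))
    if norm <= 0:
        return path
    tangent = tangent / norm
    end = pts[-1]
    m = max(1.0, 4.0 * thick)
    x0 = max(0, int(end[0] - m)); x1 = min(mask.shape[1] - 1, int(end[0] + m))
    y0 = max(0, int(end[1] - m)); y1 = min(mask.shape[0] - 1, int(end[1] + m))
    ys, xs = np.nonzero(mask[y0: y1 + 1, x0: x1 + 1])
    if ys.size == 0:
        return path
    rel = np.column_stack([xs + x0 - end[0], ys + y0 - end[1]]).astype(float)
    proj = rel @ tangent
    perp = np.abs(rel @ np.array([-tangent[1], tangent[0]]))
    ahead = proj[(proj > 0.5) & (perp <= 0.75 * thick)]
    if ahead.size == 0:
        return path
    new_end = end + tangent * float(ahead.max())
    new_pts = np.vstack([pts, new_end])
    arc = np.append(path.arc_length, path.length + float(ahead.max()))
    return FilamentPath(
        points=new_pts, arc_length=arc, broken=path.broken,
        curled=path.curled, thickness_px=path.thickness_px,
    )


@dataclass(frozen=True)
class TrackResult:
    """Per-frame tip angles of a sequence; unusable frames are NaN gaps."""

    times: np.ndarray
    theta: np.ndarray  # deg; NaN where tracking failed
    gap: np.ndarray  # bool, True where the frame was unusable
    broken: np.ndarray
    curled: np.ndarray
    paths: list[FilamentPath | None] = field(repr=False, default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.times)


def track_sequence(
    frames: Iterable, config: TrackerConfig | None = None,
    keep_paths: bool = True,
) -> TrackResult:
    """Track an ordered frame sequence.

    ``frames`` may yield bare arrays (timestamps are frame_index/frame_rate)
    or objects with ``image``/``time_s``/``frame_index`` attributes (e.g.
    rendered synthetic frames).  Frames that raise tracking errors become
    flagged NaN gaps, never silent interpolations.  Consecutive angles are
    unwrapped to the nearest branch (|step| <= 180 deg) when configured.
    """
    config = config or TrackerConfig()
    times, theta, gap, broken, curled = [], [], [], [], []
    paths: list[FilamentPath | None] = []
    n = 0
    for item in frames:
        if hasattr(item, "image"):
            img = item.image
            t = getattr(item, "time_s", n / config.frame_rate)
            fi = getattr(item, "frame_index", n)
        else:
            img, t, fi = item, n / config.frame_rate, n
        try:
            ang, path = track_frame(img, config, frame_index=fi)
            theta.append(ang)
            gap.append(False)
            broken.append(path.broken)
            curled.append(path.curled)
            paths.append(path if keep_paths else None)
        except (EmptyFrameError, TooShortPathError, DegenerateTipError):
            theta.append(np.nan)
            gap.append(True)
            broken.append(False)
            curled.append(False)
            paths.append(None)
        times.append(t)
        n += 1
    theta_arr = np.asarray(theta, dtype=float)
    if n == 0 or not np.isfinite(theta_arr).any():
        raise EmptySeriesError("no frame produced a usable tip angle")
    if config.unwrap:
        theta_arr = _unwrap_nearest(theta_arr)
    return TrackResult(
        times=np.asarray(times, dtype=float),
        theta=theta_arr,
        gap=np.asarray(gap, dtype=bool),
        broken=np.asarray(broken, dtype=bool),
        curled=np.asarray(curled, dtype=bool),
        paths=paths,
    )


def _unwrap_nearest(theta: np.ndarray) -> np.ndarray:
    """Shift each angle by a multiple of 360 to sit within 180 deg of the
    previous finite angle (nearest-branch continuation)."""
    out = theta.copy()
    prev = np.nan
    for i, v in enumerate(out):
        if not np.isfinite(v):
            continue
        if np.isfinite(prev):
            out[i] = v + 360.0 * round((prev - v) / 360.0)
        prev = out[i]
    return out


def manual_midline(points: np.ndarray, n_dense: int = 200) -> FilamentPath:
    """Densify clicked points into a midline by cubic-spline interpolation,
    parameterized by cumulative chordal distance."""
    from scipy.interpolate import CubicSpline

    pts = np.asarray(points, dtype=float)
    seg = np.diff(pts, axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    if s[-1] <= 0:
        raise DegenerateTipError("annotation points are coincident")
    sx = CubicSpline(s, pts[:, 0])
    sy = CubicSpline(s, pts[:, 1])
    sd = np.linspace(0.0, s[-1], n_dense)
    dense = np.column_stack([sx(sd), sy(sd)])
    dseg = np.diff(dense, axis=0)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(dseg[:, 0], dseg[:, 1]))])
    return FilamentPath(points=dense, arc_length=arc)


@dataclass(frozen=True)
class ManualComparison:
    r_squared: float
    coefficients: np.ndarray  # cubic polynomial, highest degree first
    frame_indices: np.ndarray
    manual_angles: np.ndarray
    auto_angles: np.ndarray


def compare_to_manual(
    auto: TrackResult, annotations, config: TrackerConfig | None = None
) -> ManualComparison:
    """Validate automatic tracking against manual click annotations.

    For each annotated frame the manual midline is rebuilt by cubic-spline
    interpolation through the clicked points and its tip angle measured with
    the same tip-angle operation; a cubic polynomial predicting the automatic
    angles from the manual ones is then fit, and the squared Pearson
    correlation between prediction and automatic values is reported.
    """
    from .calibration import r_squared

    config = config or TrackerConfig()
    frames, man, aut = [], [], []
    for fi, grp in annotations.groupby("frame_index"):
        grp = grp.sort_values("point_index")
        pts = grp[["x_px", "y_px"]].to_numpy(dtype=float)
        if fi >= len(auto.theta) or not np.isfinite(auto.theta[fi]):
            continue
        path = manual_midline(pts)
        frames.append(int(fi))
        man.append(tip_angle(path, config))
        aut.append(float(auto.theta[fi]))
    if len(frames) < 4:
        raise TooShortPathError("need annotations on at least 4 tracked frames")
    man_arr = np.asarray(man)
    aut_arr = np.asarray(aut)
    if np.ptp(man_arr) == 0:
        from .errors import UndefinedCorrelationError

        raise UndefinedCorrelationError("manual tip-angle series is constant")
    coefs = np.polyfit(man_arr, aut_arr, 3)
    pred = np.polyval(coefs, man_arr)
    r2 = r_squared(pred, aut_arr)
    return ManualComparison(
        r_squared=r2,
        coefficients=coefs,
        frame_indices=np.asarray(frames),
        manual_angles=man_arr,
        auto_angles=aut_arr,
    )
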