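"""Shape-ensemble dimensionality analysis.

Every tracked midline is resampled to a fixed number of arc-length-equidistant
points and the pooled ensemble (all frames, all exposures) is decomposed by
PCA.  Coordinates all share pixel units, so no per-coordinate standardization
is applied, and no Procrustes alignment is performed: the overall orientation
of the filament *is* the measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .errors import InvalidParamsError, ZeroVarianceError
from .tracking import FilamentPath

__all__ = [
    "ShapeModes",
    "resample_path",
    "build_shape_ensemble",
    "shape_pca",
    "cumulative_variance",
    "reconstruct",
]


def resample_path(path: FilamentPath, P: int) -> np.ndarray:
    """Resample a midline to ``P`` points equally spaced in arc length and
    concatenate into a 2P vector (all x coordinates, then all y)."""
    if P < 2:
        raise InvalidParamsError("P must be >= 2")
    if path.length <= 0:
        raise InvalidParamsError("path has zero arc length")
    s = np.linspace(0.0, path.length, P)
    x = np.interp(s, path.arc_length, path.points[:, 0])
    y = np.interp(s, path.arc_length, path.points[:, 1])
    return np.concatenate([x, y])


def build_shape_ensemble(
    paths, P: int, nominal_length: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a collection of paths into an (n, 2P) matrix.

    Entries that are None, or broken paths shorter than half the nominal
    filament length, are excluded; the returned boolean mask marks which input
    positions were kept.
    """
    rows, kept = [], []
    for p in paths:
        ok = p is not None and p.length > 0
        if ok and nominal_length is not None and p.broken:
            ok = p.length >= 0.5 * nominal_length
        kept.append(bool(ok))
        if ok:
            rows.append(resample_path(p, P))
    if not rows:
        raise ZeroVarianceError("no usable shapes in the ensemble")
    return np.asarray(rows), np.asarray(kept, dtype=bool)


@dataclass(frozen=True)
class ShapeModes:
    """Mean shape, orthonormal principal directions and variance spectrum of a
    pooled shape ensemble."""

    mean_shape: np.ndarray  # 2P vector
    components: np.ndarray  # (n_components, 2P), orthonormal rows
    explained_variance: np.ndarray  # fractions, sum to 1
    P: int

    @property
    def n_components(self) -> int:
        return len(self.explained_variance)

    def project(self, shape: np.ndarray, k: int | None = None) -> np.ndarray:
        comps = self.components if k is None else self.components[:k]
        return comps @ (np.asarray(shape) - self.mean_shape)


def shape_pca(shapes: np.ndarray) -> ShapeModes:
    """Mean-centered PCA over a pooled (n_shapes, 2P) ensemble, components
    ordered by decreasing variance."""
    X = np.asarray(shapes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidParamsError("need at least 2 shapes")
    total_var = float(np.var(X - X.mean(axis=0)))
    if total_var <= 1e-24:
        raise ZeroVarianceError("all shapes are identical")
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    pca.fit(X)
    return ShapeModes(
        mean_shape=pca.mean_,
        components=pca.components_,
        explained_variance=pca.explained_variance_ratio_,
        P=X.shape[1] // 2,
    )


def cumulative_variance(modes: ShapeModes, k: int) -> float:
    """Fraction of total shape variance explained by the first k components."""
    if not 1 <= k <= modes.n_components:
        raise InvalidParamsError(
            f"k must be in 1..{modes.n_components}, got {k}"
        )
    return float(np.sum(modes.explained_variance[:k]))


def reconstruct(modes: ShapeModes, coefficients) -> np.ndarray:
    """Mean shape plus a linear combination of the leading components."""
    c = np.asarray(coefficients, dtype=float)
    if c.size > modes.n_components:
        raise InvalidParamsError("more coefficients than components")
    return modes.mean_shape + c @ modes.components[: c.size]


def shape_tip_angle(shape: np.ndarray, tip_fraction: float = 0.25) -> float:
    """Tip angle of a 2P shape vector (same convention as the tracker)."""
    from .tracking import FilamentPath, tip_angle, TrackerConfig

    P = shape.size // 2
    pts = np.column_stack([shape[:P], shape[P:]])
    seg = np.diff(pts, axis=0)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    path = FilamentPath(points=pts, arc_length=arc)
    return tip_angle(path, TrackerConfig(tip_fraction=tip_fraction))
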