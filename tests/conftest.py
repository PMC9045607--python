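import numpy as np
import pytest

from filmbend.synthetic import (
    GeneratorParams,
    generate_exposure_design,
    render_frames,
    simulate_session,
    standard_solutions,
)
from filmbend.tracking import TrackerConfig, track_sequence


@pytest.fixture(scope="session")
def solutions():
    return standard_solutions()


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free generator at the analysis frame rate (5 Hz)."""
    return GeneratorParams(frame_rate=5.0, sigma_theta=0.0)


@pytest.fixture(scope="session")
def small_session(solutions, quiet_params):
    """One noise-free permutation block with short exposures, rendered and
    tracked end to end; shared across tests that need a realistic session."""
    design = generate_exposure_design(1, solutions, seed=11, exposure_s=30.0)
    series = simulate_session(design, quiet_params, seed=12)
    tracked = track_sequence(
        render_frames(series, quiet_params), TrackerConfig(frame_rate=5.0)
    )
    return design, series, tracked


def straight_bar_mask(angle_deg: float, length: float = 120.0,
                      thickness: float = 5.0, shape=(200, 300),
                      root=(150.0, 12.0)) -> np.ndarray:
    """Binary mask of a straight stroke from a root point at a given angle
    (deg, CCW from +x, image y down)."""
    mask = np.zeros(shape, dtype=bool)
    t = np.linspace(0.0, length, int(length * 2))
    x = root[0] + np.cos(np.deg2rad(angle_deg)) * t
    y = root[1] - np.sin(np.deg2rad(angle_deg)) * t
    r = int(np.ceil(thickness / 2))
    dy, dx = np.mgrid[-r: r + 1, -r: r + 1]
    keep = dx * dx + dy * dy <= (thickness / 2) ** 2
    offs = np.column_stack([dx[keep], dy[keep]])
    cols = (np.rint(x)[:, None] + offs[:, 0]).astype(int).ravel()
    rows = (np.rint(y)[:, None] + offs[:, 1]).astype(int).ravel()
    mask[rows.clip(0, shape[0] - 1), cols.clip(0, shape[1] - 1)] = True
    return mask
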