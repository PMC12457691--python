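import numpy as np
import pytest

import rodtrack as rt


@pytest.fixture(scope="session")
def stadium():
    """Straight rod (stadium) contour, length 4 µm tip-to-tip, width 0.8 µm."""
    poly, centerline = rt.simulate_bent_rod_contour(
        rt.ContourSimConfig(length=4.0, width=0.8, curvature=0.0)
    )
    return poly, centerline


@pytest.fixture(scope="session")
def bent_rod():
    """Bent rod with curvature 0.2 µm⁻¹."""
    poly, centerline = rt.simulate_bent_rod_contour(
        rt.ContourSimConfig(length=4.0, width=0.8, curvature=0.2)
    )
    return poly, centerline


@pytest.fixture(scope="session")
def brownian_cohort():
    """2000 Brownian 30-frame tracks at D = 0.01 µm²/s, no noise (seeded)."""
    cfg = rt.TrajectorySimConfig(
        n_traj=2000,
        frac_directed=0.0,
        frac_slow=1.0,
        d_slow=0.01,
        d_fast=0.01,
        n_frames=30,
        t_lag=1.0,
        loc_noise_sd=0.0,
        seed=11,
    )
    tracks, truth = rt.simulate_trajectories(cfg)
    return cfg, tracks, truth


def ballistic_track(v=0.05, t_lag=1.0, n=20, angle=0.3):
    """Noise-free straight-line trajectory as a track table."""
    import pandas as pd

    t = np.arange(n)
    x = v * t_lag * t * np.cos(angle)
    y = v * t_lag * t * np.sin(angle)
    return pd.DataFrame(
        {"traj_id": 0, "frame": t, "t_s": t * t_lag, "x_um": x, "y_um": y}
    )
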