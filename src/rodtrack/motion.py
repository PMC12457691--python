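"""MSD computation and directed/diffusive motion classification.

A trajectory is classified by comparing its mean-squared-displacement curve
over a short fit window to a ballistic model (MSD = (v t)², fitted linearly
as sqrt(MSD) = v t) and to a Brownian model (MSD = 4 D t). A track is
*directed* when the ballistic fit reaches R² >= ``r2_dir`` (checked first —
a ballistic track also fits a line well), otherwise *diffusive* when the
linear fit reaches R² >= ``r2_diff``, otherwise *unclassified*. Tracks
shorter than the minimum duration are not classified at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from rodtrack.errors import ConfigError

CLASSIFICATION_COLUMNS = [
    "traj_id",
    "label",
    "r2_dir",
    "r2_diff",
    "speed_um_s",
    "d_msd_um2_s",
    "n_frames",
]


@dataclass
class MSDProfile:
    """Time-averaged MSD of one trajectory (lag 0 excluded).

    ``msd[i]`` is the mean over all overlapping pairs ``(j, j+n_i)`` of the
    squared displacement at lag ``lags[i] = n_i * t_lag`` seconds, and
    ``n_pairs[i]`` the number of pairs averaged.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    n_points: int


@dataclass
class MotionClassification:
    traj_id: int
    label: str  # directed | diffusive | unclassified | too_short
    r2_dir: float
    r2_diff: float
    speed_um_s: float  # NaN unless directed
    d_msd_um2_s: float  # NaN unless diffusive
    n_frames: int


@dataclass
class DensityEstimate:
    """Surface density of directed foci, µm⁻²."""

    mean_density: float
    sd_density: float
    per_frame: np.ndarray
    cell_area_um2: float
    n_directed_tracks: int


def compute_msd(traj: pd.DataFrame, t_lag: float, max_lag_frames: int | None = None) -> MSDProfile:
    """Time-averaged MSD with the overlapping-pair estimator.

    ``traj`` holds one trajectory (columns ``x_um, y_um``, consecutive
    frames). Lags run from 1 to ``max_lag_frames`` (default: track length
    minus one).
    """
    xy = traj[["x_um", "y_um"]].to_numpy()
    n = len(xy)
    if n < 2:
        raise ValueError("compute_msd requires >= 2 points")
    max_lag = n - 1 if max_lag_frames is None else min(max_lag_frames, n - 1)
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=int)
    for i, lag in enumerate(lags):
        d = xy[lag:] - xy[:-lag]
        msd[i] = np.mean(np.sum(d * d, axis=1))
        n_pairs[i] = n - lag
    return MSDProfile(lags=lags * t_lag, msd=msd, n_pairs=n_pairs, n_points=n)


def _fit_window(n_points: int) -> int:
    """Number of MSD lags used for model fits: min(n/4, 10), at least 2."""
    return max(2, min(n_points // 4, 10))


def classify_trajectory(
    msd: MSDProfile,
    r2_dir: float = 0.9,
    r2_diff: float = 0.8,
    min_frames: int = 10,
    traj_id: int = -1,
) -> MotionClassification:
    """Label one trajectory as directed, diffusive or unclassified.

    Both models are zero-intercept least-squares fits over the first
    ``min(n/4, 10)`` lags: the ballistic model on sqrt(MSD) vs t (linear in
    the speed v) and the Brownian model MSD = 4 D t. R² = 1 − SS_res/SS_tot
    on the fit window. A degenerate all-zero MSD is a perfect fit of the
    zero-diffusion model.
    """
    if msd.n_points < min_frames:
        return MotionClassification(traj_id, "too_short", np.nan, np.nan, np.nan, np.nan, msd.n_points)
    k = _fit_window(msd.n_points)
    t = msd.lags[:k]
    y = msd.msd[:k]
    if np.all(y == 0):
        return MotionClassification(traj_id, "diffusive", np.nan, 1.0, np.nan, 0.0, msd.n_points)

    s = np.sqrt(y)
    v = float(np.sum(t * s) / np.sum(t * t))
    ss_tot_s = float(np.sum((s - s.mean()) ** 2))
    r2d = 1.0 - float(np.sum((s - v * t) ** 2)) / ss_tot_s if ss_tot_s > 0 else 1.0

    d = float(np.sum(t * y) / np.sum(t * t) / 4.0)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2f = 1.0 - float(np.sum((y - 4.0 * d * t) ** 2)) / ss_tot if ss_tot > 0 else 1.0

    if r2d >= r2_dir:
        return MotionClassification(traj_id, "directed", r2d, r2f, v, np.nan, msd.n_points)
    if r2f >= r2_diff:
        return MotionClassification(traj_id, "diffusive", r2d, r2f, np.nan, d, msd.n_points)
    return MotionClassification(traj_id, "unclassified", r2d, r2f, np.nan, np.nan, msd.n_points)


def classify_tracks(
    tracks: pd.DataFrame,
    t_lag: float,
    r2_dir: float = 0.9,
    r2_diff: float = 0.8,
    min_frames: int = 10,
) -> pd.DataFrame:
    """Classify every trajectory in a track table.

    Returns one row per trajectory with columns
    ``traj_id, label, r2_dir, r2_diff, speed_um_s, d_msd_um2_s, n_frames``.
    """
    rows = []
    for tid, grp in tracks.groupby("traj_id"):
        msd = compute_msd(grp.sort_values("frame"), t_lag)
        c = classify_trajectory(msd, r2_dir, r2_diff, min_frames, traj_id=int(tid))
        rows.append(
            (c.traj_id, c.label, c.r2_dir, c.r2_diff, c.speed_um_s, c.d_msd_um2_s, c.n_frames)
        )
    return pd.DataFrame(rows, columns=CLASSIFICATION_COLUMNS)


def summarize_directed(classifications: pd.DataFrame) -> dict:
    """Speed statistics and directional fraction of a classified cohort.

    The fraction is directed / (directed + diffusive + unclassified), i.e.
    over tracks long enough to classify. With zero directed tracks the speed
    entries are ``None`` (missing, not zero).
    """
    cls = classifications[classifications["label"] != "too_short"]
    if len(cls) == 0:
        raise ValueError("no classifiable trajectories")
    directed = cls[cls["label"] == "directed"]
    n_dir = len(directed)
    out = {
        "n_classifiable": int(len(cls)),
        "n_directed": n_dir,
        "directional_fraction": n_dir / len(cls),
        "mean_speed_um_s": float(directed["speed_um_s"].mean()) if n_dir else None,
        "median_speed_um_s": float(directed["speed_um_s"].median()) if n_dir else None,
        "sd_speed_um_s": float(directed["speed_um_s"].std(ddof=1)) if n_dir > 1 else None,
    }
    return out


def compute_density(
    classifications: pd.DataFrame,
    tracks: pd.DataFrame,
    mask: Polygon | np.ndarray,
    n_frames: int,
    pixel_size: float | None = None,
) -> DensityEstimate:
    """Mean surface density of directionally moving foci, µm⁻².

    Per frame, the number of directed-classified foci located inside the
    cell mask is divided by the mask area; the mean (and SD) over the
    ``n_frames`` observation frames is reported.

    ``mask`` is a shapely polygon in µm, or a binary/label image with
    ``pixel_size``.
    """
    if isinstance(mask, Polygon):
        area = mask.area
        contains = lambda x, y: mask.contains(Point(x, y))  # noqa: E731
    else:
        if pixel_size is None:
            raise ConfigError("pixel_size is required with an image mask")
        area = float(np.count_nonzero(mask)) * pixel_size**2

        def contains(x, y):
            r, c = int(round(y / pixel_size)), int(round(x / pixel_size))
            return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c] > 0

    if not area > 0:
        raise ConfigError("mask area must be > 0")

    directed_ids = set(classifications.loc[classifications["label"] == "directed", "traj_id"])
    counts = np.zeros(n_frames)
    sub = tracks[tracks["traj_id"].isin(directed_ids)]
    for _, row in sub.iterrows():
        f = int(row["frame"])
        if 0 <= f < n_frames and contains(row["x_um"], row["y_um"]):
            counts[f] += 1
    per_frame = counts / area
    return DensityEstimate(
        mean_density=float(per_frame.mean()),
        sd_density=float(per_frame.std(ddof=1)) if n_frames > 1 else 0.0,
        per_frame=per_frame,
        cell_area_um2=float(area),
        n_directed_tracks=len(directed_ids),
    )
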