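"""Spot detection and trajectory linking.

Detection uses a scale-matched Laplacian-of-Gaussian filter (the standard
detector for diffraction-limited foci) with sub-pixel refinement; linking is
frame-to-frame optimal assignment (LAP) under a maximum displacement, with no
gap closing (a trajectory ends as soon as no admissible match exists in the
next frame).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from shapely.geometry import Point, Polygon
from skimage.feature import peak_local_max

from rodtrack.errors import ConfigError
from rodtrack.imaging import ImageStack

DETECTION_COLUMNS = ["frame", "x_um", "y_um", "quality", "intensity"]
TRACKMATE_COLUMNS = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y", "POSITION_T", "QUALITY"]


def _subpixel_offset(patch3: np.ndarray) -> float:
    """Quadratic-peak offset from a 1-D triple (v[-1], v[0], v[+1])."""
    denom = patch3[0] - 2.0 * patch3[1] + patch3[2]
    if denom >= 0:  # not a local max along this axis
        return 0.0
    off = 0.5 * (patch3[0] - patch3[2]) / denom
    return float(np.clip(off, -0.5, 0.5))


def detect_spots(
    stack: ImageStack,
    radius_um: float = 0.25,
    threshold: float = 100.0,
) -> pd.DataFrame:
    """Detect diffraction-limited foci in every frame.

    The frame is filtered with a scale-normalized LoG at
    ``sigma = radius_um / sqrt(2)``; local maxima of the (sign-flipped)
    response above ``threshold`` and at least ``radius_um`` apart are kept
    and refined to sub-pixel precision by a quadratic fit to the 3x3
    response neighbourhood.

    Note that the threshold is in response units tied to the image intensity
    scaling, so it must be chosen relative to the data (as in TrackMate).

    Returns a table with columns ``frame, x_um, y_um, quality, intensity``.
    """
    sigma_px = radius_um / math.sqrt(2.0) / stack.pixel_size
    if radius_um < stack.pixel_size:
        raise ConfigError(
            f"radius_um={radius_um} is smaller than one pixel ({stack.pixel_size} µm)"
        )
    min_dist_px = max(int(round(radius_um / stack.pixel_size)), 1)

    rows = []
    for f in range(stack.n_frames):
        img = np.asarray(stack.pixels[f], dtype=float)
        resp = -(sigma_px**2) * ndimage.gaussian_laplace(img, sigma_px)
        peaks = peak_local_max(
            resp, min_distance=min_dist_px, threshold_abs=threshold, exclude_border=1
        )
        for r, c in peaks:
            dy = _subpixel_offset(resp[r - 1 : r + 2, c])
            dx = _subpixel_offset(resp[r, c - 1 : c + 2])
            rows.append(
                (
                    f,
                    (c + dx) * stack.pixel_size,
                    (r + dy) * stack.pixel_size,
                    float(resp[r, c]),
                    float(img[r, c]),
                )
            )
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def _assign_frame_pair(
    prev_xy: np.ndarray, curr_xy: np.ndarray, max_dist: float
) -> list[tuple[int, int]]:
    """Optimal links between two frames.

    Solved as a LAP on the augmented cost matrix ``[[C, D], [B, 0]]`` where
    ``C`` holds squared distances (inadmissible pairs blocked), and the
    death/birth diagonals cost ``max_dist**2`` each, so any admissible link
    is preferred over leaving both endpoints unmatched and the total squared
    displacement is minimized among maximal admissible matchings.
    """
    n1, n2 = len(prev_xy), len(curr_xy)
    if n1 == 0 or n2 == 0:
        return []
    d2 = ((prev_xy[:, None, :] - curr_xy[None, :, :]) ** 2).sum(axis=2)
    cap = max_dist**2
    big = 4.0 * cap * (n1 + n2 + 1)
    cost = np.full((n1 + n2, n1 + n2), 0.0)
    link = np.where(d2 <= cap, d2, big)
    cost[:n1, :n2] = link
    cost[:n1, n2:] = np.where(np.eye(n1, dtype=bool), cap, big)
    cost[n1:, :n2] = np.where(np.eye(n2, dtype=bool), cap, big)
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n1 and c < n2 and d2[r, c] <= cap
    ]


def link_detections(
    detections: pd.DataFrame,
    max_dist_um: float = 0.4,
    max_gap: int = 0,
    t_lag: float | None = None,
) -> pd.DataFrame:
    """Link per-frame detections into trajectories.

    Frame-to-frame assignment minimizes total squared displacement subject to
    ``max_dist_um``; unmatched detections start new trajectories and a
    trajectory ends when no admissible match exists in the next frame.

    Parameters
    ----------
    detections
        Table with at least ``frame, x_um, y_um`` (``quality``/``intensity``
        carried through if present); need not be sorted.
    max_dist_um
        Maximum linking displacement between consecutive frames, µm.
    max_gap
        Only 0 is supported: no gap closing.
    t_lag
        Frame interval used to fill the ``t_s`` column (taken from an
        existing ``t_s`` column if absent).

    Returns a track table with ``traj_id, frame, t_s, x_um, y_um`` plus any
    carried columns, sorted by (traj_id, frame).
    """
    if max_gap != 0:
        raise ConfigError("max_gap must be 0: gap closing is not supported")
    if detections.empty:
        return pd.DataFrame(columns=["traj_id", "frame", "t_s", "x_um", "y_um"])
    det = detections.sort_values("frame", kind="stable").reset_index(drop=True)
    frames = det["frame"].to_numpy()
    xy = det[["x_um", "y_um"]].to_numpy()

    traj_of = np.full(len(det), -1, dtype=int)
    next_id = 0
    active: dict[int, int] = {}  # traj_id -> row index of its last detection
    for f in np.unique(frames):
        idx = np.flatnonzero(frames == f)
        prev_ids = [tid for tid, ri in active.items() if frames[ri] == f - 1]
        prev_rows = np.array([active[tid] for tid in prev_ids], dtype=int)
        links = (
            _assign_frame_pair(xy[prev_rows], xy[idx], max_dist_um) if len(prev_ids) else []
        )
        matched_curr = set()
        for pi, ci in links:
            tid = prev_ids[pi]
            traj_of[idx[ci]] = tid
            active[tid] = int(idx[ci])
            matched_curr.add(ci)
        for ci in range(len(idx)):
            if ci not in matched_curr:
                traj_of[idx[ci]] = next_id
                active[next_id] = int(idx[ci])
                next_id += 1
        # drop tracks that found no continuation
        active = {tid: ri for tid, ri in active.items() if frames[ri] == f}

    out = det.copy()
    out["traj_id"] = traj_of
    if "t_s" not in out.columns:
        out["t_s"] = out["frame"] * (t_lag if t_lag is not None else 1.0)
    cols = ["traj_id", "frame", "t_s", "x_um", "y_um"] + [
        c for c in out.columns if c not in ("traj_id", "frame", "t_s", "x_um", "y_um")
    ]
    return out[cols].sort_values(["traj_id", "frame"]).reset_index(drop=True)


def filter_tracks(
    tracks: pd.DataFrame,
    min_frames: int = 10,
    mask: Polygon | np.ndarray | None = None,
    pixel_size: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Keep trajectories with at least ``min_frames`` points (and, if a mask
    is given, a centroid inside a labelled cell).

    ``mask`` may be a shapely polygon in µm or a label/binary image (then
    ``pixel_size`` is required). Returns the filtered table and a counts
    dict (``n_input, n_kept, n_dropped_short, n_dropped_outside``).
    """
    if tracks.empty:
        return tracks.copy(), {
            "n_input": 0,
            "n_kept": 0,
            "n_dropped_short": 0,
            "n_dropped_outside": 0,
        }
    sizes = tracks.groupby("traj_id").size()
    long_ids = set(sizes[sizes >= min_frames].index)
    n_short = int((sizes < min_frames).sum())

    n_outside = 0
    kept_ids = set()
    centroids = tracks.groupby("traj_id")[["x_um", "y_um"]].mean()
    for tid in long_ids:
        if mask is None:
            kept_ids.add(tid)
            continue
        cx, cy = centroids.loc[tid]
        if isinstance(mask, Polygon):
            inside = mask.contains(Point(cx, cy))
        else:
            if pixel_size is None:
                raise ConfigError("pixel_size is required with an image mask")
            r, c = int(round(cy / pixel_size)), int(round(cx / pixel_size))
            inside = (
                0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c] > 0
            )
        if inside:
            kept_ids.add(tid)
        else:
            n_outside += 1
    out = tracks[tracks["traj_id"].isin(kept_ids)].reset_index(drop=True)
    counts = {
        "n_input": int(len(sizes)),
        "n_kept": int(len(kept_ids)),
        "n_dropped_short": n_short,
        "n_dropped_outside": n_outside,
    }
    return out, counts


def write_tracks_csv(tracks: pd.DataFrame, path) -> None:
    """Write a track table in the TrackMate-compatible column subset."""
    out = pd.DataFrame(
        {
            "TRACK_ID": tracks["traj_id"],
            "FRAME": tracks["frame"],
            "POSITION_X": tracks["x_um"],
            "POSITION_Y": tracks["y_um"],
            "POSITION_T": tracks["t_s"],
            "QUALITY": tracks.get("quality", pd.Series(np.nan, index=tracks.index)),
        }
    )
    out.to_csv(path, index=False)


def read_tracks_csv(path) -> pd.DataFrame:
    """Read a track table in either the internal or the TrackMate format."""
    head = pd.read_csv(path, nrows=0)
    if "traj_id" in head.columns:
        out = pd.read_csv(path)
        return out.sort_values(["traj_id", "frame"]).reset_index(drop=True)
    return read_trackmate_csv(path)


def read_trackmate_csv(path) -> pd.DataFrame:
    """Read a TrackMate spots-export CSV into the internal track table.

    Accepts plain exports as well as TrackMate v7 files whose first rows
    repeat the header in human-readable form (non-numeric rows are dropped).
    """
    raw = pd.read_csv(path)
    missing = [c for c in TRACKMATE_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigError(f"TrackMate CSV is missing columns: {missing}")
    raw = raw[TRACKMATE_COLUMNS].apply(pd.to_numeric, errors="coerce")
    raw = raw.dropna(subset=["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"])
    out = pd.DataFrame(
        {
            "traj_id": raw["TRACK_ID"].astype(int),
            "frame": raw["FRAME"].astype(int),
            "t_s": raw["POSITION_T"],
            "x_um": raw["POSITION_X"],
            "y_um": raw["POSITION_Y"],
            "quality": raw["QUALITY"],
        }
    )
    return out.sort_values(["traj_id", "frame"]).reset_index(drop=True)
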