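"""Synthetic data with known ground truth.

Three generators emulate the statistical structure the analysis pipeline
assumes:

* :func:`simulate_trajectories` — 2-D single-particle trajectories drawn from
  a mixture of two Brownian populations (slow/fast) plus a directed
  subpopulation moving at constant speed, with Gaussian localization noise;
* :func:`simulate_movie` — TIRF-like image stacks of diffraction-limited
  spots inside rod-shaped cell footprints with Poisson–Gaussian noise;
* :func:`simulate_bent_rod_contour` — bent-rod cell outlines with
  controllable curvature, width and length.

Every simulated observation traces back to a ground-truth record so that
detection, linking, classification and estimation can be scored by recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from scipy.special import erf
from shapely.geometry import LineString, Point, Polygon

from rodtrack.errors import ConfigError
from rodtrack.imaging import ImageStack

TRACK_COLUMNS = ["traj_id", "frame", "t_s", "x_um", "y_um", "true_class", "true_param"]


@dataclass
class TrajectorySimConfig:
    """Conditions for trajectory simulation.

    Defaults reproduce a wild-type-like cohort: a directed subpopulation at
    56.5 nm/s, and a diffusive remainder that is a 23%/77% mixture of slow
    (0.0024 µm²/s) and fast (0.0147 µm²/s) Brownian populations, sampled
    at 10 Hz.

    Parameters
    ----------
    n_traj
        Number of trajectories.
    frac_directed
        Fraction of trajectories moving at constant speed.
    frac_slow
        Fraction of the *non-directed* population in the slow component
        (the mixture weight w1).
    d_slow, d_fast
        Diffusion coefficients of the two Brownian components, µm²/s.
    speed
        Directed speed, µm/s.
    n_frames
        Frames per trajectory (the maximum when ``length_dist`` is
        ``"geometric"``).
    length_dist
        ``"fixed"`` (every track has ``n_frames`` points) or ``"geometric"``
        (lengths geometric with mean ``mean_frames``, truncated to
        ``[2, n_frames]``), so the minimum-duration filter is exercised.
    mean_frames
        Mean of the geometric length distribution (ignored for fixed).
    t_lag
        Frame interval, seconds.
    loc_noise_sd
        Gaussian localization error SD per coordinate, µm.
    seed
        Seed for the generator; identical seeds give identical output.
    """

    n_traj: int = 1000
    frac_directed: float = 0.12
    frac_slow: float = 0.23
    d_slow: float = 0.0024
    d_fast: float = 0.0147
    speed: float = 0.0565
    n_frames: int = 30
    length_dist: Literal["fixed", "geometric"] = "fixed"
    mean_frames: float = 20.0
    t_lag: float = 0.1
    loc_noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_traj < 1:
            raise ConfigError("n_traj must be >= 1")
        for name in ("frac_directed", "frac_slow"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.d_slow < 0 or self.d_fast < 0:
            raise ConfigError("d_slow and d_fast must be >= 0")
        if self.d_slow > self.d_fast:
            raise ConfigError("d_slow must not exceed d_fast")
        if self.speed < 0:
            raise ConfigError("speed must be >= 0")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if self.length_dist not in ("fixed", "geometric"):
            raise ConfigError(f"length_dist must be 'fixed' or 'geometric', got {self.length_dist!r}")
        if self.length_dist == "geometric" and not self.mean_frames > 1:
            raise ConfigError("mean_frames must be > 1 for geometric lengths")
        if not self.t_lag > 0:
            raise ConfigError("t_lag must be > 0")
        if self.loc_noise_sd < 0:
            raise ConfigError("loc_noise_sd must be >= 0")


@dataclass
class MovieSimConfig:
    """Conditions for TIRF-like movie simulation.

    Foci live inside rod-shaped cell footprints. Directed foci travel
    perpendicular to the long axis of their cell (the geometry of
    circumferential cell-wall synthesis seen in a TIRF projection); diffusive
    foci perform Brownian motion reflected at the cell boundary.

    Parameters
    ----------
    frame_shape
        (rows, cols) of each frame, pixels.
    pixel_size
        µm per pixel.
    n_frames
        Number of frames.
    cell_footprints
        Rod polygons in µm (see :func:`stadium_footprint`). All must lie
        inside the frame.
    psf_sigma
        Gaussian PSF standard deviation, µm.
    spot_amplitude
        Integrated intensity of one focus above background, counts.
    background
        Constant offset added to every pixel, counts.
    poisson_gain
        Counts per photon for shot noise; 0 disables Poisson noise.
    gaussian_sd
        Read-noise SD, counts; 0 disables.
    trajectory_config
        Motion parameters of the foci (``n_traj`` counts initial foci across
        all cells; ``n_frames`` is taken from the movie).
    respawn_directed
        If True, a directed focus leaving its cell is replaced by a new one
        (fresh trajectory id) entering from a lateral edge, keeping the
        number of directed foci per cell constant.
    seed
        Seed for the generator.
    """

    frame_shape: tuple[int, int] = (32, 96)
    pixel_size: float = 0.1
    n_frames: int = 100
    cell_footprints: list[Polygon] = field(default_factory=list)
    psf_sigma: float = 0.12
    spot_amplitude: float = 2000.0
    background: float = 100.0
    poisson_gain: float = 1.0
    gaussian_sd: float = 10.0
    trajectory_config: TrajectorySimConfig = field(default_factory=TrajectorySimConfig)
    respawn_directed: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.pixel_size > 0:
            raise ConfigError("pixel_size must be > 0")
        if not self.psf_sigma > 0:
            raise ConfigError("psf_sigma must be > 0")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if not self.cell_footprints:
            raise ConfigError("cell_footprints must contain at least one polygon")
        h_um = (self.frame_shape[0] - 1) * self.pixel_size
        w_um = (self.frame_shape[1] - 1) * self.pixel_size
        frame_box = Polygon([(0, 0), (w_um, 0), (w_um, h_um), (0, h_um)])
        for i, fp in enumerate(self.cell_footprints):
            if not frame_box.contains(fp):
                raise ConfigError(f"cell_footprints[{i}] extends outside the frame")
        if self.poisson_gain < 0 or self.gaussian_sd < 0:
            raise ConfigError("noise parameters must be >= 0")


@dataclass
class ContourSimConfig:
    """Conditions for bent-rod contour simulation.

    The cell is a rod of tip-to-tip ``length`` and diameter ``width`` whose
    centerline is a circular arc of the given (signed) ``curvature``;
    curvature 0 gives a straight stadium. ``width_noise_sd`` perturbs the
    local width along the shaft.
    """

    length: float = 4.0
    width: float = 0.8
    curvature: float = 0.0
    width_noise_sd: float = 0.0
    n_points: int = 100
    seed: int = 0

    def validate(self) -> None:
        if not self.length > self.width > 0:
            raise ConfigError("must have length > width > 0")
        if self.n_points < 20:
            raise ConfigError("n_points must be >= 20")
        if self.width_noise_sd < 0:
            raise ConfigError("width_noise_sd must be >= 0")
        k = abs(self.curvature)
        if k > 0:
            shaft = self.length - self.width
            if k * self.width / 2 >= 1.0:
                raise ConfigError("curvature too high: inner radius collapses (|curvature|*width/2 >= 1)")
            if k * shaft >= math.pi:
                raise ConfigError("curvature too high: rod arc exceeds a half circle and self-intersects")


@dataclass
class SyntheticGroundTruth:
    """Ground truth of one simulated dataset.

    Attributes
    ----------
    per_trajectory
        One row per trajectory: ``traj_id, true_class, true_param,
        n_frames`` where ``true_param`` is the diffusion coefficient
        (µm²/s) for diffusive tracks and the speed (µm/s) for directed
        ones; ``true_class`` is ``"directed"`` or ``"diffusive"``.
    true_positions
        Noise-free positions, same layout as the observed track table.
    detections
        For movies: one row per rendered focus per frame
        (``frame, traj_id, x_um, y_um, cell_id``).
    centerline
        For contours: the analytic centerline polyline, shape (n, 2), µm.
    """

    per_trajectory: pd.DataFrame | None = None
    true_positions: pd.DataFrame | None = None
    detections: pd.DataFrame | None = None
    centerline: np.ndarray | None = None


# ---------------------------------------------------------------------------
# trajectories


def _draw_lengths(cfg: TrajectorySimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.length_dist == "fixed":
        return np.full(cfg.n_traj, cfg.n_frames, dtype=int)
    p = 1.0 / cfg.mean_frames
    lengths = rng.geometric(p, size=cfg.n_traj)
    return np.clip(lengths, 2, cfg.n_frames)


def simulate_trajectories(
    cfg: TrajectorySimConfig,
) -> tuple[pd.DataFrame, SyntheticGroundTruth]:
    """Simulate a cohort of 2-D trajectories.

    Diffusive tracks take independent Gaussian steps of per-axis variance
    2·D·t_lag; directed tracks advance speed·t_lag per frame along a fixed
    random orientation. Independent Gaussian localization noise of SD
    ``loc_noise_sd`` is added to every reported position.

    Returns
    -------
    tracks, ground_truth
        ``tracks`` is a long-format table with columns
        ``traj_id, frame, t_s, x_um, y_um, true_class, true_param``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lengths = _draw_lengths(cfg, rng)
    directed = rng.random(cfg.n_traj) < cfg.frac_directed
    slow = rng.random(cfg.n_traj) < cfg.frac_slow
    orientations = rng.uniform(0.0, 2.0 * math.pi, size=cfg.n_traj)

    frames_list, ids, xs, ys, cls, par = [], [], [], [], [], []
    true_xs, true_ys = [], []
    gt_rows = []
    for i in range(cfg.n_traj):
        n = int(lengths[i])
        t = np.arange(n)
        if directed[i]:
            u = np.array([math.cos(orientations[i]), math.sin(orientations[i])])
            pos = np.outer(t * cfg.t_lag * cfg.speed, u)
            true_class, true_param = "directed", cfg.speed
        else:
            d = cfg.d_slow if slow[i] else cfg.d_fast
            steps = rng.normal(0.0, math.sqrt(2.0 * d * cfg.t_lag), size=(n - 1, 2))
            pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
            true_class, true_param = "diffusive", d
        noisy = pos + rng.normal(0.0, cfg.loc_noise_sd, size=pos.shape)
        ids.append(np.full(n, i))
        frames_list.append(t)
        xs.append(noisy[:, 0])
        ys.append(noisy[:, 1])
        true_xs.append(pos[:, 0])
        true_ys.append(pos[:, 1])
        cls.extend([true_class] * n)
        par.extend([true_param] * n)
        gt_rows.append((i, true_class, true_param, n))

    traj_id = np.concatenate(ids)
    frame = np.concatenate(frames_list)
    tracks = pd.DataFrame(
        {
            "traj_id": traj_id,
            "frame": frame,
            "t_s": frame * cfg.t_lag,
            "x_um": np.concatenate(xs),
            "y_um": np.concatenate(ys),
            "true_class": cls,
            "true_param": par,
        }
    )
    truth = SyntheticGroundTruth(
        per_trajectory=pd.DataFrame(
            gt_rows, columns=["traj_id", "true_class", "true_param", "n_frames"]
        ),
        true_positions=tracks.assign(
            x_um=np.concatenate(true_xs), y_um=np.concatenate(true_ys)
        ),
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# movies


def stadium_footprint(
    center: tuple[float, float],
    length: float,
    width: float,
    angle_deg: float = 0.0,
) -> Polygon:
    """A rod-shaped (stadium) cell footprint, µm.

    ``length`` is tip-to-tip; the straight mid-section has length
    ``length - width`` and the caps are semicircles of radius ``width/2``.
    """
    if not length > width > 0:
        raise ConfigError("stadium requires length > width > 0")
    half = (length - width) / 2.0
    shaft = LineString([(-half, 0.0), (half, 0.0)])
    poly = shaft.buffer(width / 2.0, quad_segs=32)
    poly = shapely.affinity.rotate(poly, angle_deg, origin=(0, 0))
    return shapely.affinity.translate(poly, xoff=center[0], yoff=center[1])


def _principal_angle(poly: Polygon) -> float:
    xy = np.asarray(poly.exterior.coords)[:-1]
    xy = xy - xy.mean(axis=0)
    cov = xy.T @ xy
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, np.argmax(evals)]
    return math.atan2(u[1], u[0])


def _sample_point_inside(poly: Polygon, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    for _ in range(10_000):
        p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
        if poly.contains(Point(p)):
            return p
    raise RuntimeError("failed to sample a point inside the footprint")


def _spawn_directed_at_edge(
    poly: Polygon, axis_angle: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Entry point on a lateral edge and inward perpendicular direction."""
    u = np.array([math.cos(axis_angle), math.sin(axis_angle)])  # long axis
    v = np.array([-u[1], u[0]])  # transverse
    c = np.asarray(poly.centroid.coords[0])
    coords = np.asarray(poly.exterior.coords)[:-1] - c
    s_min, s_max = (coords @ u).min(), (coords @ u).max()
    w_half = (coords @ v).max()
    # stay off the hemispherical caps
    margin = 0.9 * w_half
    s = rng.uniform(s_min + margin, s_max - margin)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    start = c + s * u - sign * v * (w_half * 0.98)
    return start, sign * v


def _trajectory_positions_in_cells(
    cfg: MovieSimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame focus positions and the per-trajectory ground-truth table."""
    tcfg = cfg.trajectory_config
    tcfg.validate()
    angles = [_principal_angle(fp) for fp in cfg.cell_footprints]
    cell_of = rng.integers(0, len(cfg.cell_footprints), size=tcfg.n_traj)
    directed = rng.random(tcfg.n_traj) < tcfg.frac_directed
    slow = rng.random(tcfg.n_traj) < tcfg.frac_slow

    rows = []  # frame, traj_id, x, y, cell_id
    gt = []  # traj_id, true_class, true_param, cell_id, start_frame
    next_id = 0

    def run_directed(tid: int, cell: int, start_frame: int, pos: np.ndarray, vdir: np.ndarray):
        nonlocal next_id
        poly = cfg.cell_footprints[cell]
        f = start_frame
        p = pos.copy()
        while f < cfg.n_frames and poly.contains(Point(p)):
            rows.append((f, tid, p[0], p[1], cell))
            p = p + vdir * tcfg.speed * tcfg.t_lag
            f += 1
        gt.append((tid, "directed", tcfg.speed, cell, start_frame))
        if cfg.respawn_directed and f < cfg.n_frames:
            start, v = _spawn_directed_at_edge(poly, angles[cell], rng)
            tid2 = next_id
            next_id += 1
            run_directed(tid2, cell, f, start, v)

    for i in range(tcfg.n_traj):
        cell = int(cell_of[i])
        poly = cfg.cell_footprints[cell]
        tid = next_id
        next_id += 1
        if directed[i]:
            if cfg.respawn_directed:
                start, v = _spawn_directed_at_edge(poly, angles[cell], rng)
            else:
                start = _sample_point_inside(poly, rng)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                a = angles[cell]
                v = sign * np.array([-math.sin(a), math.cos(a)])
            run_directed(tid, cell, 0, start, v)
        else:
            d = tcfg.d_slow if slow[i] else tcfg.d_fast
            p = _sample_point_inside(poly, rng)
            sd = math.sqrt(2.0 * d * tcfg.t_lag)
            for f in range(cfg.n_frames):
                rows.append((f, tid, p[0], p[1], cell))
                for _ in range(50):  # reflecting boundary by rejection
                    q = p + rng.normal(0.0, sd, size=2)
                    if poly.contains(Point(q)):
                        p = q
                        break
            gt.append((tid, "diffusive", d, cell, 0))

    det = pd.DataFrame(rows, columns=["frame", "traj_id", "x_um", "y_um", "cell_id"])
    per_traj = pd.DataFrame(
        gt, columns=["traj_id", "true_class", "true_param", "cell_id", "start_frame"]
    )
    n_frames = det.groupby("traj_id").size().rename("n_frames")
    per_traj = per_traj.merge(n_frames, on="traj_id", how="left")
    return det.sort_values(["frame", "traj_id"]).reset_index(drop=True), per_traj


def _render_spots(
    frame: np.ndarray, xs_px: np.ndarray, ys_px: np.ndarray, sigma_px: float, amplitude: float
) -> None:
    """Add integrated-Gaussian spots (total flux = amplitude) in place."""
    n_rows, n_cols = frame.shape
    half = max(int(math.ceil(4 * sigma_px)), 2)
    s = sigma_px * math.sqrt(2.0)
    for x, y in zip(xs_px, ys_px):
        c0, c1 = int(math.floor(x)) - half, int(math.floor(x)) + half + 1
        r0, r1 = int(math.floor(y)) - half, int(math.floor(y)) + half + 1
        c0, c1 = max(c0, 0), min(c1, n_cols)
        r0, r1 = max(r0, 0), min(r1, n_rows)
        if c0 >= c1 or r0 >= r1:
            continue
        cols = np.arange(c0, c1)
        rows_ = np.arange(r0, r1)
        gx = 0.5 * (erf((cols + 0.5 - x) / s) - erf((cols - 0.5 - x) / s))
        gy = 0.5 * (erf((rows_ + 0.5 - y) / s) - erf((rows_ - 0.5 - y) / s))
        frame[r0:r1, c0:c1] += amplitude * np.outer(gy, gx)


def simulate_movie(cfg: MovieSimConfig) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Render a TIRF-like movie of moving foci inside cell footprints.

    Each focus is drawn as a pixel-integrated 2-D Gaussian of SD
    ``psf_sigma`` at its true sub-pixel position with total flux
    ``spot_amplitude``; Poisson shot noise (if ``poisson_gain > 0``), the
    constant ``background`` offset and Gaussian read noise are then applied.

    Returns the stack and a ground truth linking every rendered focus to a
    trajectory id.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    det, per_traj = _trajectory_positions_in_cells(cfg, rng)

    stack = np.zeros((cfg.n_frames, *cfg.frame_shape))
    sigma_px = cfg.psf_sigma / cfg.pixel_size
    for f, grp in det.groupby("frame"):
        _render_spots(
            stack[f],
            grp["x_um"].to_numpy() / cfg.pixel_size,
            grp["y_um"].to_numpy() / cfg.pixel_size,
            sigma_px,
            cfg.spot_amplitude,
        )
    if cfg.poisson_gain > 0:
        stack = rng.poisson(stack * cfg.poisson_gain) / cfg.poisson_gain
    stack = stack + cfg.background
    if cfg.gaussian_sd > 0:
        stack = stack + rng.normal(0.0, cfg.gaussian_sd, size=stack.shape)

    truth = SyntheticGroundTruth(per_trajectory=per_traj, detections=det)
    image = ImageStack(
        pixels=stack, pixel_size=cfg.pixel_size, t_lag=cfg.trajectory_config.t_lag
    )
    return image, truth


# ---------------------------------------------------------------------------
# contours


def _arc_centerline(length: float, curvature: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Points and unit tangents of an arc of given arclength and curvature."""
    s = np.linspace(0.0, length, n)
    if abs(curvature) < 1e-12:
        pts = np.column_stack([s - length / 2.0, np.zeros(n)])
        tans = np.tile([1.0, 0.0], (n, 1))
        return pts, tans
    r = 1.0 / curvature
    theta = s * curvature - length * curvature / 2.0
    pts = np.column_stack([r * np.sin(theta), r * (1.0 - np.cos(theta)) - 0.0])
    tans = np.column_stack([np.cos(theta), np.sin(theta)])
    return pts, tans


def simulate_bent_rod_contour(
    cfg: ContourSimConfig,
) -> tuple[Polygon, np.ndarray]:
    """Generate a bent-rod cell outline and its analytic centerline.

    The shaft centerline is a circular arc of arclength ``length - width``
    and signed curvature ``curvature`` (a straight segment for 0); the
    contour is that centerline offset by ``width/2`` on both sides with
    semicircular end caps, so the tip-to-tip extent of a straight rod equals
    ``length``. ``width_noise_sd`` adds Gaussian jitter to the local width
    along the shaft.

    Returns
    -------
    polygon, centerline
        The (simple) cell polygon and the tip-to-tip centerline polyline.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    shaft_len = cfg.length - cfg.width
    n = cfg.n_points
    pts, tans = _arc_centerline(shaft_len, cfg.curvature, n)
    normals = np.column_stack([-tans[:, 1], tans[:, 0]])

    widths = np.full(n, cfg.width)
    if cfg.width_noise_sd > 0:
        widths = widths + rng.normal(0.0, cfg.width_noise_sd, size=n)
        widths = np.clip(widths, 0.2 * cfg.width, None)

    left = pts + normals * (widths[:, None] / 2.0)
    right = pts - normals * (widths[:, None] / 2.0)

    def cap(center: np.ndarray, tangent: np.ndarray, radius: float, outward: float) -> np.ndarray:
        # semicircle from +normal to -normal, bulging along outward*tangent
        phis = np.linspace(math.pi / 2, -math.pi / 2, 33)
        nvec = np.array([-tangent[1], tangent[0]])
        out = [
            center + radius * (math.cos(phi) * outward * tangent + math.sin(phi) * nvec)
            for phi in phis
        ]
        return np.array(out)

    # boundary: left side forward, far cap (left->right), right side backward,
    # near cap (right->left)
    far_cap = cap(pts[-1], tans[-1], widths[-1] / 2.0, +1.0)
    near_cap = cap(pts[0], tans[0], widths[0] / 2.0, -1.0)[::-1]
    boundary = np.vstack([left, far_cap, right[::-1], near_cap])
    poly = Polygon(boundary)
    if not poly.is_valid or not poly.is_simple:
        poly = poly.buffer(0)
        if not isinstance(poly, Polygon) or not poly.is_valid:
            raise ConfigError("generated contour is self-intersecting; reduce curvature or width noise")

    tip0 = pts[0] - tans[0] * (widths[0] / 2.0)
    tip1 = pts[-1] + tans[-1] * (widths[-1] / 2.0)
    centerline = np.vstack([tip0, pts, tip1])
    return poly, centerline
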