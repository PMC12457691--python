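"""Per-trajectory diffusion-coefficient estimation and mixture decomposition.

For a Brownian particle in 2-D, displacement magnitudes r over an interval
Δt follow CDF(r, Δt) = 1 − exp(−r² / (4 D Δt)). Each (non-directed)
trajectory's D is estimated by least-squares fitting this model to the
empirical CDF of its overlapping displacements at a fixed frame lag
(Δt = lag · t_lag, lag 4 by default). The cohort of per-trajectory
coefficients is then decomposed into two populations by maximum-likelihood
fitting of a two-component log-normal mixture (EM on log D), yielding the
component medians D₁ < D₂ and the slow-population weight w₁.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from rodtrack.errors import InsufficientDataError

DC_COLUMNS = ["traj_id", "d_um2_s", "n_displacements", "fit_residual"]


@dataclass
class DCEstimate:
    """CDF-fit diffusion coefficient of one trajectory."""

    traj_id: int
    d_um2_s: float
    n_displacements: int
    fit_residual: float
    degenerate: bool = False  # all displacements zero


@dataclass
class MixtureFit:
    """Two-component log-normal mixture of diffusion coefficients.

    ``d1 < d2`` are the component medians (exponentiated log-space means),
    ``sigma1/sigma2`` the log-space SDs and ``w1`` the weight of the slow
    component. ``loglik_path`` records the log-likelihood after each EM
    iteration of the winning start (non-decreasing by construction).
    """

    d1_um2_s: float
    d2_um2_s: float
    sigma1: float
    sigma2: float
    w1: float
    loglik: float
    converged: bool
    n_points: int
    n_excluded_nonpositive: int = 0
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def separation(self) -> float:
        """Ashman's D: mode separation in pooled-SD units (>2 ≈ bimodal)."""
        return abs(np.log(self.d2_um2_s) - np.log(self.d1_um2_s)) / np.sqrt(
            (self.sigma1**2 + self.sigma2**2) / 2.0
        )

    @property
    def effectively_unimodal(self) -> bool:
        return self.separation < 2.0


def displacements_at_lag(traj: pd.DataFrame, lag_frames: int = 4) -> np.ndarray:
    """Overlapping displacement magnitudes |r(i+lag) − r(i)| in µm.

    Returns an empty array when the track has fewer than ``lag_frames + 1``
    points (such tracks are skipped upstream).
    """
    xy = traj[["x_um", "y_um"]].to_numpy()
    if len(xy) <= lag_frames:
        return np.empty(0)
    d = xy[lag_frames:] - xy[:-lag_frames]
    return np.hypot(d[:, 0], d[:, 1])


def estimate_dc_cdf(r_values: np.ndarray, delta_t: float, traj_id: int = -1) -> DCEstimate:
    """Fit D to the empirical displacement CDF.

    The empirical CDF uses Hazen plotting positions (i − 0.5)/n on the
    sorted magnitudes; D̂ minimizes the sum of squared deviations from
    1 − exp(−r²/(4 D Δt)), searched over log D around the closed-form
    moment/MLE start mean(r²)/(4 Δt). All-zero input returns D̂ = 0 with
    the ``degenerate`` flag set.
    """
    r = np.asarray(r_values, dtype=float)
    if len(r) < 1:
        raise InsufficientDataError("estimate_dc_cdf requires >= 1 displacement")
    if not delta_t > 0:
        raise ValueError("delta_t must be > 0")
    r2_mean = float(np.mean(r**2))
    if r2_mean == 0.0:
        return DCEstimate(traj_id, 0.0, len(r), 0.0, degenerate=True)
    d0 = r2_mean / (4.0 * delta_t)
    rs = np.sort(r)
    ecdf = (np.arange(1, len(rs) + 1) - 0.5) / len(rs)
    rs2 = rs**2

    def sse(log_d: float) -> float:
        model = 1.0 - np.exp(-rs2 / (4.0 * np.exp(log_d) * delta_t))
        return float(np.sum((ecdf - model) ** 2))

    res = minimize_scalar(
        sse, bounds=(np.log(d0) - 4.0, np.log(d0) + 4.0), method="bounded",
        options={"xatol": 1e-6},
    )
    return DCEstimate(traj_id, float(np.exp(res.x)), len(r), float(res.fun))


def estimate_dc_per_track(
    tracks: pd.DataFrame,
    t_lag: float,
    lag_frames: int = 4,
    min_frames: int = 10,
) -> pd.DataFrame:
    """CDF-fit D for every sufficiently long trajectory in a track table.

    Tracks with fewer than ``min_frames`` points are skipped. Returns one
    row per kept trajectory: ``traj_id, d_um2_s, n_displacements,
    fit_residual``.
    """
    delta_t = lag_frames * t_lag
    rows = []
    for tid, grp in tracks.groupby("traj_id"):
        if len(grp) < max(min_frames, lag_frames + 1):
            continue
        r = displacements_at_lag(grp.sort_values("frame"), lag_frames)
        est = estimate_dc_cdf(r, delta_t, traj_id=int(tid))
        rows.append((est.traj_id, est.d_um2_s, est.n_displacements, est.fit_residual))
    return pd.DataFrame(rows, columns=DC_COLUMNS)


def _kmeans_1d(y: np.ndarray, rng: np.random.Generator, n_iter: int = 50) -> np.ndarray:
    """Two-means on a 1-D sample; returns the two centers."""
    c = np.array([np.percentile(y, 25), np.percentile(y, 75)])
    if c[0] == c[1]:
        c = c + np.array([-1e-6, 1e-6])
    for _ in range(n_iter):
        assign = np.abs(y[:, None] - c[None, :]).argmin(axis=1)
        new = np.array(
            [y[assign == k].mean() if np.any(assign == k) else c[k] for k in (0, 1)]
        )
        if np.allclose(new, c):
            break
        c = new
    return c


def _em_once(
    y: np.ndarray,
    w: float,
    m: np.ndarray,
    s: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[float, float, np.ndarray, np.ndarray, np.ndarray, bool]:
    n = len(y)
    path = []
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        log_p1 = np.log(w) - 0.5 * ((y - m[0]) / s[0]) ** 2 - np.log(s[0])
        log_p2 = np.log1p(-w) - 0.5 * ((y - m[1]) / s[1]) ** 2 - np.log(s[1])
        mx = np.maximum(log_p1, log_p2)
        log_tot = mx + np.log(np.exp(log_p1 - mx) + np.exp(log_p2 - mx))
        ll = float(np.sum(log_tot)) - n * 0.5 * np.log(2 * np.pi)
        path.append(ll)
        g = np.exp(log_p1 - log_tot)
        w = float(np.clip(g.mean(), 1e-6, 1 - 1e-6))
        n1 = g.sum()
        n2 = n - n1
        m = np.array([np.sum(g * y) / n1, np.sum((1 - g) * y) / n2])
        s = np.array(
            [
                np.sqrt(np.sum(g * (y - m[0]) ** 2) / n1),
                np.sqrt(np.sum((1 - g) * (y - m[1]) ** 2) / n2),
            ]
        )
        s = np.maximum(s, 1e-4)
        if ll - ll_old < tol:
            converged = True
            break
        ll_old = ll
    return ll, w, m, s, np.asarray(path), converged


def fit_lognormal_mixture(
    dc_values: np.ndarray,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureFit:
    """Maximum-likelihood two-component log-normal mixture of D values.

    Equivalent to a two-component Gaussian mixture on log D, fitted by EM
    from a 2-means initialization plus ``n_restarts`` seeded random starts;
    the best log-likelihood wins. Components are ordered so d1 < d2 and w1
    is the weight of the slow component. Zero or negative values (outside
    log-normal support) are excluded and counted.

    Raises :class:`InsufficientDataError` with fewer than 20 positive
    values. Non-convergence after all restarts is flagged, the best
    candidate is still returned.
    """
    dc = np.asarray(dc_values, dtype=float)
    n_excl = int(np.sum(~(dc > 0)))
    y = np.log(dc[dc > 0])
    if len(y) < 20:
        raise InsufficientDataError(
            f"mixture fit requires >= 20 positive D values, got {len(y)}"
        )
    rng = np.random.default_rng(seed)
    sd = float(y.std()) or 1e-3

    starts = []
    c = _kmeans_1d(y, rng)
    starts.append((0.5, np.sort(c), np.array([sd / 2, sd / 2])))
    for _ in range(n_restarts):
        m = np.sort(rng.choice(y, size=2, replace=False))
        starts.append(
            (
                float(rng.uniform(0.2, 0.8)),
                m,
                sd * rng.uniform(0.3, 1.0, size=2),
            )
        )

    best = None
    for w0, m0, s0 in starts:
        ll, w, m, s, path, conv = _em_once(y, w0, m0.copy(), s0.copy(), tol, max_iter)
        if best is None or ll > best[0]:
            best = (ll, w, m, s, path, conv)
    ll, w, m, s, path, conv = best
    if m[0] > m[1]:
        w, m, s = 1.0 - w, m[::-1], s[::-1]
    return MixtureFit(
        d1_um2_s=float(np.exp(m[0])),
        d2_um2_s=float(np.exp(m[1])),
        sigma1=float(s[0]),
        sigma2=float(s[1]),
        w1=w,
        loglik=ll,
        converged=bool(conv),
        n_points=len(y),
        n_excluded_nonpositive=n_excl,
        loglik_path=path,
    )


def aggregate_replicates(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Per-strain medians of mixture parameters across biological replicates.

    ``per_replicate`` needs columns ``strain, replicate_id, w1, d1_um2_s,
    d2_um2_s`` (one row per replicate). Returns one row per strain with the
    medians and replicate count.
    """
    req = {"strain", "replicate_id", "w1", "d1_um2_s", "d2_um2_s"}
    missing = req - set(per_replicate.columns)
    if missing:
        raise ValueError(f"per_replicate is missing columns: {sorted(missing)}")
    out = (
        per_replicate.groupby("strain")
        .agg(
            w1=("w1", "median"),
            d1_um2_s=("d1_um2_s", "median"),
            d2_um2_s=("d2_um2_s", "median"),
            n_replicates=("replicate_id", "nunique"),
        )
        .reset_index()
    )
    return out


def fold_change(summary: pd.DataFrame, strain_num: str, strain_den: str, column: str = "w1") -> float:
    """Ratio of a per-strain median between two strains (e.g. w1 mutant/WT)."""
    s = summary.set_index("strain")[column]
    return float(s.loc[strain_num] / s.loc[strain_den])
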