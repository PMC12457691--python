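"""Per-trajectory diffusion coefficients and the two-population decomposition.

Each Brownian track's D is estimated by fitting the displacement CDF model
CDF(r, dt) = 1 - exp(-r^2 / (4 D dt)) at a 4-frame lag; the cohort of D
values is then decomposed into slow and fast populations by a two-component
log-normal mixture (EM on log D).
"""

import rodtrack as rt
from rodtrack.diffusion import estimate_dc_per_track, fit_lognormal_mixture

cfg = rt.TrajectorySimConfig(
    n_traj=4000, frac_directed=0.0, frac_slow=0.23,
    d_slow=0.0024, d_fast=0.0147, n_frames=30, t_lag=0.1,
    loc_noise_sd=0.0, seed=2,
)
tracks, _ = rt.simulate_trajectories(cfg)
dc = estimate_dc_per_track(tracks, t_lag=cfg.t_lag, lag_frames=4)
fit = fit_lognormal_mixture(dc["d_um2_s"].to_numpy(), n_restarts=5, seed=2)

print(f"{len(dc)} per-trajectory D estimates from {cfg.n_traj} tracks")
print(f"slow fraction w1 : {fit.w1:.3f}   (truth 0.230)")
print(f"slow D1          : {fit.d1_um2_s:.5f} µm²/s (truth 0.00240)")
print(f"fast D2          : {fit.d2_um2_s:.5f} µm²/s (truth 0.01470)")
print(f"bimodal?         : {not fit.effectively_unimodal} (separation {fit.separation:.1f} pooled SDs)")
print("-> w1 is the weight of the slow population; D1/D2 are the component")
print("   medians of the fitted log-normal mixture.")
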