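"""Simulate a trajectory cohort and classify directed vs diffusive motion.

A wild-type-like cohort mixes a directed subpopulation (constant speed
56.5 nm/s, the circumferential cell-wall-synthesis motion seen in TIRF)
with slow and fast Brownian populations. The MSD classifier should recover
the directed fraction and speed.
"""

import rodtrack as rt
from rodtrack.motion import classify_tracks, summarize_directed

cfg = rt.TrajectorySimConfig(
    n_traj=1000, frac_directed=0.12, frac_slow=0.23,
    d_slow=0.0024, d_fast=0.0147, speed=0.0565,
    n_frames=30, t_lag=1.0, loc_noise_sd=0.02, seed=1,
)
tracks, truth = rt.simulate_trajectories(cfg)
cls = classify_tracks(tracks, t_lag=cfg.t_lag)
summary = summarize_directed(cls)

print(f"simulated {cfg.n_traj} tracks, true directed fraction {cfg.frac_directed}")
print(f"recovered directed fraction : {summary['directional_fraction']:.3f}")
print(f"recovered mean speed        : {summary['mean_speed_um_s'] * 1000:.1f} nm/s")
print(f"recovered median speed      : {summary['median_speed_um_s'] * 1000:.1f} nm/s "
      f"(truth {cfg.speed * 1000:.1f} nm/s)")
print("-> the directed fraction should sit near 0.12 and the median speed near")
print("   56.5 nm/s; the mean runs high because a few fast Brownian tracks")
print("   slip past the ballistic R² gate with inflated apparent speeds.")
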