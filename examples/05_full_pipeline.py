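"""Two-strain, multi-replicate run of the full SPT pipeline.

Four replicates per strain are simulated: a wild-type-like strain (slow
fraction 0.23) and a mutant-like strain in which the slow fraction is
1.56-fold higher (the signature of diffusive enzymes taking over cell-wall
synthesis when the dominant synthase is deleted). The pipeline reports
per-replicate mixture fits, per-strain medians and the fold-change.
"""

import rodtrack as rt
from rodtrack.diffusion import fold_change
from rodtrack.pipeline import CohortSpec, SPTRunConfig


def cohorts(strain, w1, n_reps=4):
    out = []
    for r in range(n_reps):
        sim = rt.TrajectorySimConfig(
            n_traj=1000, frac_directed=0.12, frac_slow=w1, d_slow=0.0024,
            d_fast=0.0147, speed=0.0565, n_frames=30, t_lag=0.1, loc_noise_sd=0.0,
        )
        out.append(CohortSpec(strain=strain, replicate_id=f"r{r + 1}", simulation=sim))
    return out


cfg = SPTRunConfig(cohorts=cohorts("WT", 0.23) + cohorts("dponA", 0.359), seed=4)
report = rt.run_spt_pipeline(cfg)

print(report.per_strain.to_string(index=False))
fc = fold_change(report.per_strain, "dponA", "WT")
print(f"\nslow-fraction fold-change dponA/WT : {fc:.2f} (truth 1.56)")
print("-> per-strain rows are medians of four replicate mixture fits;")
print("   directed tracks were excluded before the diffusion analysis.")
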