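# rodtrack

Single-particle-tracking quantification and rod-cell morphometrics for TIRF
movies of bacterial cell-wall synthesis proteins (SEDS glycosyltransferases
such as RodA and their partners).

Membrane-bound cell-wall enzymes show two kinds of motion in TIRF
time-lapse data: a small subpopulation moves *directionally* at constant
speed, perpendicular to the cell long axis (enzymes engaged in the Rod
complex, tracking circumferential glycan synthesis), while the majority
*diffuses* in the membrane, often as a mixture of a slow and a fast
population whose balance shifts when other synthases are deleted. `rodtrack`
implements the full quantification chain for this biology:

1. **Preprocessing** — per-pixel minimum-projection subtraction over the
   stack, then sliding-window averaging of two consecutive frames.
2. **Detection & linking** — Laplacian-of-Gaussian spot detection
   (radius 0.25 µm, sub-pixel refinement) and frame-to-frame LAP linking
   (max displacement 0.4 µm, no gap closing).
3. **Motion classification** — per-trajectory MSD curves fitted to a
   ballistic model MSD = (v·t)² and a Brownian model MSD = 4·D·t over the
   first min(n/4, 10) lags; a track is *directed* if the ballistic fit has
   R² ≥ 0.9, else *diffusive* if the linear fit has R² ≥ 0.8 (minimum
   duration 10 frames). Directed tracks yield the speed distribution and
   the surface density of directional foci (count inside the cell mask per
   µm² per frame).
4. **Diffusion analysis** — directed tracks are excluded; each remaining
   trajectory's diffusion coefficient is estimated by least-squares fitting
   the cumulative distribution of its displacement magnitudes at a 4-frame
   lag to

   CDF(r, Δt) = 1 − exp(−r² / (4·D·Δt)),  Δt = 4·t_lag.

5. **Mixture decomposition** — the per-trajectory D values of a replicate
   are decomposed by maximum likelihood into a two-component log-normal
   mixture (EM on log D), giving the component medians D₁ < D₂ and the
   slow-population weight w₁; strains are compared by medians across
   biological replicates.
6. **Morphometrics** — from cell contours (label masks or polygons):
   solidity (area / convex-hull area), lateral and longitudinal asymmetry
   (overlap ratio of the two cell halves split by the medial axis or by the
   perpendicular at the cell middle; 1 = perfect symmetry), width variation
   (SD of the perpendicular width profile), mean width and length.

Because no imaging data are deposited for this system, the package ships a
first-class synthetic-data module (`rodtrack.synthetic`) that generates
trajectories, TIRF-like movies and bent-rod contours with known ground
truth, so every stage is validated by parameter recovery.

## Worked example

```bash
python examples/02_diffusion_mixture.py
```

```
4000 per-trajectory D estimates from 4000 tracks
slow fraction w1 : 0.237   (truth 0.230)
slow D1          : 0.00241 µm²/s (truth 0.00240)
fast D2          : 0.01461 µm²/s (truth 0.01470)
bimodal?         : True (separation 5.1 pooled SDs)
```

The script simulates 4000 Brownian trajectories (30 frames at 10 Hz) as a
23%/77% mixture of slow (0.0024 µm²/s) and fast (0.0147 µm²/s)
populations, estimates each track's D from its displacement CDF, and fits
the log-normal mixture: the recovered weight and coefficients match the
simulation ground truth to a few percent. The other examples cover
directed-motion classification (`01`), movie-level detection, tracking,
density and kymographs (`03`), shape descriptors on a curvature sweep
(`04`) and the two-strain replicate pipeline with its 1.56-fold
slow-fraction change (`05`).

A thin CLI mirrors the library for shell use:

```bash
rodtrack track movie.tif --pixel-size 0.065 --t-lag 0.1 --out tracks.csv
rodtrack classify tracks.csv --t-lag 0.1 --out classes.csv
rodtrack diffusion tracks.csv --t-lag 0.1 --out dc.csv
```

TrackMate CSV exports are accepted as a track-table entry point, so real
detections can bypass the built-in detector.

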