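# Methods

This note documents the models, defaults and numerical choices behind
`rodtrack`, and what the synthetic-data validation does and does not show
about real data.

## Motion model and classification

Trajectories are ordered 2-D positions in µm at a fixed frame interval
`t_lag`. Two motion modes are modelled:

* **Brownian**: per-axis steps are i.i.d. Gaussian with variance
  2·D·t_lag, so the 2-D MSD is 4·D·t and the displacement magnitude over
  an interval Δt follows the Rayleigh law whose CDF is
  1 − exp(−r²/(4DΔt)).
* **Directed**: constant speed v along a fixed orientation, MSD = (v·t)².
  In real cells this motion is circumferential around the cylinder; at
  ~56 nm/s a 10–30-frame track traverses only a small arc of a ~1 µm-wide
  cell, so the TIRF-plane projection is modelled as straight-line motion.
  No cylinder projection is applied.

Classification fits both models to the time-averaged MSD (overlapping-pair
estimator) over a fit window of the first min(n/4, 10) lags, the standard
compromise against the high variance of overlapping MSD estimates at long
lags. The ballistic model is fitted linearly on √MSD vs t (linear in v, no
intercept); the Brownian model as zero-intercept least squares of MSD on
4t. R² = 1 − SS_res/SS_tot is evaluated on the fit window. A trajectory is
**directed** when the ballistic R² ≥ 0.9; the ballistic test runs first
because a ballistic track also fits a line well, so the precedence must
favour the stricter model. Otherwise it is **diffusive** when the linear
R² ≥ 0.8, else **unclassified**. Tracks under 10 frames are not classified.
An all-zero MSD is treated as a perfect fit of the zero-diffusion model. An
optional nonzero-intercept Brownian fit (localization-noise term) is not
default because the zero-intercept form matches the CDF model downstream.

Two consequences of these gates are worth knowing. First, a few percent of
genuinely Brownian tracks pass the ballistic gate with inflated apparent
speeds; the directed-speed *mean* over a mixed cohort is therefore biased
upward while the *median* is robust (both are reported). On pure directed
cohorts the mean recovers the true speed within a few percent. Second, the
directional fraction is computed per *trajectory* over all classifiable
tracks (directed + diffusive + unclassified).

## Density of directional foci

Per frame, directed-classified foci whose position lies inside the cell
mask are counted and divided by the mask area (µm⁻²); the mean and SD over
frames are reported. The denominator is the per-cell mask area (not the
imaged field), which is the natural normalization when masks are available
per cell.

## Per-trajectory diffusion coefficient (CDF fit)

Displacement magnitudes are taken at a lag of 4 frames (Δt = 4·t_lag),
overlapping, which maximizes the data per track at the cost of serial
correlation. The empirical CDF uses Hazen plotting positions (i − ½)/n,
which behave well in the tails of the small per-trajectory samples
(typically 6–26 displacements). D̂ minimizes the sum of squared deviations
between the empirical CDF and the model, searched over log D (bounded
scalar minimization seeded at the moment estimator mean(r²)/(4Δt),
tolerance 10⁻⁶ on log D). All-zero displacement sets return D̂ = 0 with a
degeneracy flag. The ECDF fit and the closed-form exponential MLE are
distinct estimators: they converge with sample size (within 5% at 10³
model displacements) but individual 10-displacement samples can disagree by
>25%; only median agreement is asserted at that size.

Directed-classified trajectories are excluded before diffusion analysis —
ballistic displacement statistics would otherwise contaminate the D
distribution (the with/without comparison is part of the test suite).

## Log-normal mixture

The per-replicate D values (positive only; zeros and negatives are
excluded with their count recorded, since log-normal support is positive)
are modelled as a two-component log-normal mixture, i.e. a two-component
Gaussian mixture on log D, fitted by EM with a 2-means initialization plus
5 seeded random restarts, likelihood tolerance 10⁻⁸, σ floored at 10⁻⁴ in
log-space to avoid component collapse. Components are ordered so D₁ < D₂
and w₁ is the slow-component weight ("fraction of slow particles");
reported D values are the exponentiated log-means (component medians).
At least 20 positive values are required. Bimodality is summarized by
Ashman's D (mode separation in pooled-SD units; < 2 is flagged effectively
unimodal). Strain-level values are medians across replicates, and
fold-changes are ratios of those medians.

Note the mixture's log-space spread in recovery runs is mostly *estimation*
noise: each population is simulated at a single true D, and the ~0.35
log-SD of the fitted components reflects the sampling variance of
per-trajectory D̂ at ~26 overlapping displacements. The decomposition would
behave the same for genuinely dispersed populations of similar spread.

## Detection and linking

Frames are filtered with a scale-normalized LoG at σ = radius/√2 (radius
0.25 µm); sign-flipped response maxima above the threshold and at least one
radius apart are kept, with sub-pixel refinement by a 1-D quadratic fit per
axis on the 3×3 response neighbourhood (localization error well under half
a pixel at high SNR). The threshold is in response units that scale with
image intensity, so it has no absolute meaning across instruments; synthetic
runs set it relative to the simulated spot amplitude (≈ 4% of the response
of an ideal spot in the bundled configurations).

Linking solves, per consecutive frame pair, an optimal assignment on the
augmented cost matrix [[C, D], [B, 0]] (C = squared distances with pairs
beyond the 0.4 µm cap blocked; death/birth diagonals at cap²), which
prefers any admissible link over leaving both endpoints unmatched and
minimizes total squared displacement among such matchings — the LAP
semantics of standard trackers. No gap closing, splitting or merging (the
max frame gap is 0); a track ends as soon as no admissible continuation
exists. Tracks shorter than 10 frames are dropped before analysis.

## Preprocessing and kymographs

Preprocessing subtracts the per-pixel minimum projection computed over the
*full* stack, then averages two consecutive frames with stride 1 (output
frame k = mean of frames k, k+1), so an n-frame stack yields n − 1 frames
and no negative values. Stride 1 is an interpretation — a tiling (stride-2)
window would halve the frame count — chosen because it preserves the frame
rate for downstream tracking. Kymographs sample bilinear intensity profiles
along a user line once per pixel length, optionally averaged over a few
perpendicular offsets; a focus crossing the line at speed v appears as a
trace of slope v in (time, position).

Coordinates follow x = column, y = row with the origin at the centre of the
top-left pixel; µm = pixel index × pixel size. The pixel size has no
default and must come from acquisition metadata.

## Shape descriptors

The medial axis is extracted in two passes: chord midpoints perpendicular
to the principal (PCA) axis are sampled every `step_um` (default 0.05 µm)
and smoothed; widths and midpoints are then re-measured perpendicular to
the local centerline tangent, and the centerline is extended along its end
tangents to the poles. Cells with elongation (length/width) < 1.5 are
rejected — the chord construction is meaningless for round cells.

* **Solidity** = polygon area / convex-hull area.
* **Lateral asymmetry**: the cell is split along the curved medial
  polyline, one half is folded across the straight pole-to-pole chord, and
  the overlap ratio is intersection-over-union with the other half. IoU is
  used because it is symmetric in the halves and equals 1 exactly at
  perfect symmetry. Folding across the *curved* axis itself was rejected:
  it maps the inner band of an arc almost onto the outer band, so it barely
  responds to curvature, whereas the chord fold decreases steeply and
  monotonically with curvature and is exact for straight rods.
* **Longitudinal asymmetry**: split by the perpendicular to the centerline
  at its arclength midpoint, mirror one half across that line, IoU. An
  ideal circular-arc rod is mirror-symmetric about this perpendicular, so
  this descriptor stays ≈ 1 on the synthetic curvature sweep; it responds
  to pole-to-pole imbalance (e.g. tapered or branched cells), not to smooth
  bending.
* **Width statistics**: widths are resampled at a given spacing (default
  one pixel) along the centerline; samples within mean-width/2 of either
  pole are excluded because chords through the hemispherical caps
  understate the cylinder diameter. Width variation is the SD of the
  remaining samples; length is the centerline arclength.

These absolute values depend on the declared IoU convention; cross-strain
*differences* are the comparable quantity.

## Synthetic data: what it emulates, and what not

The trajectory generator reproduces the statistical structure the pipeline
assumes — a directed subpopulation at constant speed, two Brownian
populations, i.i.d. Gaussian localization noise per coordinate (default SD
20 nm, a typical HaloTag-SPT figure; the acquisition literature for this
system does not state one). Track lengths are fixed at `n_frames` by
default because the validation cohorts are defined at fixed length; a
truncated-geometric mode exercises the minimum-duration filter. Not
modelled: motion blur within the exposure (secondary under continuous
acquisition), blinking/bleaching photophysics, 3-D motion and the cylinder
projection, and state switching within a track. Passing recovery tests
therefore shows the estimators are correct for the assumed model, not that
the model captures every property of real movies.

The movie generator renders pixel-integrated Gaussian spots (total flux =
amplitude) inside rod-shaped cell footprints with Poisson shot noise, a
constant offset and Gaussian read noise. Directed foci travel perpendicular
to the cell long axis and can be configured to respawn on exit so the
per-cell directional-focus count stays constant — the geometry used for
density validation. Diffusive foci reflect at the cell boundary.

The contour generator sweeps a circular-arc centerline (shaft arclength =
length − width, so tip-to-tip extent equals `length`) with semicircular
caps and optional Gaussian width jitter; configurations whose arc exceeds a
half circle or whose inner radius collapses are rejected as degenerate.

## Validation problem sizes

Recovery runs use 200 directed tracks (speed), 4000-track cohorts (mixture
and fold-change, matching the reported per-strain scale), and a 200-frame
single-cell movie (density). At these sizes the recovered values sit well
inside the acceptance tolerances (speed ~1%, D₁/D₂ ~2%, w₁ ~½ point,
density ~4% in seed sweeps) and the whole suite runs in seconds on one CPU.
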