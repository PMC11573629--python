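# Methods

## Scope and model

`colonykymo` quantifies the two-phase spatiotemporal cell-death program of
bacterial colonies from two-channel time-lapse fluorescence imaging. The
unit of analysis is the colony field, not single cells. The live channel is
a constitutive cytoplasmic fluorophore; the dead channel is a
membrane-impermeant DNA stain, so the dead/live intensity ratio at a
position is a proxy for the local fraction of dead cells. All spatial
quantities are carried in mm via the pixel calibration and all times in
hours; intensity is arbitrary 16-bit-scale units, and calibration is
metadata, never baked into pixel values.

## Synthetic colony generator

Because the analysis must be testable without microscope data, the
generator renders colonies with the structure the analysis assumes and
returns exact ground truth. It is a phenomenological schedule, not a
mechanistic model of interbacterial killing or quorum-sensing circuitry.

* **Geometry and growth.** A disk centered in the field, radius growing
  linearly from the spot radius (0.75 mm, a plausible footprint of a 1 µL
  spot) to 3 mm at 48 h and constant thereafter; a logistic law is
  available. The edge is antialiased over one pixel.
* **Death schedules.** Phase 1: inside the outermost 0.25 mm of the
  instantaneous rim, between 8 h and 40 h, the dead channel carries
  `p1_intensity_ratio / p1_attenuation` times the local live signal
  (default ratio 10; attenuation 1 for wild-type-like, 10 for
  rim-attenuated mutant-like strains). The stain marks cells at the rim at
  the time of death; the band tracks the boundary rather than filling the
  colony behind it. Phase 2: a ring nucleates at 1 mm (one third of the
  final radius — the nucleation radius is not constrained by data and is
  configurable) at 44 h with initial width 0.12 mm; both fronts move at
  0.1 mm/h for 6 h. Its intensity ratio (3) is below the rim band's,
  reflecting that the early rim episode is the higher-amplitude one.
* **Imaging artifacts.** Additive camera background (100 a.u.) with a
  linear gradient (0.1 a.u./px along columns); shot noise
  (variance = scale × mean, default scale 1, i.e. Poisson); cumulative
  rigid stage drift as a random walk with per-frame increments up to 2 px
  and 0.5°. Drift is rendered exactly by evaluating the colony fields at
  drifted coordinates — a real stage does not resample the scene — so the
  generator introduces no interpolation blur. The drift rotation pivots on
  the image center where the isotropic colony sits, so it does not change
  the scene; it is recorded in the ground truth and exercised on textured
  scenes in the registration tests instead.
* **Cadence and window.** Frames every 1 h from 0 to 54 h. The acquisition
  cadence of the original assay is not published (only a ~2.5 h display
  interval); 1 h is a stand-in chosen so that ±1-frame tolerances are
  meaningful.
* **Determinism.** All randomness comes from one seeded generator:
  identical config + seed gives bit-identical stacks.

What the generator does **not** emulate: colony morphology beyond a disk
(no sectors, no rim roughness), stain diffusion and persistence kinetics,
photobleaching, uneven focus, or autofluorescence. Passing the recovery
tests therefore shows the pipeline is correct under the stated imaging
model, not that it is robust to every real-world pathology.

## Preprocessing

* **Rolling ball.** The background is the envelope traced by a ball of
  radius *r* (default 1000 px, the scale used for stitched colony
  montages) rolled under the intensity surface — grey erosion followed by
  grey dilation with the ball's height profile as a non-flat structuring
  element. The exact computation is quadratic in *r*, so radii above 20 px
  use the standard shrink-estimate-upsample approximation. Shrinking uses
  the **block minimum**: a block mean lets bright compact structures (the
  rim death ring) leak into the background estimate, which then jumps when
  the ring ends — an artifact we observed and removed. The residual is
  clipped at zero, so residual ≥ 0 and ≤ frame everywhere.
* **Registration.** Rigid body (translation + rotation about the image
  center), estimated on the live channel and applied to both. Translation
  comes from phase correlation (plain cross-correlation normalization:
  spectral-phase whitening is unreliable on smooth fluorescence images);
  rotation from a 1-D search over candidate angles with parabolic
  refinement, scoring each candidate by the interior residual RMS after
  shift alignment (the border is cropped so edge fill cannot dominate).
  Estimates are refined iteratively (apply, re-estimate the residual,
  compose) because subpixel correlation estimates on interpolated images
  are shrunk toward zero. Estimation runs on gradient-magnitude (edge)
  maps of the frames, σ = 3 px: the raw-intensity correlation of a growing
  flat disk has a plateau of near-equal optima as wide as the per-frame
  growth, and any residual illumination tilt tips that plateau sideways —
  on drifting synthetic colonies this produced a runaway registration
  error of the order of the accumulated growth; edge maps of concentric
  boundaries have a unique optimum and no tilt. The default sequential
  policy registers each frame to the already-aligned previous frame
  (robust to slow content change, i.e. growth); its error random-walks at
  ~0.25 px per step. The fixed-reference policy registers every frame to
  frame 0 and recovers static-scene drift to ~0.2 px and ~0.02°, but is
  ill-posed under growth (a small disk anywhere inside a larger one
  correlates equally well). Out-of-frame pixels after correction are
  filled with the frame median and flagged in a validity mask.
* **Z-projection and stitching.** Maximum-intensity projection over
  slices; tile stitching by linear blend — per-tile separable weights that
  fall linearly to the tile edge, normalized to sum to one, so single-tile
  regions are copied verbatim and two-tile overlaps cross-fade linearly.

## Geometry

The colony is segmented per frame from the background-subtracted live
channel: Triangle threshold (256 bins over the observed range, the 8-bit
convention; the threshold bin maximizes the perpendicular distance to the
peak-to-farthest-tail chord in peak-normalized coordinates; ties break to
the lower bin), largest connected component, holes filled. Per frame the
centroid (mean of foreground coordinates) and the Feret (maximum caliper)
diameter and angle are computed by a pair scan over convex-hull vertices.

The kymograph samples one **fixed ray**: origin at the centroid of the
first analyzed frame, direction along its Feret angle (overridable, and
steerable away from configured excluded angular wedges — the reproducible
surrogate for manually avoiding sector outgrowths). Freezing the ray is
what makes registration matter: a drifting, unregistered colony slides off
the ray. The per-frame boundary radius is the ray's first exit from the
mask, refined to sub-pixel precision as the position where the live
intensity falls to the mid-edge level (halfway between the interior
plateau and the outside level, interpolated along the ray). The mask
endpoint itself sits where intensity crosses the segmentation threshold,
which is biased toward the outer foot of the edge; the mid-edge refinement
brings the radius error from ~1–2 px down to ~0.2 px, which matters at
coarse pixel scales and early times when the colony is only ~20 px across.

Coordinates are (row, col), 0-based pixel centers; angles in degrees
counterclockwise from the +col axis, reported in [0°, 180°) with ties to
the smaller angle.

## Kymograph and phase detection

Profiles are sampled along the ray by bilinear interpolation onto a fixed
radial grid (10 µm spacing, 0 = colony center); radii beyond the
instantaneous boundary are missing (NaN). The kymograph is
`log_base((dead + pc) / (live + pc))` with pseudocount pc = 1 a.u.
(the smallest intensity unit, negligible against ~10³-scale signal) and
log base 10, recorded in the output metadata.

The original phases were read from kymographs visually; no numeric rule
exists to inherit, so the detectors below are this package's explicit
convention.

* **Activity rule.** A band is active at time *t* when its log-ratio
  exceeds its pre-death baseline mean + max(k·SD, 0.2), k = 3. The
  absolute floor (0.2 log₁₀ units ≈ 1.6-fold) exists because the
  statistical rule alone becomes arbitrarily sensitive as the baseline
  noise vanishes, while the phases in this system are order-of-magnitude
  effects (≥ 2.5 log units above baseline); the floor discards sub-fold
  deterministic trends at no cost in sensitivity.
* **Phase 1 (rim).** The outermost 0.25 mm, tracking the moving boundary
  (the paper does not quantify the band; the width is configurable). The
  baseline is the first 6 frames (pre-death under the default schedule;
  configurable for other cadences). The episode is the longest contiguous
  active run and must span ≥ 2 frames — isolated single-frame excursions
  are noise. Onset/end are the run's first/last times; the magnitude is
  the mean band log-ratio over the run.
* **Phase 2 (interior ring).** Radial bins more than 0.4 mm inside the
  boundary (so the rim episode cannot masquerade as interior). Each bin's
  baseline is its own first 6 frames of interior visibility — a bin's
  early, pre-death history; per-bin SDs estimated from few frames are
  floored by the median SD across bins. The nucleating ring must be a
  contiguous active band ≥ 0.05 mm wide that reappears (overlapping, full
  width) in the following frame: adjacent radial bins share pixels, so
  noise excursions are radially correlated but not reproducible in time.
  The origin radius is the center of that first ring; afterwards the
  contiguous region overlapping the tracked ring is followed and the
  propagation duration is the time from onset until neither front has
  advanced by more than 0.03 mm. Absence of the ring is a reported
  outcome, not an error.
* **Strain comparison.** The rim-band fold difference is
  `base^(mean_A − mean_B)` over each colony's own rim band and a shared
  time window (the phase-1 window detected on the reference strain by
  default). Fold reciprocity holds by construction.

## Assays

RLU = luminescence / OD600. Fold change is the ratio of group means
(median ratio available). Significance uses the classical equal-variance
two-sample Student *t* test with two-tailed p (Welch available), annotated
`**` for P < 0.005 and `***` for P < 0.0005. Error summaries are plain-scale
SDs of RLU. The reporter-table simulator draws multiplicative mean-one
lognormal noise at a given CV, so the expected fold equals the configured
truth exactly.

## Problem sizes and numerical choices

Recovery checks run the full pipeline at the study's default conditions —
512² px at 15 µm/px, 1 h frames over 0–54 h, noise and drift on — in about
1–2 minutes per colony on one CPU; unit tests use geometrically identical
colonies at 160–256 px to keep the suite fast. Degenerate inputs are
rejected with named errors (empty masks, single-bin histograms, negative
intensities, non-positive OD600); blank registration frames get identity
transforms and a warning rather than an abort. Ties are deterministic
everywhere (lower histogram bin, smaller Feret angle, earliest active
run).

## Known limitations

* The phase detectors assume a pre-death baseline exists inside the
  observation window; an assay that starts after death onset needs the
  baseline parameters adjusted.
* Sequential registration error grows as a random walk along very long
  series; for static scenes the fixed-reference policy is preferable.
* The fold comparison assumes both strains share growth conditions and
  observation windows; it resamples nothing beyond the time intersection.
* Kymographs quantify a single ray per colony, as in the underlying assay;
  azimuthal averaging would reduce noise but is deliberately out of scope
  to preserve comparability.
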