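# Methods

## Problem and model

Longitudinal B-mode ultrasound of skeletal muscle shows fascicles and
aponeuroses as bright, roughly straight bands on a darker, speckled
background. The quantity of interest is the muscle fiber orientation
(MFO): the angle of each band, measured from the downward image vertical
(the NIH-Image convention), folded into [0, 180). sonofiber estimates
MFO per frame in three stages:

1. **Enhancement.** A multiscale Hessian vesselness filter. At Gaussian
   scale σ the Hessian is estimated by separable convolution with sampled
   Gaussian-derivative kernels and γ-normalized by σ². With eigenvalues
   ordered |λ₁| ≤ |λ₂|, the bright-band score is

       V = exp(−R_B²/(2β²)) · (1 − exp(−S²/(2c²))),   λ₂ < 0
       V = 0,                                          λ₂ ≥ 0

   where R_B = λ₁/λ₂ penalizes blob-like structure and S = √(λ₁²+λ₂²)
   (the Hessian Frobenius norm) suppresses low-contrast noise. The
   multiscale response is the per-pixel maximum over all scales.

2. **Binarization.** Otsu's threshold (256 uniform bins over the
   enhanced image's range, smallest-level tie-break); pixels strictly
   above threshold form the candidate map.

3. **Iterative line extraction.** Candidate regions fall into three
   patterns: long thin single fibers, branched regions where adjacent
   fibers adhere, and short fragments of a partially imaged fiber. The
   detector repeatedly takes the region with the largest
   equivalent-ellipse major-axis length L; if its aspect ratio exceeds
   T1 and its width ω is below T2 the orientation is the ellipse
   major-axis angle (cheap second-moment computation), otherwise one
   line is extracted by a Hough transform restricted to that region's
   own pixels (global accumulator maximum; ties to smallest θ, then
   smallest ρ). Pixels within (removal_width − 1)/2 of the detected
   infinite line are then cleared map-wide, which removes noise near the
   line and consumes collinear fragments of the same broken fiber, so a
   fragment's angle is not reported twice. The loop stops after N lines
   or when the current region's length falls below T3 · L¹.

   The efficiency argument rests on the routing: on non-branched
   content every line takes the ellipse path, and the expensive Hough
   voting runs only on deliberately branched components.

## Parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| MVEF scales σ | 1, 2, 3, 4, 5 | px | band half-widths covered by the filter |
| β | 0.5 | — | blobness sensitivity |
| c | auto | intensity | structureness sensitivity; auto = half the max Hessian Frobenius norm at each scale |
| T1 | 5 | — | aspect-ratio gate for the ellipse path (strict >) |
| T2 | 30 | px | width gate for the ellipse path (strict <) |
| T3 | 0.10 | — | last-to-first length-ratio stop |
| N | 7 | lines | per-frame cap; preset `N_REDUCED_ARCHITECTURE = 4` for imaging with fewer visible patterns |
| removal_width | 17 | px | strip cleared around each detected line (±8 px) |
| θ step / ρ step | 1° / 1 px | | Hough accumulator resolution |
| connectivity | 8 | | component connectivity (diagonal thin traces stay connected) |

The MVEF scale set, β and the auto-c rule are this package's choices:
fascicle bands in clinical sonograms span a few pixels to roughly ten,
and min-max normalizing the input before filtering makes the auto-c rule
independent of the source intensity units. All are overridable through
`DetectorConfig` / `VesselnessParams`.

## Angle conventions

All angles are measured from the downward image vertical and folded to
[0, 180), with one fixed handedness used everywhere: angle a corresponds
to the line direction (Δrow, Δcol) = (cos a, −sin a), i.e. positive
angles rotate from the down vector toward decreasing column. The ellipse
orientation φ, the Hough conversion (a Hough normal θ maps to the NIH
angle θ itself), the removal strip, the overlay renderer and the
synthetic generator all share this convention — mixing mirror conventions
between the two estimation paths would make line removal erase the wrong
branch of a crossing region, which is why the convention is centralized
and property-tested (transposing a pixel set maps φ to (90° − φ) mod 180).

## Shape descriptors

L and ω are the major/minor axis lengths of the ellipse with the same
normalized second central moments as the region. Second moments per unit
area are augmented by 1/12 on the diagonal (the variance of a unit
square pixel), so a single pixel has a well-defined isotropic ellipse
(L = ω = 4·√(1/12) ≈ 1.155) and a 1-pixel-thick bar of l pixels has
Ar = l exactly. Isotropic regions get φ = 0 by a deterministic tie-break;
such regions never pass the T1 gate, so the tie-break never reaches the
output as an ellipse-path angle.

## Numerical choices

- **Derivative kernels.** Sampled Gaussian second-derivative kernels are
  moment-corrected: the second-derivative kernel is shifted to zero DC
  and rescaled to exact unit curvature, the first-derivative kernel to
  exact unit slope. Uncorrected sampled kernels respond at the 1e-4
  level to constant images, which the structureness term would amplify
  on flat background. Kernels truncate at 4σ with reflective boundaries;
  an image smaller than the kernel raises an error naming the minimum
  size.
- **Otsu** is computed by vectorized cumulative sums and verified in
  tests against exhaustive search over all candidate levels.
- **Hough** votes are binned at round((ρ + diag)/ρ_step); the winning
  cell's vote count is reported with the line. Only the source region's
  pixels vote.
- **Removal strip** membership uses distance ≤ half-width + 1e-9 so
  pixels exactly on the strip edge do not flip with rounding of
  cos(90°) ≈ 6e-17.
- **Tie-breaks**: longest region by L, then larger area, then smaller
  label; Hough ties by smallest θ, then smallest ρ. The terminal line
  that triggers the T3 stop is kept by default
  (`drop_terminal_short_line=False` flips this), since the stop check
  runs after the line is recorded.

## Synthetic data

`sonofiber.synthfix` renders anti-aliased rotated bars of known angle,
length, width and intensity, adds a background level, blurs (Gaussian,
σ = 1 px default), and multiplies per-pixel unit-mean gamma speckle
(shape k = 4 by default — a standard surrogate for fully developed
multiplicative ultrasound speckle; variance 1/k). Broken bars carve gap
intervals along the axis; crossings verify on the noiseless render that
the two bars merge into one 8-connected component (the branched pattern
the Hough path exists for). Sequences share geometry while bar angles
follow a per-frame trajectory, with per-frame seeds derived
deterministically from the base seed (frame 0 reproduces the base scene
exactly).

What the generator does *not* emulate: point-spread-function anisotropy,
attenuation with depth, log compression, curvature of real fascicles,
and intensity inhomogeneity of real aponeuroses. Passing recovery tests
therefore demonstrates correctness of the geometry pipeline under
multiplicative noise, not clinical-grade accuracy on scanner data.

Branched-crossing test scenes use bar width 7 px: under the default
speckle, thinner arms occasionally fragment in the binarized map, in
which case no branched component exists and the scene no longer
exercises the Hough path it is meant to test.

## Problem sizes

Test and acceptance runs use 160–300 px frames, 50 single-bar fixtures
for angle-recovery statistics, 5 crossing fixtures, and a 50-frame
sinusoidal sequence (±5° around 110°). These sizes give stable
statistics (angle errors well below 1°, correlation ≈ 1) while keeping
the full suite in a few seconds.

## Known limitations

- The detector reports straight lines; curved fascicles are approximated
  by their dominant orientation.
- Otsu assumes a roughly bimodal enhanced histogram; a frame with no
  bright structure yields scattered small regions, bounded by N and T3.
- One line is extracted per branched region per iteration; a region with
  more than two branches needs several iterations, and removal may
  temporarily split it into fragments that re-enter the queue.
- Angles are axial (mod 180°); a sequence crossing 0°/180° would need
  unwrapping downstream.
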