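# sonofiber

Automatic muscle fiber orientation (MFO) estimation in B-mode ultrasound
images of skeletal muscle.

In longitudinal sonograms, fascicles and aponeuroses appear as bright,
roughly straight bands whose angles carry the muscle's architecture
(fascicle orientation, and downstream, pennation angle and fascicle
length). Measuring those angles by hand frame-by-frame is slow and
operator-dependent; voting-based line detectors are accurate but
expensive when every candidate pixel votes. sonofiber implements an
efficient alternative for researchers in muscle biomechanics and
rehabilitation: enhance the tubular bands, binarize, then extract lines
one at a time, longest region first, using cheap second-moment ellipse
orientation for ordinary regions and falling back to a region-restricted
Hough transform only for branched ones.

## Method

Per frame:

1. **Multiscale vesselness enhancement** — at each Gaussian scale σ, the
   σ²-normalized Hessian eigenvalues (|λ₁| ≤ |λ₂|) score bright bands by
   `exp(−R_B²/2β²)(1 − exp(−S²/2c²))` with R_B = λ₁/λ₂ and
   S = √(λ₁² + λ₂²), zero where λ₂ ≥ 0; the response is the per-pixel
   maximum over scales.
2. **Otsu binarization** of the enhanced image → candidate map.
3. **Iterative detection** — take the 8-connected region with the
   largest equivalent-ellipse length L; if aspect ratio Ar > T1 and
   width ω < T2 (defaults 5 and 30 px) report the ellipse major-axis
   angle, otherwise run a Hough transform over that region's pixels and
   take the global accumulator peak; clear a 17-px-wide strip along the
   detected line (consuming noise and collinear broken-fiber fragments);
   stop at N lines (default 7) or when the current length drops below
   10 % of the first (T3).

Angles follow the NIH-Image convention: degrees from the downward image
vertical, in [0, 180). Each output line carries its detection order,
angle, estimation method (`ellipse`/`hough`), source-region shape
descriptors, and Hough votes where applicable.

## Worked example

No clinical data ships with the package; the built-in generator renders
sonogram-like frames with exact ground truth — bright bars with known
angle/length/width, Gaussian blur, and unit-mean multiplicative gamma
speckle:

```python
from sonofiber import BarSpec, SceneSpec, render_scene, run_pipeline

scene = SceneSpec(
    shape=(200, 200),
    bars=(
        BarSpec(angle_deg=112.0, center=(60, 100), length=150, width=4),   # fascicle
        BarSpec(angle_deg=108.0, center=(100, 100), length=150, width=4),  # fascicle
        BarSpec(angle_deg=90.0, center=(150, 100), length=170, width=8),   # aponeurosis
    ),
    seed=42,
)
frame, truth = render_scene(scene)
result = run_pipeline(frame)
for ln in result.lines:
    print(f"{ln.order:>5} {ln.angle_deg:>8.2f} {ln.method:>8} "
          f"{ln.L:>7.1f} {ln.omega:>6.1f} {ln.Ar:>6.1f}")
```

prints

```
    1    90.03  ellipse   196.8    8.6   22.9
    2   112.00  ellipse   169.4    6.1   27.8
    3   107.95  ellipse   169.3    6.2   27.4
```

The horizontal aponeurosis surrogate is detected first (longest region,
true angle 90°), then the two fascicles (true angles 112° and 108°), all
recovered within 0.05° here, and all through the fast ellipse path —
every region was long and thin, so the Hough transform never ran. L, ω
and Ar are the major axis, minor axis and aspect ratio of the region's
moment-equivalent ellipse in pixels; detection would fall back to
`hough` only for a region failing the Ar > 5, ω < 30 gate, e.g. two
crossing fascicles merged into one X-shaped component.

## Command line

```sh
sonofiber detect frames/ -o out/ --roi 40,10,300,440 --overlay
sonofiber track sequence.tif -o out/
sonofiber enhance frame.png -o enhanced.tif
sonofiber make-fixtures -o fixtures/ --seed 1
```

`detect` and `track` write `lines.csv`
(frame, order, angle_deg, method, L, omega, Ar, anchor, votes), a YAML
run manifest, and optional per-frame overlays (lines color-coded by
method) and float-TIFF intermediates. `--roi top,left,height,width`
crops scanner tags away before processing.

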