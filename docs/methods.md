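# Methods

## Scope and data model

`angioquant` quantifies 2-D grayscale en-face projections of microvascular
beds.  It does not read OCT volumes, reconstruct flow signal, or stitch
sub-images: the input is an already-projected raster (8/16-bit PNG or
TIFF), normalized on load by the format's full-scale value (255 or 65535)
so that intensity thresholds mean the same thing across images.  Grayscale
images are float64 arrays in [0, 1]; masks are boolean arrays.  Pixel pitch
is unknown in general and carried only as documentation (the reference
configuration assumes ~8 µm/px, at which the largest microvessels of
~100 µm span ~13 px).

## Segmentation

Binarization is the composition

1. **Contrast stretch** — intensities at or below the `saturation_frac`
   quantile map to 0, at or above the `1 − saturation_frac` quantile map
   to 1, linear in between.  Default 0.01 per tail (1% of pixels saturated
   at each end).  A constant image degenerates to all zeros with a warning.
2. **Top-hat low-pass (V1)** — the image minus its grayscale opening by a
   Euclidean disk of radius `V1` (erosion then dilation).  This retains
   bright structures narrower than the disk (vessels) and removes the
   slowly varying background.  The raw opening is available via
   `lowpass_mode="opening"`, but it is not the default: with the reference
   `V1 = 15` an opening's 31 px disk would erase every vessel at the ~13 px
   width scale, so the filter the reference parameters were tuned for must
   be the top-hat.
3. **Global threshold (V2)** — pixels strictly below `V2` are zeroed;
   pixels at or above pass through unchanged.
4. **Adaptive threshold (V3)** — a pixel is vessel iff it exceeds the mean
   of its `V3 × V3` sliding neighborhood (mirror padding at borders).
   Window sides are coerced to the nearest odd integer ≥ 3 so a center
   pixel exists; the reference `V3 = 10` runs as 11.  If the window exceeds
   the image, the global mean is used with a warning.

Defaults are the reference optimum `(V1, V2, V3) = (15, 0.15, 10)`.

Numerical conventions: the strict local-mean comparison uses an absolute
tie tolerance of 1e-9 — the sliding-sum mean filter leaves ~1e-17 float
residue in exactly-flat regions, and a bare `>` would turn zero-background
fields into false positives.  The tolerance is ~4 × 10⁶ times smaller than
one 8-bit quantization step, so it only absorbs float noise; exactly flat
regions are classified background.  The structuring element is a discrete
Euclidean disk; the adaptive neighborhood is a sliding window (disjoint
tiles were rejected: they would imprint tile boundaries on the mask).

## Skeletonization

Masks are thinned to unit-width centerlines by the two-subiteration
boundary-deletion scheme of Zhang & Suen (scikit-image implementation,
fixed scan order, hence deterministic), preserving 8-connected foreground /
4-connected background topology.  Isolated single pixels are retained as
length-1 segments — deleting them would silently change VLF.  No spur
pruning is applied; pruning would also change VLF and is left to the
caller.

## Metrics

- `VAD = foreground pixels / total pixels` of the mask.
- `VLF = skeleton pixels / total pixels`.  Pixel count is used as length
  directly, without a √2 correction for diagonal steps.
- **Box counting**: the grid is anchored at the top-left corner; partial
  boxes at the right/bottom edges count.  Default box lengths are powers
  of 2 from 2 to `min(H, W)/2`; images under 16 px per side get the `l = 1`
  scale prepended so at least three scales exist.  `N(1)` equals the pixel
  count, so the `l = 1` point is excluded from automatic fits whenever at
  least three larger scales are available.
- **Linear-region fit**: quasi-fractal rasters are linear only over a
  subsection of the log-log curve, so the fit region is selected
  automatically as the contiguous run of at least `min(5, n)` points
  maximizing r², preferring longer runs and earlier starts on ties.  A
  manual `fit_range` override is exposed.  FD = −slope; the chosen range,
  slope and r² are recorded on the curve.  Fits on fewer than 3 scales are
  refused.
- For vessel masks, FD is computed on the skeleton (more sensitive to
  pattern change than the filled mask); for the pentaflake calibration it
  is computed on the rendered raster directly.
- Results from images under 16 px per side carry an accuracy warning: the
  crop-size study shows FD estimates in that regime scatter widely.

## Pentaflake calibration

The generator places a point-up regular pentagon of circumradius
`0.48 × raster` at the raster center and recursively replaces each
pentagon of circumradius `R` with six of circumradius `R/(1+φ)`
(`φ = (1+√5)/2`): five centered at distance `R·(1 − 1/(1+φ))` toward each
vertex with the parent's orientation, one concentric copy rotated by π.
Pentagons are rasterized filled (outline mode exists for sensitivity
checks), without anti-aliasing, so the raster is an exact union of digital
pentagons.  At iteration 5 on a 1024² raster the smallest pentagons have
~4 px circumradius — resolved, but coarsely; the raster was chosen at 1024
because crop studies to 512 px require the source to exceed 512 px per
side.

The closed-form dimension is `log 6 / log(1+φ) ≈ 1.8617`.  Box counting on
the rendered raster yields ≈ 1.82: the rasterized figure is a
quasi-fractal (finite iteration, finite resolution, filled pentagons of
dimension 2 at the smallest scales), so the estimate depends mildly on the
rendering and fitting conventions; agreement within ±0.05 is the
calibration criterion.

Crop-size behavior: sampling square crops (shared random centers from the
central region where all sizes fit, undefined-FD crops skipped) shows the
mean FD error falling from ~0.16 at 16 px to under 0.01 at ≥128 px, where
it reaches the Monte-Carlo resolution floor, while the FD spread falls
monotonically (~0.4 → ~0.03); 8 px crops are distinctly worse than 16 px.
Hence the 16 px minimum window rule and the warning below it.

## Vessel phantoms

Phantoms emulate the *appearance statistics* of en-face angiography:
bright tortuous vessels on a dim noisy background.  Vessels are random
walks (unit steps; per-step heading change ~ N(0, tortuosity²)) entering
from the image edges, dilated to a per-vessel width drawn from
`width_range`, with recursive branching (probability `branch_prob` per
step, branch width × 0.7, depth ≤ 2).  The image is
`background + intensity · mask`, Gaussian-blurred, plus additive Gaussian
noise, clamped to [0, 1]; the returned truth mask is the exact pre-blur
support.  All randomness flows from one integer seed; identical specs give
bit-identical outputs.

Defaults (256 px raster, 5 main vessels, widths 3–13 px, tortuosity
0.15 rad, branch probability 0.01, intensity 0.8 over background 0.08,
noise σ 0.05, blur σ 1 px) produce truth VAD ≈ 0.17–0.36 across seeds,
matching typical microvascular bed density at ~8 µm/px.  The phantoms do
**not** model speckle decorrelation physics, flow-dependent signal,
shadowing or projection artifacts — so passing phantom tests demonstrates
correctness of the measurement pipeline, not robustness to every
real-world artifact.

## Validation and parameter sweep

Computer segmentations are scored against gold-standard masks by pixel
confusion counts; overlays use yellow/green/red/black for TP/FN/FP/TN.
`Se = TP/(TP+FN)`, `Sp = TN/(TN+FP)`; undefined ratios (empty gold
foreground or background) are returned as missing and warned about.  The
sweep scores every `(V1, V2, V3)` combination by `(Se+Sp)/2` (the
arithmetic mean, not Youden's J), records the full scatter, and breaks
score ties by smaller `(V1, V2, V3)`.  The shipped default grid is the
Cartesian product of 10 values per variable — `V1 ∈ [3, 30]`,
`V2 ∈ [0.05, 0.5]`, `V3` odd in `[5, 41]` — 1000 combinations; stage
outputs are cached per distinct `(saturation, mode, V1)` and `V2`, so a
sweep costs roughly one opening per distinct `V1`.  Percent variation
between manual and automatic metrics is `100·|manual − auto|/manual`
(manual in the denominator), undefined when the manual value is 0.

## Sliding maps

A `window × window` crop is evaluated at every pixel; the value is stored
at the window's designated center, offset `⌊(window−1)/2⌋` from its
top-left corner (the 0-based equivalent of a 1-based (16,16) center in a
32 px window).  Windows are clipped at image borders; the clipped band of
`⌊window/2⌋` px is flagged invalid and excluded from ROI statistics.  The
mask is skeletonized once globally and the skeleton cropped per window —
re-thinning each crop would create window-boundary artifacts and cost
~window² more.  VAD/VLF maps are computed exactly for all pixels via
integral images; the FD map is fitted per position and accepts a stride
(each value fills its stride block) for large images.  Windows with an
empty skeleton crop get FD 0 with a validity flag off.  The default window
is 32 px (~250 µm at ~8 µm/px): large enough to contain at least one
full-width vessel, small enough to keep the map resolving local variation.

## Known limitations

- FD of finite rasters is convention-dependent (box anchoring, fit-region
  choice); comparisons across software should use one implementation.
- VLF inherits the skeletonization's sensitivity to single-pixel mask
  differences; between independently produced masks of the same field it
  varies far more than VAD or FD (on the order of 20% vs under 5%).
- The adaptive threshold hollows out perfectly flat bright plateaus wider
  than the window (no pixel exceeds the neighborhood mean); real images
  carry texture, and vessels near or below the window size, so this arises
  mainly on synthetic constant-intensity fixtures.
- Problem sizes in the test suite (256 px phantoms, 1024 px pentaflake,
  crop pools of 400–1500) were chosen to estimate each property stably;
  they are the package's own study conditions, not measurements of any
  particular instrument.
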