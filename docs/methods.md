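# Methods

## Radiometric model

A thermogram is an 8-bit grayscale image whose sidecar records the scene
extremes T_min and T_max (°C) registered by the camera software, the surface
emissivity (default 0.97, human skin), the working distance (default 1.2 m)
and the sensor IFOV (default 1.36 mrad). Gray levels convert to temperatures
through the affine map

    T(g) = T_min + (g / g_max) · (T_max − T_min),

where g_max is the **observed** maximum gray level of the image, not the
nominal depth. This keeps the hottest pixel pinned to T_max and makes the
calibration image-dependent; the map is taken verbatim as the tool's
conversion contract. Emissivity is carried as metadata only — no radiance
correction is attempted. All-zero images are rejected as degenerate.

Per-region statistics use the population standard deviation (divide by n);
reported tables carry no indication either way, so the population convention
was fixed and is documented here (tests tolerate ±0.01 °C against either).

The optics helper returns `safety_factor · (IFOV/1000) · distance`:
0.001632 m theoretical spot at the protocol distance, and ×3 (MFOV) ≈ 0.49 cm,
the practical bound for reliable readings — which is why lesions below about
half a centimeter are outside the tool's design envelope.

The stabilization check takes a cool-down series (minute, °C) and returns the
first time point after which every successive slope stays within a tolerance
(default 0.05 °C/min, the camera sensitivity per minute); the criterion is
this package's own, chosen because acquisition protocols only prescribe the
outcome (roughly 25 min of rest) rather than a test statistic. A series that
never flattens returns +∞.

## Body masking

Otsu's threshold is computed from the 256-bin histogram with class 1 = gray
≤ t. σ_B²(t) is defined as 0 whenever a class is empty, ties in the argmax
resolve to the lowest threshold, and a constant image is a degenerate-input
error. The body is the bright class (hot renders bright; `--invert` covers
reversed palettes). A configurable scale-bar rectangle is zeroed before
thresholding (default: none — phantoms carry no bar). The raw threshold mask
is then reduced to its largest 8-connected component and hole-filled: this
cleanup is not part of the thresholding theory but is required so the contour
tracing downstream sees one simply-connected silhouette. Foreground fractions
of 0% or >95% raise a segmentation failure, which surfaces as the pipeline's
"unknown" outcome.

## Breast segmentation

Coordinates are 0-based with origin top-left, x = column, y = row; "above"
means smaller y. Side naming is anatomical: the patient's right breast is the
viewer's left half. Horizontal mirroring of the input provably swaps the two
outputs.

**Fold detection.** Threshold = (maximum gray *within the body*) − offset
(default 10 gray levels). The within-body maximum is used rather than the
global one so that a bright scale bar or border artifact cannot shift the
threshold. Supra-threshold 8-connected components are ranked per lateral half
(relative to the body centroid column) by maximum interior Euclidean distance
— the fold is a thick structure, so ranking by thickness rather than area is
the intended reading of "largest"; area breaks ties. A component spanning the
midline contributes ridge points to both sides; points split at the centroid
column. Ridge points are the per-column topmost pixels of the kept
components.

**Polynomial completion.** Each side's ridge points are fitted independently
by least squares to y = a₀ + a₁x + a₂x². Fewer than three distinct x values
is an error. The in-range real root of the difference polynomial nearest the
midline is the split point; with no real root the midline column at the mean
fold height is used, flagged low-confidence.

**Armpit detection.** The contour is the morphological gradient (mask minus
its 3×3 erosion). Each lateral contour line is parameterized top-to-bottom as
x(y) over the rows above the split point, and slopes are taken with the
two-point secant of step h = 10 px, clamped to forward/backward differences
near the ends. The armpit score at a point is |forward secant − backward
secant| with the same step: this statistic peaks *at* a contour corner,
whereas differencing two successive centered secants peaks h samples to
either side of it, so the forward/backward form is used. Exact-tie plateaus
(a crisp corner seen through an h-wide window) resolve to their center. A
near-zero peak (straight contour) is a segmentation failure.

**Assembly.** Upper boundary: straight segments from each armpit point to the
split point. Lower boundary: the fitted polynomials, minus a guard band
(default 4 rows) excluded just above them — the fold crease is itself the
hottest skin in the region; without the guard band its thermal tail would
dominate both side means and hijack the hotspot search toward the mask edge.
The region is clipped to the body mask and divided at the split column.
Empty sides raise the "unknown" outcome.

## Asymmetry rule

The verdict uses only the side means: |T̄_right − T̄_left| ≥ 1.0 °C flags
"problem detected" (≥, so exactly 1.0 °C is positive); max/min/SD differences
are reported but never drive the verdict. The threshold is configurable
(`--delta-t`) because the literature quotes suspicious ranges from 1 to
2.5 °C, with 1.0 °C the default operating point. The hotter side is reported
only on a positive verdict.

## Hotspot localization

Watershed flooding is classically described from regional minima, while the
screening question asks for the hottest region; the package resolves this by
flooding the additive inverse of the thermal matrix (−T), restricted to the
hotter side's mask, so warm peaks become catchment basins. Seeds are the
h-maxima of T with depth δ (default 0.5 °C — below it, structure is at the
noise/quantization scale; configurable), labeled with 8-connectivity;
`skimage.segmentation.watershed` performs the flooding with watershed lines
kept. A constant region is a single basin with no lines. The hotspot is
defined as the basin containing the globally hottest masked pixel — not the
basin with the highest mean — because it is deterministic and assertable by
construction. Its centroid is temperature-weighted. Shape descriptors (area,
best-fit-ellipse eccentricity, major/minor elongation, with ∞ for degenerate
line-like basins) are emitted without any diagnostic label: distinguishing a
compact tumor-like spot from an elongated vessel-like pattern is left to the
expert. The watershed operates on the thermal matrix, not the gray image:
temperatures are the physical quantity, and δ then has units of °C.

## Phantom generator

The generator emulates what the algorithms consume in a frontal acquisition,
not tissue biophysics (no bioheat modelling):

* **Silhouette** (default 240×320 px, scaled with image width): raised-arm
  bars flanking a head/neck block, a torso whose lateral contour steps from
  the arm half-width (75 px) to the torso half-width (55 px) across a 4-row
  notch at the armpit row (~90), then widens gently toward the hips. Edges
  are softened with a σ=1 px Gaussian.
* **Temperatures**: background 22 °C, body 33 °C (clinical scenes put skin
  near 33 °C over a ~21–23 °C room).
* **Fold ridges**: Gaussian tubes (σ ≈ 3 px) of height 4 °C along two
  quadratics with vertices at the breast centers — the fold is rendered as
  the hottest skin, which is the premise the fold threshold relies on.
* **Lesion**: a broad warm plateau (elliptical, semi-major 24 px, smooth
  shoulder) of 1.5–3 °C plus a small 0.3 °C focal peak at its center. A
  vascularized lesion warms much of the breast, and the screening statistic
  is the *side mean*: a few hot pixels cannot move a 2000-px region mean by
  1 °C, so a realistic detectable lesion must be spatially extended. The
  lesion peak stays below the ridge peak so the fold threshold continues to
  isolate the folds. A vessel-arc variant (warm tube along a polyline) covers
  elongated angiogenesis-like patterns.
* **Noise**: additive Gaussian, default σ = 0.05 °C (the camera sensitivity);
  randomized sweeps draw σ from 0.02–0.08 °C.
* **Quantization**: the °C field's own extremes become the sidecar
  t_min/t_max and gray = round(255·(T−t_min)/(t_max−t_min)), so phantoms are
  self-calibrating and the conversion round-trips within half a gray step.

Ground truth is generated from the same geometric definitions the pipeline
estimates: the true fold polynomials, their intersection, the inner notch
corners as armpit points, and breast masks assembled with the same guard
band (the breast proper excludes the fold crease by definition, so the IoU
comparison is definitional rather than tuned). The truth "lesion disk" is
the circle of the stated radius around the lesion center; the lesion is
placed off-fold so fold detection and hotspot localization stay decoupled.
The expected verdict is computed by applying the asymmetry rule to the truth
masks on the rendered field.

Randomized sweeps vary image width 288–352 px (height = 0.75 width), body and
background temperatures, ridge height 3.5–4.5 °C, ridge thickness, armpit
rows ±8 px, torso width ±10%, and fold vertex height; half the phantoms (by
default) carry a lesion with contrast drawn from 1.5–3.0 °C. Outcomes are
tabulated into a confusion table whose "unknown" column is fed by
segmentation failures, exactly as the pipeline reports them.

What the phantoms do **not** emulate: anatomical variability beyond these
parameter ranges (body habitus, asymmetric posture, pendulous or occluded
folds), physiological texture (vascular mottling, gradients from cooling),
scale bars and camera artifacts, and any relation between lesion depth and
surface contrast. Passing the sweeps therefore demonstrates that the
algorithms recover the structures they are designed around under realistic
noise and geometric variation — not clinical performance; the published
clinical rates are reproduced only as confusion-table arithmetic.

## Screening metrics

Rates are computed over resolved (non-unknown) cases — forced by the
published arithmetic, e.g. a sensitivity of 18/23 when 42 sick cases were
enrolled — with the unknown rate reported separately. Values are truncated
(not rounded) to 4 decimals, matching conventions such as 5/23 → 0.2173; the
complement identities tpr+fnr = 1 and fpr+specificity = 1 therefore hold to
within one truncation unit. The mean match is the unweighted mean of the two
per-class (truncated) match fractions; this reproduces the published
79.605% overall-coincidence figure and is exposed under that derivation
without asserting it as anyone's canonical definition.

## Problem sizes and numerical choices

The validation sweeps use 200 randomized phantoms each for segmentation
recovery and screening rates and 60 lesion phantoms for hotspot
localization; at these sizes a ±1 case changes a rate by ≤1%, adequate for
the ≥0.85/≥0.90/≥0.95 checks, and a full run completes in well under a
minute on one CPU. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); identical seeds give bit-identical phantoms
and byte-identical pipeline reports. Degenerate inputs (constant images,
empty masks, contours shorter than 2h+1, all-zero gray) raise typed errors
that the pipeline converts into the "unknown" outcome with exit code 3.

## Known limitations

* Frontal views only; semi-oblique acquisitions need a different geometric
  model.
* The fold threshold assumes the inframammary fold is the hottest structure
  inside the body mask; a lesion hotter than the fold would corrupt the fold
  evidence (in practice the crease is consistently among the warmest skin).
* The gray→°C map inherits the camera software's scene extremes; no
  radiometric payload decoding or emissivity physics.
* The verdict is a fixed-threshold rule on side means — deliberately simple
  and interpretable; no texture features or learned classifier.
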