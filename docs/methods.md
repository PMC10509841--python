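# Methods

## The measurement problem

The conjunctival provocation test (CPT) applies allergen to one eye in
increasing concentrations (dilutions 1:1000, 1:100, 1:10, then the stock
extract at 30 HEP/mL) and reads the reaction from conjunctival redness and
symptoms.  Human grading is subjective; `cptquant` implements an
instrument readout: per-pixel colorimetric redness of the sclera,
aggregated over both eyes and three gaze positions, with the untreated eye
used as an in-image control that cancels illumination and white-balance
drift between captures.

## Per-pixel redness index

For a pixel with 8-bit channels normalized to `r, g, b ∈ [0, 1]`
(value / 255) and Euclidean color magnitude `s = sqrt(r² + g² + b²)`:

```
R = (27/4) · (r − sqrt((g² + b²)/2)) / s · (1 − s)²
```

* `r − sqrt((g²+b²)/2)` is red in excess of the quadratic mean of green
  and blue; it vanishes exactly for achromatic pixels, so gray sclera
  scores 0 regardless of brightness.
* Division by `s` makes the ratio a chromaticity, independent of global
  gain to first order.
* `(1 − s)²` suppresses pixels at unit color magnitude; a fully saturated
  pure channel (`s = 1`) scores exactly 0.  `R = 0` is defined at `s = 0`
  (black) by the limit convention.

Numerical facts, frozen once by exhaustive evaluation and asserted in the
test suite:

* the maximum over pure-red pixels (`g = b = 0`) on a grid of 10⁴ points
  in (0, 1) is **6.748650202473003**; for pure red the index reduces to
  `(27/4)(1 − r)²`, so the 27/4 prefactor does *not* normalize this factor
  arrangement to a unit maximum (it would for the arrangement without the
  `1/s` factor, whose pure-red form `(27/4)·r(1−r)²` peaks at exactly 1 at
  `r = 1/3`).  We keep the `1/s` arrangement because the chromaticity
  normalization is what makes the index brightness-independent, and freeze
  the grid-search value as the documented normalization constant;
* the attainable range over the full 8-bit RGB cube is
  **[−4.735609110210861, 6.697162629757786]**.

Note that with per-channel normalization `s` ranges up to √3, so the
`(1 − s)²` weight re-grows for very bright near-white pixels (`s > 1`);
bright sclera typically sits at `s ≈ 1.2–1.4`.  This is a property of the
formula as defined and is left untouched.

## Distributions, binning, gradients

Redness over a sclera mask is summarized as a histogram with **256 uniform
bins over the attainable range** (bin width ≈ 0.0447, matching 8-bit
source granularity) plus the exact unbinned mean.  The distributions of
the three gaze positions of one eye are pooled by concatenating pixels, so
the pooled mean is the pixel-count-weighted mean.

Texture of the redness field (vessel-dominated versus diffuse reaction) is
exported as squared-gradient distributions: for spatial lags k = 1..4
pixels, the squared differences of the redness at axis-aligned pixel pairs
with both endpoints in the mask.  Lags are taken along image axes only
(the simplest reading of evenly spaced steps; diagonals could be added
without changing the contract).  These histograms use 256 bins over
[0, 1] squared-redness units with larger values clipped into the top bin —
neighboring sclera pixels differ by ≪ 1, and binning over the theoretical
maximum would collapse all structure into the first bin.  The gradient
features are exported but deliberately do **not** enter the scalar score;
no downstream use is defined for them in the scoring model.

## Internal-control white-balance normalization and the score

Illumination drift during a session shifts apparent redness of both eyes
equally.  Since the untreated (right) eye never receives allergen, any
change of its redness distribution between the reference image and a
provocation timepoint is attributed to drift:

1. build the four pooled distributions: control eye at reference and
   timepoint, treated eye at reference and timepoint;
2. find the rigid shift `δ*` that maximizes the histogram-intersection
   overlap (sum of bin-wise minima of normalized counts) of the control
   eye's timepoint distribution against its reference distribution.  The
   search runs over integer bin shifts spanning the full redness range;
   ties are broken toward the smallest |δ|, then the smaller signed δ.
   Histogram intersection was chosen as the overlap functional because it
   is standard, robust and exactly optimizable on a grid;
3. shift both timepoint distributions by `δ*`;
4. `raw = mean(shifted treated timepoint) − mean(treated reference)`;
   the score is `max(raw, 0)` (published score axes span 0–3.7), with the
   raw value preserved for audit.

Degenerate single-occupied-bin distributions carry no shape information;
for those the shift falls back to the difference of means and the result
is flagged low-confidence.  Because `δ*` is quantized to whole bins, the
internal-control cancellation is exact only to about half a bin width
(≈ 0.022 redness units); this is the dominant term in the ≤ 0.05 residual
the acceptance suite enforces on drift-only sessions.

The scalar score is a difference of distribution **means** — the mean is
the scalar the measurement model defines; alternatives (quantile shifts,
earth-mover distance) would need a separate calibration.  The reference
defaults to the pre-test baseline image; referencing the post-control-
solution image instead is supported (`reference_timepoint="control"`), and
the control-solution timepoint is itself scored so a session with a
reactive control can be rejected.  Classification is strict:
positive iff score > threshold.

## Segmentation

The deep segmentation network of the original instrument is not
reproduced; segmentation is a pluggable interface
(`segmenter(image) → EyeSegmentation`) with a classical baseline suited to
pre-cropped single-eye images:

* iris: largest dark (`mean channel < 0.35`), roughly circular connected
  component between 64 px and 30% of the image;
* sclera: bright (`> 0.45`), low-saturation (`(max−min)/max < 0.32`)
  components adjacent to the iris, closed and hole-filled; skin is
  excluded by its higher saturation, which is invariant to exposure.

Validity checks mirror the clinical artifact controls and gate scoring:
`eye_missing` (no iris candidate, e.g. a blink or empty frame),
`mask_too_small` (sclera below 2% of the image — rejects blink frames
without rejecting side gazes), `iris_sclera_uncoupled` (less than 30% of
the iris perimeter adjacent to sclera — tolerant to partial eyelid
occlusion).  The presence of two open eyes is enforced at session level:
scoring refuses a timepoint unless both eyes' images pass validation.
Downstream scores depend on segmentation only through the mask contract;
swapping the baseline for exact ground-truth masks moves phantom session
scores by well under 0.05 score units.

## Synthetic generator: what it emulates, what it does not

Phantoms are composed of an elliptical sclera on skin background, an iris
disk displaced ±0.45·radius by gaze, vessels as random-walk polylines with
Gaussian cross-section (producing the localized-gradient signal the
gradient feature targets), diffuse redness as a uniform red-channel
increment over the sclera, per-channel multiplicative illumination cast,
global exposure, Gaussian sensor noise (sd 0.008 per channel), and 8-bit
round-half-up quantization so renders are bit-reproducible.  Default
geometry is 192×144 px with a 26 px iris — small enough that a full
session (6 timepoints × 2 eyes × 3 gazes) renders and scores in about a
second, while leaving several thousand sclera pixels per image.

Ground truth per image: exact masks plus the mean injected redness — the
mean over the sclera of the index increase caused by the redness sources,
measured on the ideal (cast-, noise- and quantization-free) scene.  Session
ground truth differences therefore isolate the allergen effect exactly.

The session cast drift model is a red-channel gain drawn uniformly from
+8% to +14% with ±1% green/blue jitter, applied to both eyes equally: the
LED face mask stabilizes most of the illumination and residual room-light
drift is warm.  No magnitude is prescribed by the protocol, so this range
was fixed once as a realistic worst case large enough that an uncorrected
pipeline visibly mis-scores (the drift alone moves the un-normalized mean
redness by ≈ 0.06–0.11 units).

The cohort simulator reproduces the reference study structure by default:
41 patients distributed (4, 11, 16, 7, 3)/41 over first-reactive
categories {1:1000, 1:100, 1:10, stock, none}, assigned by
largest-remainder quota so exact multiples reproduce exactly (114
measurements under the stop rule).  The stop rule is keyed to the latent
category, mirroring the operator stopping on observed redness while
keeping ground truth exact.  sIgE is log-normal per category (medians
40/15/6/2/0.5 kU/L, log-sd 0.6 — spanning CAP classes ~1–5 with realistic
overlap); instrument scores at the reactive timepoint are
`0.65 + 0.25·level + N(0, 0.15)` (above the |N(0, 0.15)| noise floor and
increasing with sensitivity), and symptom grades are
`round(0.3 + 0.7·reactive + N(0, 0.8))` clipped to 0–3 — a weak reactive
signal under dominant observer/subject noise, matching the empirical
finding that symptom scores carry little dose information.

Not emulated: eyelids, lashes, specular reflections, tear film, camera
optics, pupil dynamics, photorealistic texture.  Passing tests therefore
demonstrate correctness of the measurement pipeline under controlled
confounders, not segmentation performance on real photographs — the
baseline segmenter's thresholds are tuned to the phantom's color regime.

## ROC and thresholds

Thresholds sweep 0.0–3.7 (75 grid points).  Sensitivity is tp/(tp+fn).
Specificity is reported as the standard tn/(tn+fp) — the quantity the
validation narrative uses — and precision tp/(tp+fp) is exported
alongside.  Smoothing fits each rate as a monotone function of the
threshold by isotonic regression (sensitivity non-increasing, specificity
non-decreasing — regressing sensitivity directly on the false-positive
rate would average the many thresholds sharing a tied rate and collapse
the curve); the smoothed ROC is the parametric polyline of those fits and
AUC its trapezoidal area after appending the all-positive corner (1, 1),
which a strict-inequality sweep never reaches.

The operating threshold maximizes Youden's J = sensitivity + specificity −
1 on the smoothed curve; ties go to the higher-specificity candidates, and
a remaining plateau of exactly optimal thresholds resolves to its midpoint
(the stable choice under resampling — with well-separated score clusters J
is flat over the whole gap between them).  The stringent threshold is the
smallest grid threshold whose smoothed specificity reaches the floor
(default 0.97); an unattainable floor returns the highest-specificity
threshold, flagged.

## Clinical layer

SSS = sum of four 0–3 symptom grades (range 0–12, both ends attainable).
CAP classes use the conventional ladder 0.35 / 0.7 / 3.5 / 17.5 / 50 /
100 kU/L with half-open intervals (a concentration equal to a boundary
joins the upper class); the table is configuration, not a constant.  The
study-inclusion sIgE floor of 0.01 kU/L is recorded as-is but flagged
anomalous, since it lies below the CAP class-1 boundary.  Sensitivity
categories support four rules — SSS ≥ 3, human redness grade > 1, the
combination (either), and instrument score > threshold — each returning
the first (weakest-dilution) measurement where the rule fires.  Group
comparisons of mean CAP class use two-sided equal-variance t tests with
the conventional star ladder; groups under 2 patients are skipped and
flagged, and the headline sensitive-versus-insensitive contrasts are read
against the "none" reference group.

## Known limitations

* The classical segmenter is calibrated to the phantom color regime; real
  photographs need a substituted segmenter honoring the same contract.
* Rigid histogram shifting models the cast as a translation of the
  redness distribution; strong casts act mildly multiplicatively, leaving
  a sub-bin residual.
* Scores on phantom sessions occupy roughly 0–0.3 redness units (diffuse
  increments up to ~0.16 without channel clipping); the 0–3.7 score axis
  of clinical data is exercised by the tabular cohort simulator rather
  than by rendered images.
* The gradient features are computed and exported but not consumed by the
  score.
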