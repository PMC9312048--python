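# Methods

## The measurement model

A traced frontal sinus outline is modelled as an open polyline arc in a
calibrated millimetre frame (x toward the image-right baseline terminus, y
superior). The arc runs from the left terminus of the supraorbital baseline
to the right one; the baseline segment itself implicitly closes the region.
The stroke of the original tracing is ignored: the arc is a zero-width
polyline, so the "inner border" of a drawn outline and the outline itself
coincide. Raster inputs (masks, ImageJ ROIs) are converted from the y-down
pixel convention to this frame only at the I/O boundary (`sinustd.raster`).

The ray origin is the intersection of the facial midline with the baseline
segment. Its placement is summarised by the midline ratio r = RB / B, where
RB is the distance from the origin to the image-right terminus and B the
total baseline length; r ≈ 0.5 for a centred origin. The angle datum is the
origin-to-right-terminus direction, angles increase counterclockwise, and the
default fan is 59 rays at 3°, 6°, …, 177°. Because angles are measured
relative to the baseline, profiles are invariant under rigid motions of the
whole configuration, and leveling a tilted image is a convenience (for
overlay placement), not a prerequisite of the geometry.

**Outermost rule.** A ray may cross a scalloped arc several times; the
line length L(θ) is the distance to the crossing farthest from the origin.
Crossings closer than 1e−9 mm along the ray are merged first, so a hit that
lands exactly on a shared vertex of two segments counts once. Intersections
are computed by a vectorised parametric segment–ray solve; the test suite
checks it against an independent per-segment brute-force oracle.

**Eligibility.** A sinus is measurable when (a) the arc rises strictly above
the baseline somewhere, (b) the origin lies strictly between the termini, and
(c) the arc is one connected chain anchored on the termini (touching lobes).
For arcs that stay on or above the baseline these conditions guarantee that
every ray in (0°, 180°) crosses the arc at least once, so all 59 lengths are
defined.

**Standardisation and scoring.** Profiles are standardised by the *total*
baseline length, s(θ) = L(θ)/B, which makes them invariant to global
rescaling (and hence to the image calibration). The Total Difference
TD = Σ|s_a − s_b| is an L1 distance on the 59-vector — a pseudometric: zero
for identical profiles, symmetric, triangle inequality. Ranking sorts
candidates by ascending TD with a stable sort, so ties keep input order.
A raw-millimetre variant (no standardisation) is available behind a flag for
workflows where all images share one calibration; the standardised score is
the default and the recommended one.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| ray fan (start, step, end) | 3, 3, 177 | degrees | the 59-line fan of the method |
| calibration target | 39.49 | mm | Howells' pooled orbital-breadth mean (dacryon–ectoconchion) |
| crossing merge tolerance | 1e−9 | mm | merges vertex-exact double hits; far below tracing precision |
| anchoring tolerance | 1e−6 | mm | arc endpoints / origin must sit on the baseline this closely |
| outlier fence multiplier k | 3 | IQRs | extreme outliers only |

## Error statistics

Bias = observed − expected; inaccuracy = |bias|. For each of the four line
variables (angle bias/inaccuracy, length bias/inaccuracy) the pipeline
applies a signed cube-root transform at the line level (bias can be
negative, so a log transform is unsuitable; the signed cube root is monotone
and sign-preserving), removes extreme outliers, averages per
image × mode × event, and feeds the summary means into fully within-subject
repeated-measures ANOVAs with subject = image (mode × round for
intraobserver error, mode × observer for interobserver error). No sphericity
correction is applied. Post hoc per-mode paired t-tests are Holm-adjusted.
Midline ratios and time-like quantities are treated as single summary points
per image × mode × event rather than per line.

Numerical choices:

* **Quartiles** use linear interpolation between order statistics (the NumPy
  default).
* **Outlier filter** re-fits its fences and repeats until no value falls
  outside them. A single pass of a re-fitted fence filter is not idempotent
  (removing a point shifts the quartiles, e.g. [0, 0, 0, 0, −1, −4]); the
  fixed-point form is, and on continuous data the iteration converges after
  the first pass in all but pathological cases.
* **Zero-variance designs** (all values identical) have zero effect sums of
  squares; F is reported as 0 and p as 1 rather than NaN.
* The RM ANOVA is computed by `pingouin.rm_anova` behind the package's
  surface; the tests verify it against a direct sums-of-squares
  decomposition and the paired-t equivalence (F = t²) in the two-condition
  case, and check the null rejection rate is calibrated at α = 0.05.
* Holm adjustment is `statsmodels`' step-down implementation, verified
  against a hand-worked example.

## The synthetic-data generator

`generate_outline` emulates the morphology an eligible sinus shows in a
posterior-anterior radiograph: two smooth lobes (Gaussian envelopes with
randomised heights, centres and widths), scallops ("arcades") as raised-cosine
bumps, and a window that pins the arc to the baseline termini and keeps it
strictly above the baseline in between. Default population values — baseline
width 60 mm, lobe apex heights 24/27 mm, 3 arcades per lobe of ~3 mm
amplitude, midline ratio drawn from N(0.52, 0.02) — were chosen once as
plausible adult magnitudes consistent with outlines spanning the supraorbital
region and a near-centred midline, and are configurable. One integer seed
fans out through `numpy.random.SeedSequence` to independent per-image and
per-event streams, so identical seeds reproduce identical vertices and noise
draws bit for bit.

`simulate_observer` models three independent Gaussian error sources per
measurement event: angle placement (sd in degrees, per line), length reading
(sd as a fraction of B, per line, added to the true ray length at the placed
angle), and origin placement (sd in mm along the baseline, one draw per
event). Expected values are the noiseless profile from the true origin at
the nominal angles. Per-mode defaults (angle sd 0.8°/0.3°/0.2°, length sd
1.5 %/0.8 %/0.5 % of B, origin sd 0.8/0.5/0.3 mm for freehand / overlay /
semi-automated collection) encode only the ordering "freehand noisier than
overlay noisier than semi-automated"; the magnitudes are package defaults,
not measured quantities, and every study function accepts explicit noise
models.

What the generator does **not** emulate: radiographic texture and
segmentation ambiguity, correlated (systematic) observer error across
neighbouring rays, drift between measurement rounds, population structure in
sinus shape (age, sex, ancestry), or truly discontinuous/unilateral sinuses
(it only produces eligible outlines). Passing tests therefore demonstrate
the correctness and stability of the measurement and scoring machinery under
idealised independent noise — not the identification error rate to expect on
real radiographs.

## Problem sizes used by the test and acceptance runs

The simulated observer study uses the 10-image × 3-mode × 3-event design
(5310 line records); invariance and oracle properties are checked over 1000
random outlines (6 randomly chosen angles each against the brute-force
intersection oracle, all 59 via the implementation path); noise-recovery
checks use 10⁴ simulated lines; the identification experiment uses 20
individuals with length noise of 1 % of baseline and angle noise of 0.2°.
These sizes make the full suite run in well under a minute while keeping
Monte-Carlo error far smaller than the tested effects.

## Known limitations

* The eligibility → full-ray-coverage guarantee assumes the arc does not dip
  below the baseline between its anchored endpoints; arcs that do are still
  measurable whenever each ray crosses them, and `cast_ray` reports a clear
  error for the angle otherwise.
* `extract_outer_contour` expects a mask whose single component touches the
  baseline row; perimeter follows the sub-pixel boundary polygon of the
  hole-filled foreground (the traced outer contour), a convention that can
  differ by a few per cent from other perimeter estimators at low resolution.
* The ImageJ ROI codec supports the polygon, freehand and line types used by
  this workflow, not the full ROI zoo.
* No match/non-match decision threshold is provided — only TD values and
  rankings; calibrating a threshold needs a reference database.
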