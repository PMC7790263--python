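# Methods

## Feature space

Each analysed site (or pixel) carries three raw, linear sensor counts
from white-light laser endoscopy: R, G and the 445 nm narrow-band blue
signal B445. The working coordinates are the G-normalised log ratios

* `x = ln(R/G)` — hemoglobin absorbs green far more than red, so x
  increases with hemoglobin content;
* `y = ln(B445/G)` — the 445 nm signal is absorbed by surface blood
  even more strongly than green, so y decreases under adherent blood.

Both are dimensionless and invariant to any gain applied to all three
channels (illumination intensity, working distance, sensor exposure),
which is what makes thresholds in this plane transferable between
images. Channel values are accepted as arbitrary positive reals — no
bit depth, white balance or gamma handling is assumed; inputs are
treated as linear raw signals. Non-positive or non-finite channels are
a domain error for single sites; in image mode the default policy
marks such pixels unclassifiable (an optional epsilon-clamp, default
0.5 counts, trades those holes for fabricated features in shadowed
pixels). Each plot-table row is treated as one already-aggregated site
value; no neighbourhood averaging is applied before the log transform.

## Discriminant model

Two binary tasks are modelled, one per colour family: blood vs.
reddish tumor, and white coating vs. whitish tumor. Classes are taken
as Gaussian in (x, y) with a shared (pooled within-class) covariance
S, so the optimal rule is linear: with class means m+ (adherent) and
m− (tumor),

```
w = S⁻¹ (m₊ − m₋),    score(z) = w·z − ½ w·(m₊ + m₋) + ln(π₊/π₋)
```

and the boundary `score = 0` is reported as `Y = slope·X + intercept`
with an explicit positive side. Defaults use equal priors (the
boundary then depends on geometry only and equals the
nearest-Mahalanobis-mean rule; empirical priors are available as an
option). Numerical edge cases: a pooled covariance with condition
number above 1e12 is a fit error (collinear inputs); coincident class
means raise a degenerate-boundary error; a boundary whose normal has
|w_y| below 1e−12 is vertical and cannot be written in slope form, so
it raises an unsupported-geometry error rather than returning garbage.
Points exactly on the boundary are assigned to the tumor class:
for masking it is safer to retain an ambiguous pixel than to discard
tumor area. Models are stored at full float precision (bit-exact JSON
round trip); display rounds to two decimals, matching the published
"−4.90X + 7.13" style. The published boundaries themselves are
available as `reference_models()`.

## Validation and cross-validation

Performance is reported as a 2×2 confusion matrix (rows = true class)
and the accuracy rate `100·(tp+tn)/total`, displayed to one decimal.
Cross-validation follows the original swap design: the held-out
validation sites are returned to the pool, an equally sized per-class
replacement validation set is drawn uniformly without replacement from
the original construction sites, the boundary is refitted on the
remaining pool and scored on the replacement set. The study drew the
replacement with a random number table; here a seeded generator plays
that role, so every replicate is reproducible and logged with its
seed. Stratifying the swap by class preserves the validation design's
class balance.

The study's single manually excluded aberrant site is generalised to
an optional rule — exclude points whose within-class squared
Mahalanobis distance exceeds the chi-square(2 df) quantile (default
0.999) — which is **off** by default; published validation counts are
taken as post-exclusion counts.

## Pixel masking and StO2 summaries

For whole images the two boundaries are applied per pixel inside a
required tumor ROI. The two tasks were constructed on separately
plotted red- and white-appearing sites, so whole-image application
needs a routing rule — the main methodological gap this package had to
close. Three are provided, recorded in output metadata:

* `either` (default): blood if the blood rule fires, else white
  coating if the coating rule fires, else tumor; when both fire, blood
  wins (the more extreme signature, and clinically the more important
  to exclude);
* `red_route`: a chroma gate (`ln(R/G) > 0.8` by default) sends each
  pixel to exactly one task;
* `annotation`: a user-supplied per-pixel task map.

Under `either`, pixels of one colour family can be claimed by the
other family's boundary (e.g. a few percent of reddish-tumor pixels
fall on the coating side of the coating rule at full spectral noise);
this is inherent to applying two independently constructed binary
rules to one image and is visible in the scene benchmarks.

Label maps use the fixed legend {0 unclassifiable, 1 tumor, 2 blood,
3 white coating}. StO2 summaries (pixel count, median, min, max) are
emitted for the combined region (tumor + adherent), the exposed tumor
and the adherent region; NaN StO2 pixels (saturation/halation markers)
are excluded from statistics and counts and tallied separately in the
log. Medians use the mean-of-middle-two convention. Regions with no
valid pixel are omitted with a logged notice.

## Synthetic-data generator

No endoscope data ships with the package; the generator emulates the
published study population so every stage is testable end to end.

**Spectra.** Each class's (R, G, B445) triple is multivariate
lognormal. Positivity is guaranteed, the strongly right-skewed
published ranges are respected, and the features (x, y) are then
exactly Gaussian — the regime where LDA is the Bayes rule, giving the
tests clean oracle properties. Log-medians are set to the published
per-class channel medians (construction cohort). The published tables
do not determine the log-space covariance, so it is calibrated:

* per-channel log-SD = (log of the published range ratio)/8, clipped
  so that the central-99% width of the channel stays within a factor
  of two of the published range width (the printed extremes of a few
  channels are too skewed about the median for a symmetric-in-log
  model to track both tails; the clip binds for blood B445 and
  marginally for reddish-tumor G). The extremes of ~70–90 manually
  plotted, partly within-lesion-correlated sites are treated as ~4 SD
  events rather than iid Gaussian extremes;
* cross-channel log correlation = 0.97: channel counts co-vary
  strongly with illumination, distance and surface geometry — the very
  gain that the log-ratio features are designed to cancel. This value
  also reproduces the reported ~96% discriminability of the harder
  (coating vs. whitish) task; weak correlations (say 0.7) would leave
  so much independent per-channel noise in the ratios that the two
  whitish classes would overlap far more than the published accuracy
  rates allow.

**Two cohorts.** The validation cohort's printed ranges are
systematically narrower than the construction cohort's (its plots were
placed on cleaner, more typical sites). The generator therefore
exposes construction models (`default_class_models`) and
validation-stage models (`validation_class_models`) that keep the same
population locations but use the validation cohort's tighter spreads;
the cohorts' median shifts are treated as lesion-sampling noise rather
than population structure. This reproduces the study's evaluation
pattern — boundaries fitted on construction-like draws score higher on
validation-like sites than on fresh construction-like sites — which is
the mechanism behind the published drop from ~96% held-out accuracy to
82–90% under swap-based cross-validation. `run_study` wires this up:
per task and class, 500 sites split 70% construction (fitting) / 30%
validation-stage (scoring), matching the study's ~3:1 cohort ratio,
followed by 20 swap replicates.

**StO2.** Per class, truncated normal with support equal to the
published range and SD = (range width)/6; the location is solved
numerically (Brent) so the truncated median equals the published
median. The published data constrain only median and range; the
normal-in-the-middle shape is a modelling choice.

**Scenes.** A scene is a frame with a rectangular or polygonal tumor
ROI and elliptical adherent patches (position, area fraction, aspect,
angle — geometry is cosmetic and carries no empirical claim; patches
must lie inside the ROI and their area fractions must sum below 1).
Per pixel, spectra are drawn from the true class's lognormal with the
log-space spread scaled by `noise_sd` (1 = full site-level
variability; 0 = exact class-median spectra) and StO2 from the class's
truncated normal. Outside-ROI pixels are filled with tumor-model draws
purely to keep the planes positive; they are labelled background and
never summarised. The default scene is 300×400 px with a 240×320 ROI
and two patches totalling 32% of the ROI. All generator output is
bit-for-bit reproducible for a fixed seed.

**What the generator does not emulate.** Spatial correlation within
regions (pixels are iid given the class), halation/saliva/specular
noise, demosaicing or registration artefacts, partial-volume mixtures
at patch borders, and any real relationship between a pixel's spectrum
and its StO2 (the two are drawn independently given the class).
Passing tests therefore demonstrate correctness of the pipeline's
logic and its behaviour under the published class statistics — not
performance on real endoscope frames.

## Problem sizes and determinism

Default benchmark sizes — 500 sites per class and task for the study
emulation, 20 cross-validation replicates, 2000 sites per class for
fitting the scene models, 300×400 px scenes (~77k ROI pixels, ≥10⁴
pixels per summarised region) — are chosen so all sampling errors are
small relative to the effects being checked (binomial SE ≤ ~1.3
percentage points on accuracies, ≤ ~0.2 on StO2 medians). Every
stochastic routine takes an explicit seed; derived seeds are spawned
deterministically from it.

## Known limitations

* Exact reproduction of the published coefficients (−4.90/7.13,
  −0.52/0.17) from data is impossible: the raw plot coordinates were
  never published, and the original fitting tool's prior convention is
  unknown. The published boundaries are shipped verbatim instead, and
  fitting is verified against analytic boundaries and oracle rules.
* The blood task is near-perfectly separable under the lognormal
  calibration (the published 95.9% includes two reddish-tumor sites in
  a heavier-than-lognormal tail that the generator does not model).
* Multiclass (>2) discrimination, regularised/kernel discriminants,
  ROC analysis and tumor-ROI detection are out of scope; the ROI is an
  input.
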