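# Methods

This note records the models, parameter choices, numerical conventions
and known limitations behind `colonoidquant`. Everything quantitative
stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external data.

## Study design

The design grid is six treatment arms — DMSO vehicle (reference),
tofacitinib, budesonide, TNF + Poly(I:C) stimulation, and the two
drug + stimulation combinations — crossed with two oxygen tensions
(2% physioxia as reference, 20% atmospheric) across donors, with
technical replicate wells and repeat experiments. `design.SampleKey`
carries (donor, oxygen, condition, well, experiment) on every
measurement row so all stages join consistently. Donor identifiers
encode diagnosis (HC/UC) as metadata only; no computation branches on
it. Dose bookkeeping is the identity µg/mL = µM × (g/mol) / 1000;
rounding is presentation-only. The DMSO vehicle fraction (0.033% v/v)
is stored as a constant because the stock concentrations needed to
derive it are not part of the dosing records.

## Brightfield morphometry

**Threshold.** The Phansalkar local threshold on intensities
normalized to [0, 1] is

    t = m · (1 + p·e^(−q·m) + k·(s/r − 1)),   defaults k=0.25, r=0.5, p=2, q=10,

with m, s the mean and standard deviation over a (2·radius+1)² window,
computed with mirror padding (uniform filters on x and x²; the
variance is clipped at 0 before the square root). Polarity is
`dark_objects` (value < t) by default because colonoids image as dark
rims on a bright background. The radius is per-experiment
configuration — different imaging sessions resolve different scales —
with 15 px as the default matched to the synthetic wells. The
implementation is checked for bit-identical agreement against a
direct-definition sliding-window oracle; with continuous-valued local
statistics, exact ties between a pixel value and its threshold are
measure-zero and have not been observed.

**Particle analysis.** On the binary mask: fill holes (so a colonoid's
lumen counts toward its area), label with 8-connectivity, drop any
particle touching the image border, drop particles with pixels outside
the region of interest when one is supplied (polygon, rasterized with
pixel-center convention), and drop particles below the minimum size.
The minimum-size field of classic particle analysis is an *area* when
the image is calibrated, so `min_size` defaults to an area of 10 µm²;
an equivalent-diameter reading is also supported
(`min_size_unit="diameter"`) because the phrasing of such settings is
often ambiguous in practice.

**Top-100 statistic.** Wells are summarized by the mean area of their
100 largest particles, ranked by area descending with ties broken by
ascending label id for determinism. With fewer than 100 particles the
mean covers all of them and the summary is flagged `truncated` rather
than padded or rejected. Condition summaries average well means per
donor × oxygen × condition and refuse mixed calibrations within a
group.

## Optical density and stain deconvolution

OD is computed per channel as −log10((I + 1)/I0) with I0 = 255 for
8-bit input; the +1 offset keeps zero pixels finite and makes I = 254
map exactly to OD 0. OD is clipped to [0, 3]. Chromogens mix linearly
in OD space (Beer–Lambert), so deconvolution solves M·c = od per pixel
with M's columns the unit stain vectors and clips negative
concentrations at 0. The default H-DAB vectors are the standard
published set — hematoxylin ≈ (0.65, 0.70, 0.29), DAB ≈ (0.27, 0.57,
0.78), residual = normalized cross product — because per-slide manual
deconvolution settings are inherently instrument-specific; custom
vectors are accepted everywhere and results obtained with the default
set should be read with that stand-in in mind. The float-path round
trip (synthesize M·c, deconvolve) is exact to 1e−9; through 8-bit
quantization the worst-case OD error at OD ≤ 1.3 is ≤ 0.02, which the
synthetic H-DAB generator keeps within by construction.

## IHC quantification

**Region segmentation.** Colonoid structures are segmented from
Gaussian-smoothed total chromogen OD (hematoxylin + DAB) with a fixed
threshold, closing (disk radius 2 px) and hole filling. This is a
deliberate classical stand-in for a trained pixel classifier: it is
deterministic, shippable, and behind a small functional interface so a
learned segmenter can replace it.

**Annotation filters.** Objects are excluded by mean OD-sum < 0.15,
solidity < 0.25, or residual-channel mean above 0 — operationalized as
exceeding a 1e−3 OD tolerance, since a literal "> 0" test would
exclude every object under float noise. The OD-sum statistic is the
*mean* of (hematoxylin + DAB) OD over the object; where aggregation
conventions differ between tools, the mean is this package's
documented choice.

**CK20 positive area.** The DAB channel is smoothed with a Gaussian of
sigma 2.5 px and pixels above OD 0.3 inside kept annotations count as
positive; the section score is 100 × positive px / annotation px. The
smoothing blurs a band of roughly sigma's width at planted boundaries,
which is why the planted-area recovery test carries a ±2-point band.

**Ki67 nuclei.** Detection on the hematoxylin channel: resample to
0.5 µm/px, subtract a morphological-opening background (disk radius
8 µm, a rolling-ball analog), Gaussian smooth at sigma 1.3 µm,
threshold at OD 0.1, split touching nuclei by distance-transform
watershed, and keep components of 15–200 µm². Classification: exclude
nuclei with hematoxylin mean < 0.11 (strict), call positive at DAB
mean > 0.15 (strict); the percentage is positives over non-excluded
nuclei. Intensity means are taken on the resampled but unsmoothed
channels so the smoothing scale does not bias them.

## Fluorescence quantification

**Detection.** Nuclei are detected on DAPI (channel aliases such as
"Ch1-T2" resolve via a documented map) after resampling to 0.225
µm/px. The default detector is classical — Gaussian smooth (sigma
2 px), foreground above an intensity floor (30), distance-transform
watershed — with a per-object detection score defined as peak smoothed
response / 256, lying strictly below 1. The detector interface
(image → labels + scores) mirrors star-convex deep detectors so a
pretrained network can be plugged in; the classical default exists to
keep the package free of weight files and nondeterminism. Objects
scoring below the probability threshold (0.6) are dropped.

**Filters.** Nuclei outside 12–175 µm² or with DAPI mean below the
mode-specific floor are excluded. The area window is read in µm²
(the plausible nuclear-area range); the DAPI floor is 60 for the TUNEL
read-out and 25 for the triple-marker read-out, both retained as
mode-specific defaults.

**Cytoplasm and compound classes.** Nuclei are expanded by 5 µm
(a common default; not a measured quantity — configurable), with
overlaps resolved by nearest-nucleus partition so cytoplasm masks are
pairwise disjoint and exclude all nuclei. A cell is CK20+ iff its
cytoplasmic CK20 mean exceeds 15 and KI67+ iff its nuclear KI67 mean
exceeds 25 (8-bit scale — the cut-off magnitudes only make sense on
0–255 data, so the synthetic generator renders 8-bit channels). The
headline statistic is 100 × |KI67+ ∧ CK20+| / |CK20+|, undefined (an
error) when no cell is CK20+.

**TUNEL.** The TUNEL channel is smoothed (sigma 1 px — whether the
original classifier saw raw or smoothed pixels is unknowable, so the
sigma is an explicit config default), thresholded at mean signal 68.2,
and connected regions are traced to polygons (0.5-level contours),
simplified with Douglas–Peucker at tolerance 1.5 px, re-rasterized and
unioned. The metric is summed area (µm²) per kept DAPI nucleus. Per
region the areas before/after simplification and the perimeter are
recorded; the induced area change is bounded by tolerance × perimeter
(asserted in tests). On convex regions simplification changes area by
< 2%.

## Immunoblot normalization

Fold change = (target/GAPDH) / (target/GAPDH at DMSO) within each
donor × oxygen × target group, on the linear scale; log transforms are
the statistics layer's concern. DMSO rows are exactly 1 by
construction and lane-wise gain changes cancel (scale invariance).
Intensities at or below a configurable floor (default 0) are rejected,
not clipped — a near-zero loading control would otherwise silently
explode the ratio. Paired markers divide the two GAPDH-normalized
signals before the DMSO fold step.

## Panel statistics

**Preprocessing.** Tokens are cleaned by stripping asterisks;
"OOR <" becomes 50% of the analyte's minimum detected value (an
analyte with *only* below-range readings has no minimum and errors);
"OOR >" rows are flagged and excluded rather than imputed, because a
principled substitute for an above-range reading would require the
calibration curve. The detection-range rule — concentrations between
10 pg/mL and the upper limit — is operationalized as: retain an
analyte when its median observed value is ≥ 10 pg/mL (and ≤ the
per-analyte upper limit when known) and at most 10% of its rows are
above-range. The aggregation (median, 10%) is this package's
documented, configurable choice; the underlying rule does not specify
one.

**Mixed model.** Per analyte, natural-log concentration is modeled
with fixed condition, oxygen and interaction effects (treatment coding,
DMSO and 2% O₂ references) and a random per-donor intercept, fitted by
REML (statsmodels MixedLM; verified against lme4's REML estimates to
1e−4 on a simulated panel). Contrast p-values are two-sided t tests of
the Wald statistic on residual degrees of freedom n − p. A
Satterthwaite approximation would be marginally more accurate at small
n, but the fitting backend does not expose the gradient quantities it
needs; for the balanced 6-donor × 12-cell panels this package targets,
the n − p choice keeps the simulated type-I error within [0.03, 0.08]
at α = 0.05 (measured over 500 null panels in the acceptance script).
Boundary fits with zero donor variance — including noise-free data,
where the model degenerates to OLS — are returned flagged `singular`
rather than raised. A Shapiro–Wilk p-value on the residuals is
attached as the normality diagnostic. Raw contrast p-values are pooled
across analytes and Benjamini–Hochberg adjusted (step-up, via the
standard multiple-testing routine; tests pin it to the hand-computed
step-up definition).

**Classical layer.** Paired t (two-sided, df n−1, ≥ 3 complete pairs,
zero-variance differences rejected); repeated-measures one-way ANOVA
from the explicit sum-of-squares decomposition — F = MS_condition /
MS_error with df (k−1), (k−1)(n−1) — so the degenerate no-variation
grid returns F = 0, p = 1 instead of NaN (the general case is
cross-checked against statsmodels AnovaRM to 1e−10); Šídák adjustment
1 − (1−p)^m over the m requested pairwise contrasts; ELISA statistics
on log2-transformed values. Reports list every comparison with
p < 0.2 — inter-donor variability is large in this system, and
near-threshold effects are still worth inspecting — annotated with the
*/***/**** tiers at 0.05/0.001/0.0001.

## Synthetic data: what it does and does not emulate

The generators plant exact ground truth: rasterized object areas
(pixel count × calibration², recorded per object so downstream
recovery is testable without re-reading pixels), exact class counts
via largest-remainder apportionment, and measured post-quantization
channel means. Defaults define the test conditions: wells of 60–120
colonoids (a deliberate ~1/10 scale-down of a full well to keep the
suite fast; the morphometry statistics are density-independent) with
log-normal equivalent diameters (log mean 4.1 ≈ 60 µm, log sd 0.35,
heavy right tail) at 2 µm/px; 10% of objects planted straddling the
border; dark rims (intensity 60) with lighter lumina (170) on a bright
background (220) and Gaussian noise sd 2 — the polarity and contrast
regime the threshold stage expects. H-DAB sections use nuclear
hematoxylin OD 0.7 over faint tissue OD 0.25 with DAB OD 0.5 on
positives, keeping per-channel OD under the 8-bit quantization bound.
Fluorescence sections are 8-bit with nuclei at DAPI 160, KI67 120/5
(positive/negative), perinuclear CK20 rings at 200, TUNEL patches at
150 — all comfortably on the decision side of their cut-offs, so class
recovery tests verify rule wiring and geometry, not detector
sensitivity. Chemokine panels are drawn from the very mixed model the
statistics fit, with donor sd 0.3 and residual sd 0.2 (log scale) and
optional lower-limit censoring to "OOR <".

Deliberately not emulated: photorealistic texture, uneven
illumination, focus artifacts, overlapping/clumped organoids, 3-D
structure, spectral bleed-through, and real detector noise statistics.
Passing recovery tests therefore demonstrates that the measurement
rules and geometry are implemented correctly under controlled
contrast, not that the classical detectors match trained classifiers
on real tissue — the pluggable detector/segmenter interfaces exist
precisely so calibrated replacements can be benchmarked against the
same planted truth.

## Numerical conventions and degenerate inputs

Coordinates are (row, col), 0-based, pixel-center; areas are pixel
counts × calibration². 8-bit conversion uses round-half-even; a
constant image maps to 0 under minmax by convention. Local statistics
use mirror padding. Labeling is 8-connected throughout. Sorting
tie-breaks are by ascending id. Empty inputs that make a statistic
undefined (no particles, no CK20+ cells, no kept nuclei, all-excluded
detections, all-OOR analytes) raise errors; filters that may validly
return nothing (nucleus filters, detection-range filter) return empty
results. All simulation seeds are explicit arguments; fixed seed means
bit-identical output.

## Problem sizes

Test and acceptance runs use: 80–120 colonoids per 768–1024 px well,
200-cell H-DAB sections, 300-cell fluorescence sections, 6-donor
panels, 200 simulation seeds for effect recovery and 500 for type-I
error — sizes chosen so the full suite completes in well under a
minute per stage while keeping Monte-Carlo error small relative to
every asserted tolerance.
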