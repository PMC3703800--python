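# Methods

This note documents the models and procedures implemented in `fundusbench`,
the choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Annotation model and data format

A marking is (lesion type, region, representative points, confidence).
Regions are polygons (≥3 vertices), circles (center, radius) or ellipses
(center, radii rx/ry, orientation in radians, counter-clockwise). Each
marking carries at least one representative point — a cue location, not
spatial coverage — and one of three confidence levels. The numeric
confidence scale is low → 1/3, moderate → 2/3, high → 1; the only hard
requirement on the scale is strict monotonicity, and the evenly spaced
default keeps averages on a small rational grid, which in turn makes the
threshold sweep's candidate set small. Confidence is recorded per marking,
not per representative point.

Coordinates are 0-based with the origin at the top-left pixel corner, x
rightward and y downward. The XML schema (see `ANNOTATION_DTD`) is this
package's own reconstruction of a light-weight annotation interchange
format; it is deliberately minimal and not a clinical messaging standard.
The writer emits a canonical form — fixed element order, numbers printed
with at most 6 decimal places, trailing zeros stripped — so that
`write(parse(write(s)))` is byte-stable and `parse(write(s)) == s` exactly
whenever coordinates are representable with 6 decimals (the generator
quantizes all coordinates accordingly; user-supplied higher-precision
coordinates are quantized on write). Unknown child elements of a marking
are preserved verbatim so third-party dialect extensions survive
round-trips.

## Rasterization

A pixel (row r, column c) belongs to a region iff its center
(c + 0.5, r + 0.5) lies inside: even-odd (crossing-number) rule for
polygons, non-strict `<=` on the normalized radius for circles and
ellipses. No anti-aliasing. These conventions are fixed so that independent
implementations can match the masks bit-exactly. Overlapping markings of
one expert combine by per-pixel maximum — confidence is an ordinal label,
not additive mass. Representative points are excluded from coverage by
default (`include_rep_points=True` renders them as filled circles for
sensitivity analysis). Geometry outside the image is clipped implicitly; a
polygon covering no pixel center yields an empty mask with a logged warning.

## Fusion

Per image and lesion type the N expert confidence images are averaged
pixel-wise; thresholding at τ ∈ (0, 1] gives the consensus mask, and an
image is abnormal iff its mask is non-empty. The comparison is non-strict
(average ≥ τ): with binary full-confidence experts this makes τ = 1 the
exact intersection and the smallest attainable positive average the exact
union, so both stated limits of the construction are attainable. The
original method fixes τ = 0.75 (three of four binary experts survive).

The revised method scores a candidate τ by mutual expert agreement: each
expert's images get summax-1% scores from that expert's own confidence
images, an image-wise ROC is built against the τ-induced labels, and the
per-expert EERs are averaged. Numerical choices:

* **Grid.** The objective only changes when τ crosses an attained average
  value, so the candidate grid is the set of attained positive averages
  plus 1 — an exhaustive sweep of (0, 1] at finite cost.
* **Degenerate candidates.** A τ producing single-class labels has no
  defined ROC; such candidates return NaN and are excluded from the argmin
  rather than being assigned a pseudo-EER, which would reward trivial
  ground truths. If every candidate is degenerate the search fails loudly.
* **Ties.** All candidates within 1e−12 of the minimum are reported as the
  equally performing interval; the reported optimum defaults to the
  interval maximum (the conservative, high-consensus end, which in practice
  distinguishes the otherwise-tied variants). Both endpoints are exposed.

## Evaluation protocols

Image-wise: every unique score is a threshold, classification is
"abnormal iff score ≥ t", and each threshold contributes a
(1 − SP, SN) vertex; the trivial endpoints (0, 0) and (1, 1) are always
present. Construction requires both populations. Pixel-wise: all pixels of
all test images are pooled (positives = truth-mask pixels; every other
pixel, including all pixels of normal images, is a negative), thresholds
are the unique global pixel scores optionally thinned by keeping every
j-th value of the ascending sequence (1-based positions j, 2j, …; j = 1 is
the identity; endpoints are not force-included, a flagged option can
retain the maximum).

EER is the crossing of the piecewise-linear curve with SN = 1 − FPR, by
linear interpolation between the adjacent vertices when no vertex lies on
the diagonal — deterministic and exact in the dense-score limit. WER(R̂) is
defined point-wise as (FPR + R̂·FNR)/(1 + R̂); a curve is summarized by the
minimum over its vertices (a best-operating-point choice; at R̂ = 1 the
point-wise WER at the EER crossing equals the EER). AUC is the trapezoidal
area, equal to the tie-half-credit rank statistic.

## Baseline detector

The photometric baseline estimates p(colour | lesion) with a 3-D RGB
histogram: 32 bins per channel (bin width 8 intensity levels, comparable to
the synthetic noise scale), Gaussian smoothing with σ = 1 bin
(zero-padded borders), normalized to unit mass. Likelihood maps are direct
per-pixel lookups; image scores are summax-1%. Evaluation is rank-based, so
any positive rescaling of the density is immaterial. Illumination
normalization is not applied (a preprocessing hook can be added upstream of
training/scoring); no vessel or optic-disc handling, and no
lesion-specific features — the detector is intentionally a floor, not a
contender. The product fusion rule clips likelihoods at 1e−12 to avoid
zero annihilation.

`run_benchmark` realizes the benchmark's experimental design: 5 random
50/50 train/test splits by default, per lesion type a model trained on the
training images' masks, image-wise EER reported as min/max/avg over the
iterations, and pooled pixel-wise ROC per iteration (score thinning step 25
by default). Split iterations where a lesion type has no positive training
pixels or single-class test labels are skipped and recorded. The split
generator's stream is decorrelated from the scene generator's so a scene
and its benchmark may share a seed.

## Synthetic scenes

Defaults (the generator's study conditions): 48 images of 64×64 RGB,
prevalence 0.5 (exactly half the images abnormal, positions seeded), 1–3
non-overlapping elliptical lesions per abnormal image with radii 4–9 px and
uniformly drawn type, background (120, 70, 40) with i.i.d. Gaussian channel
noise σ = 8, and per-type colour offsets (bright yellow exudates, dark red
microaneurysms/haemorrhages) whose magnitudes are several noise standard
deviations — enough that a colour-only detector is cleanly separable by
construction. Four experts, boundary jitter σ = 1 px, miss probability
0.05, false-marking probability 0.02 per expert-image (a small
low-confidence circle), confidence from lesion salience: effective radius
√(rx·ry) ≥ 7 px → high, ≥ 5.5 → moderate, else low.

A true lesion is the rasterization of the 16-vertex polygon sampling of its
ellipse — the same discretization the experts jitter — so the noiseless
limit (zero jitter/miss/false rates) reproduces the true masks exactly.
Jittered polygons that self-intersect are repaired by convex hull. Lesion
colour is a uniform offset inside the polygon (no radial falloff).

`planted_tau_scenario(n, k)` builds the recovery probe for the threshold
search: images whose central region is marked by exactly k experts at high
confidence (average k/n), decoy images whose region is marked by k−1
experts at moderate confidence (average 2(k−1)/(3n) < k/n), blank images,
and small disjoint low-confidence cues that keep every expert's image
scores informative. By construction every expert's summax scores separate
exactly the labeling induced by τ = k/n and no labeling induced by a
smaller attained threshold, so the search must recover τ* = k/n (at k = 1
the optimum sits at the union end, at k = n at the intersection).

**What passing on synthetic data shows — and does not.** The synthetic
scenes exercise the protocols' correctness (rasterization, fusion limits,
threshold recovery, ROC bookkeeping) under controlled annotator noise. They
are photometrically trivial: no vessels, optic disc, illumination gradients,
camera artifacts, or colour overlap between lesion types and anatomy.
Near-zero EERs and near-unit AUCs here validate the pipeline, not the
baseline's clinical performance; on real fundus photographs the same
baseline is expected to perform far worse, which is precisely its role as a
performance floor.

## Problem sizes

Default test and acceptance runs use 48-image 64×64 scenes, 5 benchmark
iterations, 50–100 recovery replicates and a pixel-score thinning step of
25 — small enough for interactive use while leaving every statistical check
(binomial bounds, recovery rates) well-powered.

## Known limitations

* The XML schema is a reconstruction; files from other annotation tools may
  need a translation shim.
* Fusion assumes a complete image × expert grid per lesion type.
* The colour model operates in raw RGB on 8-bit images; no colour-space
  conversion or illumination correction.
* FROC evaluation, ROC confidence bands, and EM-style consensus estimators
  (e.g. STAPLE) are out of scope.
* Image labels are derived from mask non-emptiness; a single consensus
  pixel makes an image abnormal.
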