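# Methods

`vicmorph` implements the quantitative pipeline used to phenotype aortic
valve interstitial cells (VICs) grown on flat glass versus fibrous
carbon-nanotube-like substrates: single-cell shape morphometry, a
morphology-only phenotype classifier, immunofluorescence quantification,
AFM force-spectroscopy stiffness analysis, and normality-routed statistics.
Because the original specimens are not available, every operator is
validated by parameter recovery: a seeded generator produces inputs whose
ground truth is set to the published measurement values, and the pipeline
must read those values back.

## Shape model and morphometry

A cell footprint is modelled as a smooth star polygon: an ellipse-based
radial profile `r(θ)` with raised-cosine tip bumps, anisotropically scaled
so the minimum-area rotated bounding rectangle hits a target elongation,
then uniformly scaled to a target area and rasterized. The three
parameters — area, elongation, tip count — are independently controllable,
which is what makes recovery testing meaningful. Two rendering regimes
exist: for elongation ≥ 0.56 the shape is a spindle whose two major-axis
ends are always sharpened tips (so a 1-tip request on a strongly elongated
shape renders, and is recorded, as 2 tips); below that it is a star with
equally spaced tips whose bump amplitudes are equalized by the local
ellipse radius so every tip protrudes by about 0.6 of the mean radius
regardless of anisotropy. Very thin spindles that fragment at raster
resolution are bridged by a small closing (largest component kept as a
last resort).

Descriptors:

* **Area** — foreground pixel count × pixel area. Default calibration
  0.65 µm/px (typical 10× camera sampling); every operator takes the pixel
  size explicitly so the default is never load-bearing.
* **Perimeter** — 4-direction Crofton estimator. Naive pixel-edge counting
  overestimates smooth perimeters by up to ~27% and would corrupt the DOC;
  Crofton is accurate to well under 2% at cell-scale rasters (0.2–0.8% on
  discs of radius 25–100 px). The raster tolerance is set to 2%.
* **Degree of circularity** — DOC = 2√(πA)/P ∈ (0, 1], 1 for a circle.
  Values above 1 within estimator tolerance are clipped; larger excesses
  violate the isoperimetric inequality and raise.
* **Elongation** — x = 1 − width/length of the minimum-area rotated
  bounding rectangle of the sub-pixel contour. The rectangle convention is
  fixed deliberately: the alternative ellipse-fit axes give slightly
  different axis ratios, and the classification thresholds are defined on
  x, so x is authoritative. `axis_ratio` = length/width = 1/(1 − x)
  exactly.
* **Cusp count** — local maxima of the radial distance from the centroid
  that are (a) prominent (radial prominence > 15% of mean radius) and
  (b) pointed (Menger circumradius at the tip over a ±3%-of-contour window
  below 45% of mean radius). The curvature gate mirrors how a human counts
  tips rather than bulges: the blunt far end of a mildly elongated blob is
  rejected, the sharp ends of a true spindle count (a spindle has 2 cusps,
  a drop 1, a triangle 3, a disc 0). The operator replaces a manual count
  and is validated only against generator ground truth (k-tip stars,
  k = 1..8, ≥95% exact recovery) and the calibration shapes.

## Phenotype classification

Cells are classified on elongation alone into myofibroblast-like
(myFib, low x), fibroblast-like (Fib, intermediate) and smooth-muscle-like
(SMc, high x); the published decision intervals are 0.551 and 0.817. The
classifier is a 1-D, 3-class k-medoids model solved *exactly*: in one
dimension the L1-optimal clusters are contiguous in sorted order, so
dynamic programming over contiguous 3-splits finds the global optimum, and
the usual PAM restart stochasticity disappears. Decision boundaries are
midpoints between the extreme members of adjacent clusters; classes are
relabelled by ascending medoid.

A consequence of k-medoids geometry worth stating: the optimal cut between
two clusters sits at the midpoint of their medoids. Reproducing the
published boundaries therefore constrains the population, not the
algorithm — the class-conditional elongation distributions must be centred
so that adjacent medoid midpoints land at 0.551/0.817. The generator's
default bands (myFib 0.25–0.55, Fib 0.57–0.81, SMc 0.85–0.97, each drawn
Beta(3,3)-scaled within the band) satisfy this self-consistently while
staying inside the published intervals. Note the published axis-ratio
bands (myFib 1–1.5, Fib 1.5–3, SMc > 3) are mutually inconsistent with the
printed x-thresholds under the bounding-rectangle identity (ratio 3 ⇒
x = 0.667, not 0.817); the x-thresholds are implemented as authoritative.

Soft membership is a softmax over negative scaled distances to the three
medoids. The scale defaults to the pooled within-class median absolute
deviation from the assigned medoid — a fully specified, data-driven stand-in
for the original software's proprietary membership model — and is exposed
in the estimator's parameters. Cells whose top membership is not above
0.90 are flagged excluded; on study-condition populations this excludes
1–3% of cells. Accuracy against reference labels is the agreement
fraction with a seeded 1000-resample bootstrap SD.

## Immunofluorescence quantification

All ratio metrics are built from robust, affine-invariant thresholds, so
rescaling a channel's gain or offset never changes a result.

* **Cell density** — nuclei per mm²: Gaussian smoothing (σ = 1.5 µm),
  median + 5·MAD threshold, distance-transform watershed to split touching
  pairs. Against generator centroids the detector scores F1 ≈ 0.99 at the
  dense 72-h condition (matching radius 7.5 µm, half the hard-core
  separation, so matches are unambiguous).
* **Focal-adhesion density** — vinculin-positive area / cell area. The
  cytosolic background is the in-mask median (adhesions are sparse, so the
  median is cytosol); positive pixels exceed median + 3·(1.4826·MAD),
  then a disk(1) binary opening and a 3-px minimum size suppress shot
  noise. The opening removes puncta rims and biases recovery low by
  ~0.005 at a true fraction of 0.073 — inside the acceptance tolerance and
  accepted as the price of the documented noise suppression.
* **α-SMA/actin surface ratio** — (marker⁺ ∩ actin⁺)/actin⁺ with both
  channels thresholded identically at background (out-of-mask median) +
  25% of the channel's dynamic range. A median-based rule cannot work
  here: the colocalized fractions of interest are 0.58–0.83, i.e. the
  in-mask median *is* signal. No opening is applied — the marker forms
  thin filament networks whose skeletons an opening erodes (up to −0.09
  on small spindle cells); the minimum-size filter alone handles specks.
  Identical channels give a ratio of exactly 1 by construction.
* **Stress-fiber density** — fiber area / actin-positive area. Candidate
  bright bundles come from the robust in-mask rule; connected components
  are kept only if their mean multiscale Sato ridge response (scales
  0.3–1.5 µm) exceeds 15% of the in-mask maximum, so a fiber-free uniform
  actin cell scores ~0. The operator is unspecified in the original
  analysis and is validated purely against painted-filament ground truth
  (monotone, approximately linear over fractions 0.05–0.30).

The marker generator paints punctae (FA-sized ellipses, centres kept off
the mask rim), straight thick filaments, or colocalized structures, and
then trims the final structure pixel-by-pixel so the painted count equals
round(fraction × mask area) **exactly** — the painted-pixel set is the
recovery oracle. Default contamination: cytosolic background at 20% of
signal, Gaussian noise at 5% of signal.

## AFM force spectroscopy

Units are chosen so no conversion constant appears: with E in kPa
(≡ nN/µm²), R in µm and δ in µm, the spherical-indenter Hertz law is
F = (4/3)·E/(1−ν²)·√R·δ^{3/2} in nN. Defaults: bead radius 4.0 µm
(8 µm-diameter glass bead; per-curve override supported since beads are
individually measured), ν = 0.5 (incompressible cell), fit window capped
at the 250 nm indentation trigger, spring constant an input (thermal
calibration is the instrument's job). Indentation uses the soft-sample
convention δ = (z − z0) − d with the pre-contact deflection offset
removed.

The forward generator solves δ + F(δ)/k = z − z0 by Newton iteration so
the piezo ramp splits physically between indentation and deflection, adds
Gaussian noise on force only (deflection noise dominates real
instruments; adhesion/hysteresis are not modelled), and triggers exactly
at 250 nm.

Contact-point estimation is a two-stage search: an exhaustive change-point
scan (flat baseline + Hertz rise, global RSS minimum over every sample
index) followed by a joint (E, z0) least-squares fit of the forward
deflection model. The second stage matters statistically: fitting after
converting to indentation feeds deflection noise into δ itself, an
errors-in-variables effect that biases z0 early by about one sample
spacing; the deflection-space fit is unbiased. At 2% force noise the
estimator localizes z0 within 3 sample spacings in ≥95% of curves. At 5%
noise the force signal sits below the noise floor for the first ~34 nm of
contact and the information limit caps sd(z0) near 3 nm, so the attainable
95% bound there is ~6 spacings — a limit of the physics, not the
implementation.

The modulus fit is a linear regression of F on δ^{3/2} through the origin
inside the window; E = (3/4)·s·(1−ν²)/√R. Noiseless round-trips recover E
to better than 10⁻⁶ relative across E ∈ [0.5, 50] kPa, R ∈ [2, 6] µm.
Because fixation alters absolute cell stiffness, recovery targets are the
generator's ground-truth moduli, set to the published per-class values.

Line roughness R_rms is the RMS deviation from the least-squares linear
mean line (tilt-levelled, per the standard surface-texture convention);
profile generators rescale their output so the measured R_rms equals the
requested target exactly.

## Statistics

Two-sample comparisons are routed by Shapiro–Wilk on each group (capped at
n = 5000 by seeded subsampling): both normal → Welch t-test (unequal
variances are the safe default; the choice is not specified upstream),
otherwise Mann–Whitney U. Constant samples route to Mann–Whitney with a
warning. Summaries follow the plotting convention: mean ± SD when normal,
median/quartiles with 5th–95th whiskers otherwise. The factorial
3 morphologies × 2 substrates design uses a two-way type-II ANOVA
(unbalanced cells) with Bonferroni-adjusted pairwise t post-tests
(adjusted p = min(1, m·p)). Stars: * p < 0.05, ** p < 0.01, *** p < 0.001,
strict inequalities. Empirical type-I error of the routed procedure stays
≤ 0.07 at nominal 0.05 over 1000 seeded Gaussian and lognormal nulls.

## Synthetic study conditions

The two pipeline presets encode the published per-class measurements as
generator ground truth: compositions 22/28/50 (glass) vs 44/46/10 (CNT)
percent for SMc/Fib/myFib; areas 230 ± 102, 480 ± 194, 998 ± 408 µm²
(myFib 757 ± 326 on CNT); moduli 1.4/1.6/5.5 kPa on glass, 2.8/4.2/5.7 on
CNT; FA fractions 0.024/0.020/0.030 vs 0.038/0.067/0.073; fiber fractions
0.16/0.15/0.21 vs 0.15/0.16/0.17; colocalization 0.83 vs 0.58; 72-h
densities 773 vs 775 /mm². Nuclei fields are sequential-inhibition Poisson
(hard core 15 µm, sampled in a 10 µm-extended domain so field-edge clipping
is unbiased, realized counts recorded); area draws are truncated at 50 µm²
to avoid degenerate rasters; the field area (0.15 mm²) and pixel size are
free configuration because the source does not report them.

What the generators do **not** emulate: optics (no PSF, no illumination
field, no photobleaching), cell-cell contact and overlap, segmentation
errors (masks are inputs by contract), marker intensity heterogeneity
within structures, AFM adhesion/viscoelasticity, and any temporal
dynamics. Passing recovery tests therefore demonstrates the correctness of
the measurement operators and the statistical machinery on clean,
well-calibrated inputs — not robustness to the full messiness of real
micrographs.

## Problem sizes

Recovery runs use the published sample sizes where the source states them
(147/132 force curves, 125 fields, 999 areas, 136/294/234 marker cells,
404 cusp counts, ~2500-cell classifier populations); unit and property
tests use smaller populations (10–60 draws) chosen to keep each assertion
comfortably inside its tolerance at interactive runtimes.
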