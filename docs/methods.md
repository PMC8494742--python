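# Methods

This note documents the models, conventions and design choices behind
`octaquant`, in the order data flows through the pipeline.

## Imaging geometry and conventions

All rasters live on a square grid with a physical pixel pitch; the default
is a fovea-centered 6 × 6 mm en-face scan at 600 × 600 px, i.e. 10 µm/px.
Angiograms are 16-bit (full scale 65535). Coordinates are 0-based,
row-major, origin top-left; the continuous position of pixel (i, j) is
(x, y) = (j + 0.5, i + 0.5), and the same pixel-center convention is used by
the control-point files and the resampler, so there is no half-pixel drift
between registration and warping. Connectivity is 8-neighbour everywhere a
connectivity choice matters (components, plateaus, fill).

## Colormap codec

Device software exports retinal-thickness and vessel-density maps as 24-bit
color rasters; quantification needs scalars. The codec is built around an
explicit LUT: ordered (scalar, RGB) control points, piecewise-linear in RGB
between them, strictly increasing in scalar, with an injectivity check on
the interpolated path. Since vendor conversion tables are proprietary, a
documented rainbow-style default is shipped (blue→cyan→green→yellow→red over
0–500 µm for thickness and 0–100 % for VD) and any LUT can be supplied as
`scalar,R,G,B` CSV — the pipeline's science is LUT-agnostic, and correctness
is defined by the round-trip contract rather than by any particular palette.

Decoding inverts the LUT by exhaustive nearest-neighbour search over a
densely sampled path (4096 samples, Euclidean RGB distance, ties toward the
lower scalar). Pixels farther than 8 RGB units from the path are marked
invalid in a companion mask; more than 5 % invalid pixels aborts with the
worst offending colors named. The codec's resolution constant is

    quantization_step = span / L1-path-length + span / (n_samples − 1)

(the scalar advance per 8-bit RGB unit plus the decode grid spacing). This
is the bound guaranteed for both the encode/decode round trip and for a ±1
perturbation of any single channel.

## Congestion detection

Congestion is defined photometrically and geometrically: expanded, bright,
coarse capillary networks between the affected and normal vasculature. The
detector makes those three adjectives operational on the gamma-corrected
image (γ = 3.0 by default, `out = FS·(in/FS)^(1/γ)` — monotone and
endpoint-preserving; brightness can optionally be judged on the raw image):

- *vessels*: gamma-corrected pixels ≥ `vessel_threshold` (default 24000),
  speckle components under 10 px removed;
- *caliber* at each skeleton point: `2·EDT − 1` px, where EDT is the
  Euclidean distance to the nearest background pixel. The −1 corrects the
  half-pixel overshoot on each side of center-to-center distances: a 5-px
  ribbon reads ≈ 5 px, a 1-px line ≈ 1 px, a disc of radius r peaks ≈ 2r.
  With this estimator, "diameter exceeding two pixels" (strict, > 2.0 on the
  continuous estimate) separates widths ≤ 2 px from widths ≥ 3 px;
- *component rules* (8-connected components of the vessel mask): expanded =
  any skeleton caliber > 2 px; bright = component median ≥ 32768 (50 % of
  full scale; the median is robust to skeleton artifacts, a mean variant is
  available); coarse = within-component caliber range > 2 px;
- *combination*: `bright AND (expanded OR coarse)` by default. A strict
  conjunction of all three would reject uniformly dilated bright collaterals
  that clearly belong to the phenotype; pure disjunction would admit every
  dim dilated vessel. Both alternatives remain available via `rule_mode`;
- *location*: a qualifying component must intersect the band within
  `boundary_band_px` (default 20 px = 200 µm) of the abnormal/normal
  interface — congestion bridges the two — and FAZ pixels are always
  excluded. Components are returned as hole-filled footprints.

The detector complements, not replaces, manual segmentation: externally
drawn masks round-trip losslessly through the same 8-bit raster format
(any nonzero pixel reads TRUE).

## Region system and morphometry

Per plexus, {A (abnormal), N (normal), FAZ} partitions the frame with
N = ¬(A ∪ FAZ); if an input A overlaps the FAZ, FAZ wins and the repair is
flagged. TZ = SCP-N ⊙ DCP-A. DCP-C is partitioned into DCP-C∩TZ,
DCP-C∩SCP-A, and an explicit residual class: the region definitions imply
the residual is empty whenever DCP-C ⊆ DCP-A, so a nonzero residual
fraction is a detectable inconsistency in the inputs rather than a silent
assumption.

Morphometry over a mask: area = pixel count · pitch², percent of frame,
mean VD (from the decoded VD map — matching the practice of reading VD from
the device map, not recomputing a binary vessel fraction; a recomputed
variant exists for phantoms), mean retinal thickness. Empty masks yield
flagged NaNs, never numbers. Total-frame rows include the FAZ — a
documented choice, since whether published "total" VD values excluded the
FAZ is ambiguous. Invalid-decode pixels are excluded from means and counted.

## Registration and RIRT

The baseline↔recurrence alignment is a 3 × 3 homogeneous affine solved in
least squares from ≥ 3 non-collinear control-point pairs (typically 16
vessel bifurcations); the fit interpolates exactly at 3 points and reports
the RMS point residual (no outlier rejection is performed — a configurable
residual ceiling warns instead). Warping is inverse mapping with bilinear
interpolation (hole-free), nearest-neighbour for label maps; target pixels
whose pull-back leaves the source raster are invalid in the overlap mask.

RIRT = follow-up / baseline thickness per overlap pixel (zero-baseline
pixels excluded and flagged, > 10 % of them is an error). Two threshold
semantics coexist deliberately, each implemented literally in its role:

- the ME **territory** is the *strict* superlevel set {RIRT > 1.1}
  ("more than a 10 % increase"), contoured by marching squares at 1.1;
- eye-level **recurrence** is *inclusive*: CSMT ≥ 1.10 × baseline
  ("increased by 10 % or more"); a 1e-9 relative epsilon absorbs binary
  floating point exactly at the boundary (1.1·300 > 330 in float64). The
  clinical qualifier "due to fluids" is a judgment call and not modeled.

Apexes are local maxima of a Gaussian-smoothed copy of RIRT (σ = 2 px by
default, recorded in the output; the smoothing behind published contour
plots is not documented, so σ is exposed) inside the territory, one per
flat plateau at its first raster pixel, ranked by value with raster-order
tie-breaking, and labeled FAZ / NPA / other by the mask containing them.

## Phantom generator

The phantom emulates the study conditions with closed-form ground truth:

- **geometry**: central FAZ discs (SCP radius 370 µm ≈ 0.43 mm², DCP scale
  1.22 ≈ 0.64 mm²); a nonperfusion sector (default orientation 30°, width
  80° superficial / 110° deep). Both abnormal sectors exclude the larger
  deep FAZ disc, making DCP-A ⊃ SCP-A strictly — the containment reported
  in every studied eye — and leaving a nonempty TZ;
- **vessels**: seeded random branching walks rasterized at 1–2 px caliber in
  the normal regions; no hemodynamics, speckle or point-spread physics —
  the detector criteria are purely geometric/photometric, so that is what
  the phantom controls;
- **congestion corridor**: wiggly polylines hugging the deep sector's edge
  rays just inside DCP-A (≥ 2 px clear of the boundary so the corridor
  forms its own connected components), stamped segment-wise with calibers
  spanning the full 3–6 px range (so both the expanded and coarse criteria
  hold by construction) at ≥ 60 % of full scale brightness. Normal-vessel
  signal is set to 0.10 of full scale so its gamma-corrected level (≈ 46 %)
  stays below the 50 % bright criterion — brightness is the discriminating
  feature of the phenotype, and the phantom realizes that contrast.
  Superficial congestion is off by default (optional flag), mirroring deep
  congestion in all eyes vs superficial in most;
- **thickness**: baseline 250 µm plus a smooth Gaussian-filtered texture
  (σ = 40 px, 8 µm RMS); the follow-up field multiplies the baseline by a
  raised-cosine edema blob, ratio(r) = 1 + (peak−1)(1+cos(πr/R))/2, whose
  {ratio > 1.1} superlevel set has a closed-form radius — the oracle for
  every territory test. The follow-up map is observed under a configurable
  affine eye motion (default: 1.5° rotation, 1.01 scale, (4, −3) px
  translation about the frame center); control points are exact
  pre-images of random baseline points, so noise-free registration must
  recover the motion matrix to numerical precision;
- **VD maps**: piecewise-constant by region (normal 45 %, abnormal 40 %,
  FAZ 15 %, congestion 52 % deep / 56 % superficial), smoothed and
  noise-dressed;
- no aneurysmal-dilatation phenotype is simulated: no quantitative
  definition exists to implement, so the phantom omits it rather than
  inventing one.

All randomness flows through one `numpy.random.Generator`; identical seeds
give bit-identical cases. What passing on phantoms does **not** show:
robustness to projection artifacts, segmentation-plane errors, speckle,
motion artifacts, or media opacity of real OCTA — the phantoms validate the
algebra, the rules and the numerics, not clinical-grade robustness.

## Cohort simulator and statistics

Per-eye cohorts are drawn with recurrence following
logit p = β₀ + β_mrt·MRT(DCP-C) + β_inj·N(injections). Defaults encode the
reported multivariate odds ratios (β_mrt = ln 1.044, β_inj = ln 1.803), the
observed covariate spreads (MRT ~ N(264.8, 30.2) µm; injections ~ negative
binomial with mean 3.4 and variance ≈ 3.2²), n = 76 eyes, and β₀ = −14.8,
set so the *marginal* recurrence rate is the observed 28.9 % (setting the
intercept at the covariate means would overshoot to ≈ 35 % because the
right-skewed injection counts dominate the expectation of the logistic).
Nuisance covariates (age, sex, acuity, CSMT, treatment history) are drawn
from cohort-shaped distributions but carry no effect.

The statistical layer wraps standard routines with the study's usage:
Mann-Whitney U (exact enumeration when both n ≤ 10 without ties, otherwise
tie-corrected normal approximation), Wilcoxon signed-rank, Pearson
chi-squared (warning below expected counts of 5, echoing the Fisher
fallback), Fisher exact on 2 × 2, Spearman mid-rank correlation. All
p-values are two-sided; no multiplicity correction by default (a Holm
adjuster is provided, off by default). Logistic models are maximum
likelihood with Wald 95 % CIs (exp(β ± 1.96·SE)); non-convergence and
suspected separation are flagged on the result. The multivariate model
takes terms passing univariate screening at p < 0.05 — an explicit, logged,
overridable rule (published reports rarely state their stepwise rule; this
package states its own) — with the injection subtotal terms folded into the
total count to avoid exact collinearity. OR derivations: percent odds
increase per unit = (OR−1)·100; doubling increment = smallest integer k
with ORᵏ ≥ 2 (errors for OR ≤ 1, where no doubling exists).

## Problem sizes and numerical choices

Tests and the acceptance script run phantoms at the full 600 × 600 study
geometry where the check is about the imaging pipeline (detector IoU over
ten seeds, territory vs analytic level set), and scaled-down 300 × 300
phantoms where only the wiring is under test. Logistic parameter recovery
uses n = 5000 simulated eyes (SE of the MRT log-OR ≈ 0.005, comfortably
inside the [1.02, 1.07] recovery band); type-I calibration uses 100
replicates of n = 200. Territory agreement is asserted outside a 1-px
boundary band, absorbing marching-squares/interpolation discretization.
Affine fits use `numpy.linalg.lstsq`; collinearity is tested on the second
singular value of the centered source cloud (tolerance 1e-8 relative).

## Known limitations

- The detector's component granularity means a congested segment fused with
  a large normal network into one 8-connected component is judged as a
  whole; real images may need the manual-mask path.
- The codec assumes clean full-frame maps; burned-in legends or scale bars
  would decode as invalid pixels (and trip the 5 % error on purpose).
- No B-scan (volumetric) synthesis or fluid segmentation: CSMT values are
  taken as given numbers, and RIRT is a purely 2-D en-face statistic.
- Phantom cohort covariances are diagonal (no age-injection correlation
  etc.); the simulator validates estimator calibration, not epidemiology.
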