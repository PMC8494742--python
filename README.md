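# octaquant

Quantitative analysis of capillary congestion on en-face OCT angiography
(OCTA) in chronic branch retinal vein occlusion (BRVO), and its relation to
macular edema (ME) recurrence.

After a branch vein occlusion, the deep capillary plexus (DCP) often
develops *capillary congestion* (DCP-C): expanded, bright, coarse capillary
networks bridging the nonperfused and normal vasculature. This package is a
reading-center-style toolkit for ophthalmic image analysts who want to
quantify that phenotype and relate it to edema recurrence:

- **Colormap codec** — convert device-exported 24-bit color thickness /
  vessel-density maps to physical scalar grids through an explicit LUT
  (`scalar,R,G,B` CSV), with a round-trip guarantee of one quantization step.
- **Congestion detector** — the pixel rules operationalized: after gamma
  correction (γ = 3.0), a vessel component is congestion when it is *bright*
  (median gray level ≥ 50 % of 16-bit full scale, i.e. ≥ 32768), and
  *expanded* (caliber > 2 px at 10 µm/px) or *coarse* (within-component
  caliber fluctuation > 2 px), and lies at the abnormal/normal boundary.
  Manually drawn masks are equally supported (8-bit PNG, 0/255).
- **Mask algebra** — the named region system: normal region
  N = ¬(A ∪ FAZ) per plexus, transitional zone TZ = SCP-N ⊙ DCP-A
  (Hadamard product), and the partition of DCP-C into its TZ part and its
  part under SCP-A.
- **Region morphometry** — area (mm², % of the 6 × 6 mm frame), mean vessel
  density (VD, %), mean retinal thickness (MRT, µm) over any region.
- **Registration + RIRT** — least-squares 3 × 3 affine from vessel-bifurcation
  control points, inverse-mapped bilinear warping, and the per-pixel ratio of
  increased retinal thickness RIRT = follow-up / baseline thickness. The ME
  territory is the strict superlevel set {RIRT > 1.1}; apexes (local maxima)
  are localized and labeled FAZ / NPA / other. Eye-level recurrence uses the
  inclusive rule CSMT(follow-up) ≥ 1.10 · CSMT(baseline).
- **Cohort statistics** — Mann-Whitney U / Wilcoxon / chi-squared / Fisher
  comparisons, Spearman correlation, uni- and multivariate logistic
  regression with Wald 95 % CIs, and odds-ratio derivations: an OR of
  1.044 per µm of DCP-C MRT means +4.4 % odds per µm, and 17 µm doubles
  the odds (smallest k with ORᵏ ≥ 2).
- **Phantom generator** — clinical OCTA of this kind is rarely shareable, so
  the package ships a synthetic module generating 600 × 600, 10 µm/px
  phantoms with full ground truth (region masks, vessel rasters, true eye
  motion, closed-form edema territory) plus cohort simulation with a known
  logistic recurrence model.

## Worked example

```python
import octaquant as oq

case = oq.generate_phantom_case(oq.PhantomConfig(seed=1))
truth = case.truth.masks

det = oq.detect_congestion(case.dcp, truth["DCP-A"], truth["DCP-FAZ"])
gt = truth["DCP-C"].pixels
print("detected DCP-C pixels:", det.count())
print("IoU vs ground truth:  ",
      round((det.pixels & gt).sum() / (det.pixels | gt).sum(), 3))
area_mm2, area_pct = oq.region_area(det)
print("DCP-C area:           ", round(area_mm2, 3), "mm^2")
mrt, _ = oq.mean_over_mask(case.thickness_baseline, det)
print("DCP-C MRT:            ", round(mrt, 1), "um")

t = oq.fit_affine(case.control_points)
warped, overlap = oq.warp_map(case.thickness_followup, t)
res = oq.analyze_rirt(case.thickness_baseline, warped, dcp_c=det,
                      faz=truth["DCP-FAZ"], abnormal=truth["DCP-A"],
                      overlap=overlap)
s = res.summary
print("mean/max RIRT, ME territory:", round(s.mean_territory, 3), "/",
      round(s.max_territory, 3))
print("mean/max RIRT, DCP-C:       ", round(s.mean_dcp_c, 3), "/",
      round(s.max_dcp_c, 3))
print("apex:", res.apexes[0].label, "at", (res.apexes[0].row, res.apexes[0].col))
```

prints

```
detected DCP-C pixels: 2043
IoU vs ground truth:   1.0
DCP-C area:            0.204 mm^2
DCP-C MRT:             246.5 um
mean/max RIRT, ME territory: 1.267 / 1.5
mean/max RIRT, DCP-C:        1.049 / 1.358
apex: FAZ at (299, 300)
```

The detector recovers the phantom's congestion corridor exactly (IoU 1.0);
the registered follow-up thickness map yields an edema territory whose mean
and maximum RIRT exceed those over DCP-C — the edema peaks at the fovea
(apex labeled FAZ) while the congestion corridor sits at its margin, the
spatial pattern the quantities are designed to capture.

The same flow is available from a shell:

```sh
octaquant run-all --seed 1 --out run1/
octaquant cohort --simulate --n-eyes 76 --seed 1 --out cohort1/
```

## Layout

```
src/octaquant/
  images.py        raster containers + lossless PNG I/O, coordinate conventions
  colormap.py      LUT codec for color-coded thickness / VD maps
  segmentation.py  gamma correction, vessel extraction, calibers, detector
  masks.py         region-system algebra (N, TZ, DCP-C partition)
  metrics.py       area / VD / MRT morphometry and the per-eye table
  registration.py  control-point affine fit and map warping
  rirt.py          RIRT map, ME territory, apexes, recurrence rule
  stats.py         group comparisons, Spearman, logistic model, OR arithmetic
  synthetic.py     phantom generator and cohort simulator
  pipeline.py      end-to-end case and cohort runs with traceable reports
  cli.py           click CLI (phantom, decode, segment, metrics, rirt,
                   cohort, run-all)
```

See `docs/methods.md` for the model, parameter and design documentation.
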