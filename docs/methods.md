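# Methods

## Segmentation model

The core assumption is that the three tissue types of the anterior tongue
surface — fungiform papillae (FP), filiform papillae and base tissue —
occupy distinct, roughly unimodal regions of CIELAB colour space, and that
a pixel's tissue class is therefore recoverable as the nearest of three
learned mean colours under Euclidean distance. CIELAB is used because it
is approximately perceptually uniform, so Euclidean distance tracks
perceived colour difference and the classification is less sensitive to
moderate illumination changes than RGB distance would be.

Input images are 8-bit sRGB (consumer-camera default); conversion uses the
D65 reference white. Colour markers are unweighted means over all pooled
ROI pixels of a class; pooling several ROIs per class is encouraged because
FP shade varies across the tongue (the tip tends to be pinker). Distance
includes the L\* channel by default; an `channels="ab"` switch drops
lightness for stronger illumination invariance. Ties between markers are
broken by the fixed class order fungiform < filiform < base < background,
which makes the label map deterministic and independent of marker input
order.

The three tissue classes tile only tongue tissue, but real crops contain
lips, teeth and shadow. A fourth *background* class absorbs these pixels,
supplied either as a binary tongue mask or as a fourth trained marker; the
"whole tongue area" used in the density denominator is then exactly the
union of the three tissue classes.

Colour shade drift across the tongue is handled by rectangular
re-analysis: a sub-rectangle is re-classified with markers learned from
ROIs inside it, and merged back into the global label map at pixel level
(pixels outside the rectangle are bit-identical to the initial analysis).
Connected components are extracted *after* merging, so a papilla
straddling the rectangle edge is counted once. A tongue class without a
local ROI falls back to its global marker (logged).

## Papilla quantification

Each connected component of fungiform pixels is one papilla
(8-connectivity by default — anti-aliased blob edges fragment less;
4-connectivity available). Components below `min_area_mm2` (default
0.01 mm², ≈ 0.11 mm equivalent diameter, well below any plausible FP) are
discarded as colour noise. No morphological opening/closing is applied by
default, and touching papillae are *not* split by watershed or shape
priors — interconnected papillae are meant to be resolved by regional
re-analysis, and automatic splitting is a declared non-goal.

Per papilla: pixel area, physical area (area_px · mm_per_px²), centroid
(unweighted pixel mean), outer contour, and the circular-equivalent
diameter 2·√(A/π). The diameter assumes circular shape and ignores
roundness — a known limitation of this estimate.

Density = Σ area of *retained* (post-filter) papillae / tongue pixel
count. Using filtered pixels keeps the numerator consistent with the
count; the unfiltered alternative would differ only by the removed noise
specks.

The 6-mm counting circle is placed automatically: wholly inside the
tongue mask (with a one-pixel discretisation margin), right edge tangent
to the midline, at minimal distance from the tip; an explicit centre
overrides this. Circle membership is by centroid (boundary-inclusive),
matching manual "count the papillae in the ring" practice and keeping
counts additive over disjoint regions.

## Analysis geometry

Pixel coordinates are 0-based, (x = column, y = row), origin top-left;
the tongue tip is at the image bottom by default (configurable). The tip
row is the extreme mask row in the protrusion direction; the midline is
the vertical line through the tongue-mask column centroid (adequate for
the standardised upright captures the method assumes), overridable for
curved protrusions. Bands are half-open intervals of distance from the
tip measured along image rows: Band 1 = [0, 10) mm, Band 2 = [10, 20) mm;
a centroid exactly at 10 mm falls in Band 2. Papillae beyond 20 mm are
flagged and excluded from all counts.

The 16-grid layout is one consistent reading of an 8-grids-per-side
partition: within each (side, band), 4 equal-width vertical strips between
the midline and that band's lateral mask extreme, numbered from the
midline outward — grids 1–4 in Band 1, 5–8 in Band 2. The construction is
isolated behind `TongueGeometry` so an alternative layout can be
substituted. A centroid exactly on the midline counts as LEFT
(deterministic boundary rule). Distance from the tip is measured along
rows, not along the curved tongue surface.

These rules give exact conservation (side, band and grid counts each sum
to the total — asserted on every summary) and exact left-right mirror
symmetry (mirroring the image swaps L/R grid counts) up to
floating-point ties sitting exactly on a partition boundary.

## Synthetic tongue generator

The generator emulates the statistical structure the method assumes, not
photorealism: a semi-elliptical tongue (default 40 mm wide, tip dome 15 mm
deep, 0.05 mm/px, tip at the image bottom) filled with light-pink base
tissue (sRGB 232,158,158), short threadlike filiform segments
(236,226,214) covering ~20 % of the surface, darker-pink FP disks
(198,88,108), a ±6 % multiplicative linear illumination ramp across the
frame, and additive Gaussian sensor noise (default σ = 2 RGB units).

Defaults are the study conditions the method targets: 204 papillae per
tongue with 70 % planted in the first centimetre (the observed band
gradient on real tongues, where Band 1 carries roughly 148 of ~204 FP),
and totals in the realistic 53–396 range are supported. Papilla radii are
drawn uniformly from 0.15–0.4 mm (0.3–0.8 mm diameters). Real FP
diameters up to ~1 mm occur; the slightly conservative upper bound keeps
non-overlapping placement feasible at the top of the count range, where
the first centimetre becomes genuinely crowded.

Placement is band-stratified rejection sampling (the Band-1 share is a
binomial draw), largest disks first, with three safety margins chosen so
the planted truth is *exactly* recoverable at zero noise: disks stay ≥ 1 px
inside the mask, disk boundaries stay ≥ 3 px apart (no spurious
8-connected merges), and centres stay ≥ 1.5 px away from the midline, band
edges and grid-strip edges (so sub-pixel centroid error cannot flip a bin
assignment). If the requested count cannot be placed, a capacity error
reports how many disks fitted.

Disks are rendered hard-edged (pixel-centre membership), which keeps the
rendered image bit-consistent with the truth class map; an `anti_alias`
option exists for robustness experiments but is off by default because
blended edge pixels have no unambiguous true class. All randomness flows
from a single seed; generation is bit-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: specular glare, motion blur, tongue-surface
curvature and folds, colour-class overlap between FP and base tissue
(real tongues can have weak contrast, especially posteriorly), truly
interconnected papillae, and dye staining. On synthetic images the colour
classes are well separated, so detection is essentially perfect even at
σ = 4; real images are harder, which is precisely why the regional
re-analysis and QC overlay exist.

## Validation statistics

* **Bland-Altman**: d = x − y; mean difference, sample SD (n−1), limits of
  agreement mean ± 1.96 SD. A "Bland-Altman test" is reported as the
  conventional one-sample t-test of zero mean difference, clearly labelled
  as such.
* **ICC**: two-way random effects, absolute agreement, from the two-way
  ANOVA mean squares; both single-measures ICC(2,1) and average-measures
  ICC(2,k) are returned, since reliability judgements are often quoted on
  the average-measures form.
* **Spearman**: Pearson correlation of mid-ranks (average ranks on ties);
  p-value from the t approximation with n−2 df, adequate at the n ≈ 60
  scale such studies use; an exact permutation option exists for n ≤ 10
  (factorial cost).
* **Stepwise regression**: forward selection only (no removal), entering
  at each step the predictor with the largest R² gain if its partial-F
  p-value is below 0.05; exact ties break by column order. The R² path is
  non-decreasing by construction; with the entry threshold at 1 the path
  reaches the full-model R².

## Numerical choices and degenerate inputs

* sRGB↔CIELAB via the standard D65 chain; L\* ∈ [0, 100] up to float
  round-off.
* Classification uses strict `<` against the running best distance with
  markers pre-sorted by class priority — ties resolve to the
  higher-priority class without an explicit epsilon.
* Empty fungiform class → empty papilla list (not an error); empty tongue
  mask, all-constant ratings matrix, constant rank vectors and
  non-positive areas raise explicit `ValueError`s.
* MSE in the ICC is clamped at zero against tiny negative round-off in the
  sum-of-squares decomposition.
* Stepwise treats an R² gain below 1e−12 of the total SS as "no gain"
  (prevents entering predictors after a perfect fit).

## Problem sizes used in the validation scripts

The test suite validates mostly on a reduced tongue (250×320 px at
0.1 mm/px, 40 papillae) and on 20 full-size tongues for the end-to-end
recovery and noise-robustness checks; `scripts/acceptance.py` uses 10
full-size tongues each for the zero-noise and σ = 4 conditions, and 20
tongues × 3 noise realisations for the agreement statistics. These sizes
give exact checks (recovery, conservation, determinism) and stable
stochastic ones (recall/precision, Spearman, ICC) while keeping a full run
in the tens of seconds.

## Known limitations

* Requires manual ROI selection per image; no automatic tongue detection
  or white-balance/colour-constancy correction.
* Not applicable to dye-stained (blue) tongue images — the colour contrast
  the method relies on is destroyed by staining.
* Equivalent diameter assumes circular papillae; no shape or roundness
  scoring.
* No splitting of merged/touching papillae.
* No pose normalisation or unwarping; band distances are image-plane
  distances, which understate surface distance on a strongly curved tip.
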