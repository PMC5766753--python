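# fpquant

Automated detection, counting, sizing and spatial mapping of **fungiform
papillae (FP)** on high-resolution colour photographs of the anterior 2 cm
of an unstained human tongue — plus the method-agreement statistics used to
validate an automated count against a manual reference, and a seeded
synthetic tongue generator so that every stage of the pipeline can be
validated against exact ground truth without any real image data.

FP are the pink, mushroom-shaped structures on the anterior tongue that
house taste buds; their number and spatial distribution are widely used
measures in sensory science (e.g. in studies of PROP taster status).
Manual FP counting on a dyed tongue is slow and subjective; `fpquant`
implements a colour-learning segmentation approach that needs no dye.

## Method

**Segmentation.** The analyst supplies small training ROIs for three tissue
classes — *fungiform papillae* (pink), *filiform papillae* (whitish,
threadlike) and *tongue base* (light pink) — plus an optional *background*
class or tongue mask. The image is converted from sRGB to CIELAB (D65), the
mean L\*a\*b\* colour of each class's pooled ROI pixels becomes a colour
marker, and every pixel receives the class of the nearest marker under
Euclidean colour distance

&nbsp;&nbsp;&nbsp;&nbsp;ΔE² = (L\* − L\*ₘ)² + (a\* − a\*ₘ)² + (b\* − b\*ₘ)².

Rectangular sub-regions may be re-analysed with locally learned markers
(merged back at pixel level) to handle colour-shade drift across the tongue.

**Quantification.** Each connected component of fungiform pixels is one
detected papilla, with pixel/physical area, centroid, outer boundary and a
circular-equivalent diameter d = 2·√(A/π). Whole-tongue measures: total
count, FP density = FP area / tongue area (sum of the three tissue
classes), and the count inside a 6-mm diameter circle placed left of the
midline as close to the tip as possible (the classic manual counting
region).

**Spatial mapping.** The tongue is split through the midline into left and
right sides, into two 1-cm bands from the tip (Band 1, Band 2), and each
(side, band) into 4 equal-width strips numbered from the midline outward,
giving 16 grids L1–L8 / R1–R8 (1–4 in Band 1, 5–8 in Band 2). Every
papilla is assigned by its centroid; side, band and grid counts always sum
exactly to the total.

**Validation statistics.** Bland-Altman analysis (mean difference ±
1.96 SD limits of agreement), intraclass correlation ICC(2,1)/ICC(2,k)
(two-way random effects, absolute agreement, from ANOVA mean squares),
Spearman rank correlation, and forward stepwise regression of the total FP
count on band/grid counts (partial-F entry, R² path).

**Synthetic ground truth.** `generate_tongue_image` renders a seeded
semi-elliptical tongue with base tissue, filiform speckle, non-overlapping
FP disks planted denser in the first centimetre (70 % by default),
illumination drift and sensor noise — together with the exact class map and
papilla centres/radii, so detection can be scored against planted truth.

## Worked example

Generate a synthetic tongue and quantify it end to end:

```bash
fpquant simulate --seed 9 --out demo/sim
# planted 204 papillae (band1 137, band2 67); outputs in demo/sim
```

Write a config (`demo/config.yaml`) naming the image, the calibration and
per-class training ROIs (here, representative pixels of each class; on real
photographs you would give a few rectangles per class):

```yaml
image: sim/image.png
mm_per_px: 0.05
rois:
  fungiform:  [{rect: [512, 36, 1, 1]}, ...]
  filiform:   [{rect: [301, 122, 1, 1]}, ...]
  base:       [{rect: [420, 250, 1, 1]}, ...]
  background: [{rect: [5, 5, 1, 1]}, ...]
out_dir: out
```

```bash
fpquant quantify demo/config.yaml
# 1 image(s): mean total FP = 204.0, band1/band2 = 137.0/67.0, density = 0.0733
```

All 204 planted papillae are recovered, with the correct band split. The
per-image `summary.json` holds the full summary — e.g. here `left: 105`,
`right: 99`, `circle_count: 15` (FP inside the 6-mm circle near the tip),
`density: 0.0733` (7.3 % of the tongue surface is papilla tissue) and
`mean_equiv_diameter_mm: 0.562` — and `papillae.csv` one row per papilla:

```
id,x_px,y_px,area_px,area_mm2,equiv_diameter_mm,side,band,grid,in_region
1,512.171053,36.171053,152,0.380000,0.695580,R,2,R5,True
2,413.000000,39.417582,182,0.455000,0.761133,L,2,L5,True
```

The output directory also contains the indexed label mask (`labels.png`),
a QC overlay with midline/band/circle drawn (`overlay.png`) and the derived
geometry (`geometry.json`).

Agreement statistics on a counts table:

```bash
fpquant validate counts.csv --x-col auto --y-col manual --raters img1,img2,img3
```

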