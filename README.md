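# ichseg — hemorrhage segmentation and volumetry on head CT

`ichseg` segments spontaneous intracerebral hemorrhage (ICH) on
non-contrast head CT and quantifies its volume in milliliters.  It
implements **RG-WP**: seeded region growing with marker-based **w**atershed
**p**reprocessing — a classic-vision alternative to deep segmentation
models that needs no training data and runs in seconds on a laptop.  It is
aimed at medical-image-analysis researchers who want a reproducible,
scriptable baseline for hematoma volumetry, and it ships a synthetic
head-CT phantom generator so the entire pipeline can be exercised and
validated without patient data.

## Method

Acute blood is hyperdense on CT (~50–80 HU) against brain parenchyma
(~30 HU).  The pipeline:

1. **Windowing.** HU are mapped through the diagnostic brain window
   (width 100 HU, center 45 HU) onto [0, 1] with a single clamped linear
   map: `v = clip((HU + 5) / 100, 0, 1)`.  Bone saturates at 1, air at 0.
2. **Watershed seeding.** Each slice, Gaussian-smoothed and negated, is
   flooded by a marker-based watershed (markers = regional minima after
   h-minima suppression), so bright lesions become catchment basins.  One
   seed candidate per basin is proposed; candidates may be accepted
   automatically or snapped to a clinician's click.
3. **First region growing.** A breadth-first flood from each seed admits
   4-connected pixels whose intensity differs from the seed reference
   `f(x, y)` by at most `R = f(x, y) − f(i, j)`, `|R| ≤ τ` with τ = 0.30,
   then propagates slice-to-slice by re-seeding at the centroid-nearest
   in-mask pixel.
4. **Second region growing.** Per slice, a refined cut `t*` is found by
   maximizing Otsu's between-class variance
   `σ_B²(t) = ω₀ω₁(μ₀ − μ₁)²` over a region of interest around the
   first-pass mask; the definitive mask is re-grown with the one-sided
   rule `intensity ≥ t*`.
5. **Skull-adjacent bleeds.** When a bleed abuts the skull, the brain
   parenchyma is first extracted by region growing (bone saturates the
   window, so it is excluded by construction) and used as the growth
   domain.
6. **Volumetry & evaluation.** Volume = voxel count × voxel volume.  The
   bedside ABC/2 estimate (`A·B·C/2`, assuming an ellipsoid) is provided
   for comparison, along with overlap metrics (Sen, PPV, Dice, Jaccard),
   ICC(2,1) and Bland–Altman limits of agreement.

## Worked example

Generate a synthetic case and segment it:

```bash
ichseg phantom --n 1 --seed 7 --out suite/
ichseg segment --in suite/case_000.nii.gz --seed auto \
       --out-mask mask.nii.gz --out-report report.json
ichseg evaluate --pred mask.nii.gz --truth suite/case_000_truth.nii.gz
ichseg abc2 --mask suite/case_000_truth.nii.gz
```

The segmentation report contains (abridged):

```json
{"volume_ml": 8.3619, "seeds": [{"coordinate": [7, 129, 147], "source": "auto"}],
 "tau_first": 0.3, "tau_equivalent_second": 0.3208, "parenchyma_domain": false}
```

The watershed proposed one seed inside the lesion on slice 7; the
second-pass Otsu cut sits 0.32 normalized units below the seed intensity;
the estimated volume is 8.36 mL against a ground truth of 8.36 mL
(manifest column `true_volume_ml`).  `evaluate` confirms voxel-perfect
overlap on this case:

```json
{"Sen": 1.0, "PPV": 1.0, "DSI": 1.0, "JI": 1.0, "TP": 2484, "FP": 0, "FN": 0}
```

while the ellipsoid-based bedside estimate `abc2` reads 7.69 mL
(A = 27.0 mm, B = 26.3 mm, C = 21.6 mm) — a reminder of why voxel
counting is preferred when a segmentation is available.

Manual seeds are passed as repeated `--seed S,R,C` coordinates (slice,
row, column; 0-based) and are snapped to the containing watershed basin.

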