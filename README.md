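# irismooth

Automated measurement of the **smoothness index (SI)** of the anterior iris
border in anterior-segment OCT (AS-OCT) B-scans.

The SI of one side of the iris is the ratio of the straight-line (chord)
distance between the most peripheral and most central points of the anterior
iris border (*basal length*, BL) to the along-border distance between the
same two points (*actual length*, AL); the overall SI pools both sides:

```
overall SI = (BL_nasal + BL_temporal) / (AL_nasal + AL_temporal)
```

A perfectly smooth border has SI = 1; iris crypts lengthen the border and
push SI down. Crypt blunting (as in unilateral Fuchs uveitis) raises SI in
the affected eye, so the per-subject inter-eye SI difference is the quantity
of clinical interest.

## What's inside

| module | role |
| --- | --- |
| `irismooth.preprocess` | cropping (CASIA2 window available as `CASIA2_CROP`), 256-bin CDF-inversion histogram matching, intensity complement |
| `irismooth.segment` | deterministic 2-means histogram binarization, morphological cleanup, outer-boundary extraction |
| `irismooth.smoothness` | landmark snapping, chord length, geodesic distance-transform-sum shortest path, per-side and overall SI (`measure_si` runs the whole pipeline) |
| `irismooth.synthetic` | parametric iris phantoms with analytically known SI (`render_iris`), and a two-group cohort simulator (`generate_cohort`) |
| `irismooth.agreement` | Bland–Altman limits of agreement, ICC(2,1) with F-based 95% CI, absolute inter-eye difference summaries |
| `irismooth.cli` | `measure`, `batch`, `simulate`, `agree` subcommands |

The tool is semi-automated by design: the operator supplies the four
landmark points (nasal/temporal × peripheral/central) as coordinates; the
border segmentation and the length measurements are automatic.

A note on lengths: the raw shortest 8-connected chain through a rasterized
border over-measures the underlying continuous arc (staircase effect, up to
~8% at unfavourable slopes). `measure_si` therefore traces the geodesic path
and reports the length of a polyline through every 7th path pixel
(`resample_step`; set it to 1 to recover the raw chain cost, which is always
retained on the result as `path_cost`).

## CLI

```bash
# simulate a two-group cohort (images + truth.csv + manifest.csv)
irismooth simulate --out cohort/ --n-subjects 11 --fu-effect 0.03 --seed 1

# measure one scan; landmark order: nasal-peripheral nasal-central
#                                   temporal-peripheral temporal-central
irismooth measure --image scan.png --points "140,30 131,410 134,590 140,970" \
    --out results/

# measure every image in a manifest (image, subject, eye, group, points)
irismooth batch --manifest cohort/manifest.csv --out results/

# agreement statistics from a measurement table
irismooth agree --csv results/measurements.csv --out report.json --plot plots/
```

Pipeline settings (crop window, reference histogram, segmentation sizes,
snap radius, resample step) live in a single JSON config passed with
`--config`; physical pixel spacing can be supplied as `--spacing sy,sx` (mm),
otherwise lengths are in pixel units.

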