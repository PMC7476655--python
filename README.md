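# visdemand

Quantify everyday visual demands from egocentric snapshots. The package
implements a reusable analysis pipeline for first-person scene recordings:

- **`visdemand.images`** — decode PNG/TIFF frames (8/16-bit, gray or RGB),
  undo the sRGB transfer function, and collapse to linear luminance on a
  fixed 16-bit scale (BT.601 weights).
- **`visdemand.metrics`** — five per-image quantities: tonal-range contrast
  from the 0.5% brightest/darkest pixel tails, normalized global histogram
  entropy, textured-area fraction from a 9×9 local-entropy filter (3-bit
  cutoff), high-spatial-frequency area from a 3×3 range filter (threshold
  6554 = 10% of 2¹⁶), and edge-area fraction from a Sobel detector with an
  automatic (4×mean-magnitude) threshold.
- **`visdemand.geometry`** — annotated pixel spans → degrees of visual
  angle through the camera field of view (default 1920×1080, 120°
  horizontal) → logMAR (`log10` of the angle in arcminutes, no
  letter-detail factor), plus distribution summaries.
- **`visdemand.coding`** — the 14-classifier scene-coding schema, the
  48-item task vocabulary with a bespoke escape category, six-point
  difficulty simplification, time-of-day binning, and per-classifier
  percent agreement between coders (Cohen's kappa as an optional extra).
- **`visdemand.report`** — dual task rankings (snapshot frequency vs
  participant prevalence), per-classifier category distributions, metric
  distribution summaries, and narrative word frequencies.
- **`visdemand.synth`** — synthetic images and coding tables with planted
  ground truth (constant/checkerboard/noise/ramp/tail-controlled images,
  object scenes with exact pixel spans, multinomial task/classifier draws,
  dual-coder tables with a planted agreement rate).

## CLI

```sh
# five metrics for every PNG/TIFF in a directory → CSV
visdemand metrics IMAGE_DIR -o metrics.csv [--config cfg.yaml]

# angular-size summary from an annotation CSV
visdemand objects annotations.csv -o summary.json [--threshold-deg 2.0]

# rankings, distributions, summaries, word frequencies → CSVs + JSON report
visdemand aggregate --tasks tasks.csv --codes codes.csv --metrics metrics.csv \
    --out-dir out/ [--by snapshot|participant] [--round] [--stopwords FILE]

# synthetic fixtures with a ground-truth manifest
visdemand simulate --recipe noise --seed 7 --out fixtures/
```

Recipes for `simulate`: `constant`, `checkerboard`, `noise`, `half_noise`,
`ramp`, `tail_controlled`, `object_scene`, `coding`, `dual_coder`.

## File formats

Scene codes, task records, object annotations, and metric tables are
plain CSV; the coding schema and task vocabulary ship as editable YAML
under `src/visdemand/data/`; images are PNG or uncompressed TIFF
(8/16-bit). Metric configuration can be overridden with a YAML/JSON file
mirroring `MetricConfig` field names.
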