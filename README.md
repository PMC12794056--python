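# afm-kidney — automated fibrosis mapping around kidney tubules

Interstitial fibrosis in chronic kidney disease is not spatially uniform:
in Alport syndrome, where the collagen IV (α345) network of tubular
basement membranes is disrupted, fibrosis appears to arise preferentially
around *distal* tubules. This package implements the image-analysis
pipeline for testing that hypothesis quantitatively on trichrome-stained
kidney sections, plus a ground-truthed synthetic-histology generator so the
whole chain can be validated without patient slides.

Given an RGB section image and tubule annotations (GeoJSON polygons
labelled `distal` or `proximal`, e.g. a QuPath export), the pipeline
extracts a 512 × 512-px tile around each tubule's centroid, segments
fibrosis with an HSV color threshold (green–cyan collagen band), and
computes per tile the **fibrotic metric**

    f = (fibrotic pixels) / (tile pixels),   reported as percent

then compares distal vs proximal tiles per disease group with an
independent t test (Welch by default) and a Mann–Whitney U test — one
summary row per group: per-class tile counts, mean metric, two p-values.

The per-tile metric, group comparison, synthetic generator with analytic
per-tile expectations, and a pseudobulk counts-per-million utility for
labelled single-nucleus count matrices are all importable from `afm`; the
`afm` command line and the numbered scripts under `analysis/` drive them.

## Worked example

Simulate a three-group cohort (distal enrichment only in the first group),
run the pipeline, and read the summary:

```bash
python analysis/01_simulate_cohort.py     # writes results/cohort/
python analysis/02_run_afm.py             # writes results/afm/
```

```
Disease                       n dist  metric  n prox  metric     p (t)     p (U)
alport_like                       60    32.6     120    27.0  5.98e-15  8.43e-13
hypertensive_like                 60    24.8     120    25.2     0.459     0.493
vasculitis_like                   60    24.0     120    24.1     0.848     0.572
```

Each row is one disease group: number of distal tiles, their mean fibrotic
metric in percent, the same for proximal tiles, and the p-values of both
tests. The `alport_like` group was generated with an extra expected
fibrotic area fraction of +0.08 within an enrichment radius of each distal
tubule; the pipeline recovers a 5.6-point separation (analytic expectation
5.8 points from the generator ground truth) and both tests reject. The
null groups show no separation. `analysis/03_null_calibration.py` and
`analysis/04_effect_recovery.py` replicate these two regimes to measure
type-I error and power; `results/afm/` also contains the per-tile CSV
(re-runnable stats stage: `afm stats`), per-slide breakdown, box plots and
a JSON manifest recording every threshold used.

The same run is available as a CLI for real data:

```bash
afm run --slide alport slide1.tiff slide1.geojson \
        --slide alport slide2.tiff slide2.geojson \
        --hue-min 90 --hue-max 180 --out results/my_run
```

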