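# neuroassay

Functional phenotyping pipeline for iPSC-derived neuronal cultures:
signal processing and group statistics for three cell-based assays, plus a
seeded synthetic-data generator so every stage can be validated without
recorded data.

- **MEA** (`neuroassay.mea`) — first-order Butterworth band-pass
  (200–2500 Hz) of 12.5 kHz extracellular traces, adaptive spike detection
  at 5.25× the rolling standard deviation of the filtered signal, and
  per-well average firing rates from ten-minute recordings.
- **Calcium imaging** (`neuroassay.calcium`) — transient calling on 1 Hz
  ROI fluorescence traces: candidate peaks delimited by their furthest
  strictly-decreasing flank minima, scored by the triangle area spanned by
  the peak and the two minima, thresholded at one standard deviation from
  the signal mean (two alternative readings of the rule and an
  under-the-curve area functional are pluggable), then event frequencies
  over active cells only.
- **Scratch assay** (`neuroassay.scratch`) — object counts inside the
  standardized 1.3 × 0.35 mm region, daily densities and least-squares
  recovery rates over the ten-day time course.
- **Statistics** (`neuroassay.stats`) — one-way ANOVA with Tukey HSD
  (Tukey–Kramer for unbalanced groups), mixed-design repeated-measures
  ANOVA (between-group × within-day, with Greenhouse–Geisser-corrected
  p-values reported alongside), and mean ± SEM summaries.
- **Synthetic data** (`neuroassay.synth`) — ground-truth-labeled Poisson
  spike trains embedded as biphasic waveforms in Gaussian noise, sparse
  calcium transients with exponential decay, and scratch reinvasion counts
  whose case/control divergence begins after day 4; fully deterministic
  per seed.
- **Pipeline** (`neuroassay.pipeline`, `neuroassay.cli`) — schema-validated
  YAML configuration, input validation, and a cohort-level report with
  config-hash provenance.

## CLI

```bash
neuroassay simulate  --config cfg.yaml --seed 1 --out cohort/
neuroassay mea-detect --config cfg.yaml --in cohort/mea --out mea_out/
neuroassay ca-detect  --config cfg.yaml --in cohort/calcium --out ca_out/
neuroassay scratch    --config cfg.yaml --in cohort/scratch_counts.csv --out scratch.csv
neuroassay stats      --in tidy.csv --out stats.json [--repeated]
neuroassay run-all    --config cfg.yaml --seed 1 --out run/
neuroassay validate   cohort/design.csv cohort/mea/*.csv
```

The YAML config mirrors `neuroassay.config.RunConfig`; unknown keys and
invalid values are rejected before any computation, e.g.

```yaml
seed: 1
mea:
  filter: {low_hz: 200, high_hz: 2500, order: 1}
  threshold: {k: 5.25, window_s: 0.1, dead_time_s: 0.001, polarity: both}
ca:
  rule: literal        # or peak_population / sd_only
  area: triangle       # or under_curve
scratch:
  roi: {width_mm: 1.3, height_mm: 0.35}
```

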