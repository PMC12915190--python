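# photomics

Analysis toolkit for two related workflows:

1. **Fiber photometry** — dual-channel (470 nm signal / 410 nm isosbestic
   control) trace processing: ordinary-least-squares control fit, ΔF/F
   computation `(signal − fitted_control) / fitted_control`, whole-trace
   z-scoring (population SD), peri-event extraction around behavioral bout
   onsets, threshold-based transient detection (baseline mean + k·SD with an
   absolute amplitude floor, 0.02 ΔF/F = 2% by default), and per-event
   metrics: frequency (events/min), trapezoidal AUC, and single-exponential
   decay tau.
2. **Omics screening** — per-feature fold change (raw ratio of group means)
   with a pooled-variance Student's t-test and Benjamini–Hochberg
   adjustment, threshold classification (presets: proteomic 1.1/0.9,
   phosphoproteomic 1.2/0.83, transcript-style 1.2/0.83 with adjusted
   p < 0.01), screen summaries with percentages, gene-set intersection (GMT),
   hypergeometric enrichment (enrichment factor = k/M), and degree-based hub
   ranking on a user-supplied edge list.

A `synthgen` module provides seeded simulators for all inputs (photometry
traces with photobleaching, shared motion artifacts and Poisson-timed
transients; alternating behavioral bouts; two-group abundance tables with
planted fold changes; random networks with planted hubs), so the entire
pipeline is testable offline with known ground truth.

## CLI

All functionality is reachable through the `photomics` umbrella command
(exit codes: 0 ok, 1 validation error, 2 runtime error):

```bash
# simulate a recording + bouts and analyze them
photomics simulate photometry --seed 1 --duration 360 --out-prefix demo
photomics simulate bouts --seed 1 --duration 360 --out-prefix demo
photomics photometry run --recording demo_recording.csv \
    --bouts demo_bouts.tsv --k-sd 3 --amp-floor 0.02 \
    --pre 2 --post 6 --baseline-mode whole_trace --out-dir out/

# omics screen and set operations
photomics simulate omics --seed 1 --out-prefix tbl
photomics screen --table tbl_table.tsv --groups tbl_groups.tsv \
    --preset proteomic --out-dir out/
photomics intersect --query degs.txt --gmt sets.gmt
photomics enrich --dep deps.txt --gmt sets.gmt --background bg.txt
photomics hubs --edges edges.tsv --top 9

# multi-stage runs from a YAML/JSON config (unknown keys rejected);
# a manifest.json records version, parameters, checksums and seed
photomics pipeline --config run.yaml --seed 7
```

File dialects are pinned: recording CSV (`time_s,f470,f410`), bout TSV
(`onset_s`, `offset_s`, `label`), abundance TSV (`feature_id` + sample
columns) with a sample→group TSV, GMT gene sets, two-column TSV edge lists.
All intervals are half-open and in seconds.

## Conventions and defaults worth knowing

- The control fit is plain OLS of the signal channel on the control channel
  over the whole recording.
- Baseline statistics for detection default to the whole trace; an
  `iterative_exclusion` mode re-estimates the baseline twice after dropping
  super-threshold samples.
- The amplitude floor is expressed as a ΔF/F ratio (default 0.02, i.e. 2%);
  pass `--amp-floor 2.0` if you want the literal ratio-of-2 reading.
- Z-scoring uses the population SD (denominator N).
- Simulator defaults (20 Hz sampling, noise SD 1% of baseline) are package
  choices; every generator is deterministic given its seed.
- Screen percentages are rounded half-away-from-zero to two decimals.
- Identifier normalization for set operations: case-fold plus stripping a
  numeric version suffix after the final dot.
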