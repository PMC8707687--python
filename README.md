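# plasmacv

Duplicate-design multiplexed (10-plex TMT) plasma proteome variation
analysis as a tested, reusable pipeline:

- **`plasmacv.synthetic`** — generate duplicate-design reporter matrices
  (default: 42 subjects × 2 replicate preparations spread over eleven
  10-plex sets with pooled-control channels 126 and 131) with known
  log-normal biological/analytical variation, optional channel cross-talk,
  plex batch factors and missingness, plus the ground truth to verify
  recovery.
- **`plasmacv.processing`** — reporter-matrix processing chain: isotope
  impurity correction (linear unmixing per plex), global equal-sum
  normalization, per-protein control scaling across plexes, and relative
  abundance versus the pooled internal control.
- **`plasmacv.variation`** — ≥50 % completeness filter and per-protein
  decomposition of total variation into analytical (mean duplicate CV) and
  inter-individual biological CV (square-root difference of squares), with
  cohort medians and histogram summaries.
- **`plasmacv.power`** — per-group sample sizes
  `n = ceil(2 (z_{α/2} + z_{1−β})² σ² / Δ²)` across fold changes and
  variance percentiles, with percentile-bootstrap confidence intervals and
  a Monte-Carlo power self-consistency check.
- **`plasmacv.reporting`** — deterministic TSV reports and comparison of
  estimated biological CVs against a shipped reference table (EFLM
  Biological Variation Database values for 17 abundant plasma proteins).

## CLI

One `plasmacv` entry point with five subcommands; a full round trip:

```sh
plasmacv simulate --n-proteins 500 --cv-biological 20 --cv-analytical 5 \
    --missing-rate 0.05 --seed 1 --out-prefix scratch/sim
plasmacv process --matrix scratch/sim_matrix.tsv \
    --sample-map scratch/sim_sample_map.tsv --out scratch/rel.tsv
plasmacv cv --matrix scratch/rel.tsv --sample-map scratch/sim_sample_map.tsv \
    --out scratch/cv.tsv --summary-out scratch/summary.tsv
plasmacv power --variation-table scratch/cv.tsv --seed 1 --out scratch/grid.tsv
plasmacv compare --variation-table scratch/cv.tsv --out scratch/comparison.tsv
```

`plasmacv defaults` prints the default simulation configuration.
Matrices are wide TSV (rows = protein accessions, columns `<plex>_<channel>`
such as `P01_126`, empty cells = missing); the sample map TSV has columns
`plex`, `channel`, `subject_id` (or `POOL`), `replicate`. A kit-style
impurity table (`channel`, `minus2`, `minus1`, `plus1`, `plus2` in percent)
can be passed to `simulate` (forward mixing) and `process` (correction);
an example ships in `src/plasmacv/data/`.

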