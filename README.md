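# frondquant

Quantification pipeline for duckweed (*Lemna gibba*) growth experiments
under multiple light intensities:

- **synthetic** — seeded generators for top-down dish photographs with
  exactly known frond coverage, fluorescence-yield tables built by
  inverting the PSII parameter definitions, and pigment tables with
  configurable per-PPFD means and a dark-Fv/Fm–vs–Z/(V+A+Z) linear
  coupling. Every downstream stage has parameter-recovery ground truth.
- **imaging** — frond-area measurement: circular water-surface masking
  (configured geometry or Hough detection), HSV green thresholding, and
  coverage-fraction × water-surface-area conversion to m².
- **growth** — endpoint relative growth rate, exponential area
  projection, the photon-flux integral (closed form with a stable
  RGR→0 limit), photons received, and light-use efficiency.
- **fluorescence** — Fv/Fm, Fv′/Fm′, qP, and the partitioning of
  absorbed photons into photochemistry (P), thermal dissipation
  (D = 0.8 − Fv′/Fm′) and excess (E), plus rate products with incident
  PPFD.
- **pigments** — xanthophyll-cycle and carotenoid pool sums/ratios with
  the pre/post-recovery averaging convention (zeaxanthin kept separate
  per recovery state).
- **stats** — one-way ANOVA, Tukey–Kramer HSD with an in-repo
  insert-and-absorb compact letter display, and simple linear
  regression.
- **pipeline / cli** — end-to-end orchestration with a JSON run
  manifest; deterministic under a fixed seed.

## CLI

All stages share one YAML config (every key optional; defaults describe
a 3-dish × 4-PPFD, 4-day experiment):

```sh
frondquant run-all --seed 1 --out-dir run            # full pipeline
frondquant simulate --seed 1 --out-dir run           # images + raw tables
frondquant segment --out-dir run --qc-dir run/qc     # -> areas.csv
frondquant growth --out-dir run                      # -> growth.csv
frondquant fluorescence --table run/fluor.csv --out-dir run
frondquant pigments --table run/pigments_raw.csv --out-dir run
frondquant stats --table run/growth.csv --value RGR --group ppfd --out stats.csv
```

`run-all` writes `areas.csv`, `growth.csv`, `psii.csv`, `pigments.csv`,
`stats.csv`, `regression.csv` and `run_manifest.json` under `--out-dir`;
re-running with the same config and seed reproduces the CSVs
byte-for-byte.

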