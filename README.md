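# mycomorph

Morphometric quantification of fungal mycelial growth, paired with a seeded
stochastic colony generator so that every analysis stage is verifiable by
parameter recovery — no external imaging data required.

A colony snapshot is a rooted tree of hyphae in calibrated 3D space (µm,
hours).  The package covers:

- **`mycomorph.network`** — domain model: nodes, polyline segments,
  forests, lineage path lengths, window-secant arm directions, voxel grids.
- **`mycomorph.io`** — SWC and JSON morphology dialects, multi-page TIFF
  voxel stacks.
- **`mycomorph.simulate`** — stochastic growth: phase-dependent tip
  activity, tip extension rates from a gamma-plus-linear-baseline mixture,
  elongation-triggered apical/lateral branching with Gaussian branch angles
  and gamma branching lengths, small out-of-plane tilts, full event log.
- **`mycomorph.raster`** — rasterization of networks to binary or noisy
  grayscale voxel stacks.
- **`mycomorph.kinetics`** — tip tracking across snapshots (identity or
  nearest-endpoint), extension rates, active/dormant classification,
  per-interval summaries (tip counts, k_active, φ_br).
- **`mycomorph.morphometry`** — AB/LB branch-site classification, branch
  angles in projection, branching lengths, crossing exclusion, and the
  closed-form projection-error corrections for angles and lengths.
- **`mycomorph.biomass`** — maximum-intensity projection, triangle
  thresholding, voxel biomass curves, annular region/portion partition, and
  least-squares age-of-region curve alignment.
- **`mycomorph.fitting`** — density histograms, RSS objective, Gaussian /
  gamma / rate-mixture laws, seeded differential-evolution fitting with a
  Nelder–Mead polish, weighted CDFs and samplers.
- **`mycomorph.pipeline` / `mycomorph.cli`** — YAML-configured, seeded
  end-to-end orchestration (generate → measure → fit → report).

## CLI

```sh
# grow a colony; writes series.json, per-snapshot SWC files and event CSVs
mycomorph simulate --config configs/tiny.yaml --seed 1 --out runs/sim

# per-interval tip kinetics table from a stored series
mycomorph kinetics --series runs/sim/series.json --out runs/kinetics.csv

# branch-site types and angles of the final snapshot
mycomorph morphometry --series runs/sim/series.json --out runs/morpho.csv

# fit a law to a stored histogram (CSV with `center` and `count` columns)
mycomorph fit --family gaussian --hist hist.csv --width 5.0 --seed 0

# the full pipeline: simulate, measure, fit, biomass, report
mycomorph all --config configs/paper_scale.yaml --seed 1 --out runs/full
```

Exit codes: 0 ok, 2 configuration error, 3 stage error.  Identical seed and
configuration give byte-identical reports.

Example configurations live in `configs/`; `tiny.yaml` is a sub-minute
smoke run, `paper_scale.yaml` a full 17-day colony.  The two
`branch_lengths_by_age_*.yaml` files select between the two published
age labellings of the age-resolved branching-length laws.

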