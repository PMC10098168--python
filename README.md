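# phyloclock

Relaxed molecular-clock divergence dating for gene families, as a tested,
reusable pipeline:

- **Tree handling** (`phyloclock.trees`) — Newick I/O, Minimal Ancestor
  Deviation (MAD) rooting, monophyly detection, clade-composition coding
  ("over 67% of one group"), and rank-based clade subsampling.
- **Branch-rate processes** (`phyloclock.rates`) — uncorrelated gamma
  multipliers (UGAM), autocorrelated lognormal (LN), and the mean-reverting
  square-root CIR process: exact simulation and transition densities, as
  mean-1 multipliers of a global rate μ.
- **Bayesian dating** (`phyloclock.dating`) — Metropolis-within-Gibbs
  sampling of node ages on a fixed rooted topology under a truncated-normal
  root prior, hard fossil-calibration bounds on named MRCAs, and any of the
  three rate models. The sequence likelihood is replaced by per-branch
  Poisson substitution counts `k_b ~ Poisson(r_b·μ·Δt_b·L)` — a deliberate,
  documented stand-in that keeps the full method exercisable at desk scale.
  Includes the 3-model × 8-calibration-subset grid runner.
- **Diagnostics** (`phyloclock.diagnostics`) — effective sample size
  (Geyer initial positive sequence), between-chain discrepancy
  (|Δmean|/pooled SD, pass at ESS ≥ 50 and d ≤ 0.30), root-prior boundary
  detection, leave-calibration-in cross-validation of fossil recovery, and
  the duplicate-calibration variance criterion for ranking clock models.
- **Homolog QC** (`phyloclock.qc`) — identity/coverage/E-value/length
  filters with named presets, per-genus subsampling, catalytic-site gap
  screening (±1 column adjacency), autapomorphic-insertion detection
  (≥20-residue runs), column trimming, and KDE length profiling.
- **Synthetic data** (`phyloclock.synth`) — Yule time-trees, rate and
  count simulation, planted taxonomy/alignment/hit-table fixtures with
  machine-readable truth, and a one-call end-to-end bundle builder.

## CLI

All stages are wired through one entry point; every run writes a
`manifest.json` (options, seed, version, input checksums) under `--out`.

```bash
# build a fully synthetic input bundle
phyloclock simulate --n-tips 20 --crown-age 2000 --model UGAM --seed 1 --out bundle/

# curate a hit table and screen an alignment
phyloclock qc --hits bundle/hits.tsv --profile nitrilase-blast \
    --alignment bundle/alignment.fasta --triad-cols 10,20,30 --out qc/

# MAD-root a gene tree
phyloclock root --tree bundle/gene_tree.nwk --out rooted/

# date node ages (writes per-chain trace TSVs, summary and convergence JSON)
phyloclock date --tree bundle/chronogram.nwk --counts bundle/counts.tsv \
    --calibrations bundle/calibrations.yaml --model CIR \
    --chain-length 20000 --n-chains 2 --seed 1 --out dated/

# or run the full model x calibration-subset grid
phyloclock date --tree bundle/chronogram.nwk --counts bundle/counts.tsv \
    --calibrations bundle/calibrations.yaml --grid --seed 1 --out grid/

# convergence + root-prior boundary diagnostics from traces
phyloclock diagnose --trace dated/trace_chain0.tsv --trace dated/trace_chain1.tsv \
    --root-prior 3800,800 --out diag/

# calibration cross-validation over a grid
phyloclock cv --grid grid/grid.json --calibrations bundle/calibrations.yaml --out cv/
```

Exit codes: 0 success, 2 validation error (missing inputs, bad flags),
1 runtime error.

The calibration YAML pairs a root prior (an `[old, young]` interval in Ma,
read as mean ± 2 sd of a normal truncated at 0) with hard MRCA bounds:

```yaml
root_prior: {old: 3800, young: 800}
calibrations:
  - {name: plant, tip_a: t3, tip_b: t7, min_age: 590, max_age: 750, group: plant}
```

## Notes on statistical design

- Root prior: an `[old, young]` bound pair defines Normal((old+young)/2,
  (old−young)/4) truncated at 0.
- Internal node ages are uniform over the order-compatible polytope given
  the root; the sampler carries the exact `root^-m` volume factor so the
  root marginal equals the stated prior (verified against a direct
  rejection-sampling oracle).
- Calibrations are hard bounds (uniform within), matching common
  relaxed-clock defaults.
- A likelihood-invariant "rate-time" move (ages × c, μ / c) is included to
  mix the rate-time ridge; proposal step sizes auto-tune to 20–50%
  acceptance during burn-in and are frozen afterwards.
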