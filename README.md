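# blimap

Biolayer-interferometry (BLI) binding analysis in Python:

- **`blimap.synthetic`** — simulate 1:1 Langmuir and biphasic sensorgram
  plates from known kinetics (with reference channels, Gaussian noise and
  baseline drift), sequential two-ligand competition traces with a tunable
  epitope-overlap fraction φ, and protein sequences with planted
  complementary-hydropathy motifs. Everything downstream is testable with
  no instrument data.
- **`blimap.bli`** — sensorgram/plate data model, long-format CSV I/O,
  double-reference subtraction (sample − loaded-sensor-in-buffer −
  unloaded-pin-in-analyte), and per-step re-zeroing.
- **`blimap.kinetics`** — steady-state isotherm fitting
  (R_eq = R_max·C/(C + K_D)), global 1:1 kinetic fitting (k_on, k_off,
  R_max) with biphasic model-mismatch detection, fold-change-vs-WT
  arithmetic, and binding / decreased-binding / no-binding classification.
- **`blimap.competition`** — Association-2 response gain and percent
  decrease versus the ligand-alone arm for sequential competition
  experiments.
- **`blimap.hydropathy`** — complementary-hydropathy screening on the
  Kyte–Doolittle scale: signed binary maps, bidirectional sliding-window
  scans, percent match, the normalised complementarity degree
  C = Σ|H−H′|/(L·9), strict >75% / >0.5 hit filtering, and hit clustering
  into candidate binding regions.
- **`blimap.sitemap`** — variant-panel binding-site assignment: parse
  mutagenesis panels, grade per-site effects (ablating / severe / moderate /
  enhancing / neutral), and emit a ligands × sites verdict matrix with
  primary-site calls. Ships transcribed receptor-panel tables for four
  ligands as bundled fixtures.

## CLI

The `blimap` entry point exposes one subcommand per pipeline stage:

```sh
# simulate a plate (1to1 | biphasic | sequential) from a YAML config
blimap simulate --config sim.yaml --seed 7 --out plate.csv

# fit affinity from a plate CSV (double-references automatically)
blimap fit --in plate.csv --method steady_state --out fit.tsv
blimap fit --in plate.csv --method kinetic --out fit.tsv

# quantify a sequential competition pair
blimap compete --alone alone.csv --competed competed.csv \
    --ligand1 blocker --conc1 1e-6 --out competition.tsv

# complementary-hydropathy screen (FASTA motifs vs FASTA target)
blimap hydroscan --motifs motifs.fasta --target target.fasta \
    --out hits.tsv --summary regions.tsv

# binding-site assignment from variant panels (bundled panels by default)
blimap sitemap --out matrix.tsv --report report.txt
```

Example simulate config:

```yaml
model: 1to1
analyte: cytokine
params: {k_on: 1.0e+5, k_off: 1.65e-3, r_max: 1.0}
design:
  concentrations: [6.25e-8, 1.25e-7, 2.5e-7, 5.0e-7, 1.0e-6]
  t_assoc: 1500
  t_dissoc: 300
  sample_rate: 2
  noise_sd: 0.005
  drift_rate: 0.0001
  seed: 7
```

Bundled data (`src/blimap/data/`): variant-panel TSVs (`panel_*.tsv`),
default region annotations (`regions.yaml`), and a planted-motif demo FASTA
pair (`demo_motifs.fasta` / `demo_target.fasta`).

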