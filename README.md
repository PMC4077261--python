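# spikenorm

Spike-in control based normalization (SCN) for miRNA microarray data, with
quality-control metrics, detection calls, dose-response differential
expression and a synthetic-experiment simulator.

Spike-in RNAs are added at identical concentration to every sample, so the
deviations of their probe-set intensities across arrays measure array-specific
bias. SCN extracts the shared (rank-1) component of those deviations,
extends it over the full intensity range (stabilization at low intensities,
linear extrapolation at high intensities, LOWESS smoothing with fraction 0.4,
piecewise-linear interpolation) and subtracts the resulting per-array
correction function ΔE(x, k) from every intensity. Applicability is guarded
by three explicit checks (A1 shared variance, A2 well-separated spike levels,
A3 intensity-range coverage); if any fails, MEDIAN normalization is used
instead.

## Modules

| module | contents |
| --- | --- |
| `spikenorm.io_formats` | data model (`ProbeLevelData`, `ProbeSetData`, `ExperimentDesign`), ImaGene-dialect and TSV matrix I/O, median probe-set summarization |
| `spikenorm.scn_core` | assumption checks A1–A3, rank-1 spike corrections, correction-function construction/application, `scn_normalize` orchestration with MEDIAN fallback |
| `spikenorm.baseline_norm` | MEDIAN and quantile normalization |
| `spikenorm.qc_metrics` | Exiqon and Wilcoxon detection calls; CVwithin / CVbetween / CVtreat / relativeCVspike with whisker-range rescaling |
| `spikenorm.diff_expr` | dose-response OLS with empirical-Bayes moderated t, pairwise log2 differences with CIs, comparative-Ct qPCR processing, leave-one-out Spearman CI |
| `spikenorm.synthetic_data` | simulator with injected per-array bias functions and full ground truth |
| `spikenorm.cli` | `spikenorm` command with `simulate` / `normalize` / `qc` / `de` / `run` subcommands |

## CLI

```sh
# simulate a 16-array experiment (4 groups x 4 replicates, 10 spike-in sets)
spikenorm simulate --seed 1 --out out/fixture

# normalize (scn | median | quantile); writes normalized.tsv,
# assumptions.json and correction_knots.tsv
spikenorm normalize --input-dir out/fixture --method scn --out out/norm

# CV quality metrics and detection calls
spikenorm qc --input-dir out/fixture --method scn --out out/qc

# dose-response + pairwise (high vs sham) differential expression
spikenorm de --input-dir out/fixture --method scn --out out/de

# all stages in one go
spikenorm run --seed 1 --method scn --out out/run
```

Simulation parameters can be overridden with a YAML file
(`--config sim.yaml`), e.g.:

```yaml
n_mirna_sets: 600
bias_amplitude: 0.4
probe_noise_sd: 0.05
de_fraction: 0.1
global_decrease: true
```

## Library example

```python
from spikenorm import SimulationConfig, simulate_experiment, scn_normalize

pld, design, truth = simulate_experiment(SimulationConfig(seed=1))
result = scn_normalize(pld, design)
result.report.to_dict()          # A1-A3 outcomes, fallback flag
result.data.intensities          # normalized probe-set matrix
result.correction.evaluate([8.0, 10.0], "sham_01")  # ΔE(x, k)
```

## File formats

* **ImaGene dialect** — per-array text file: free-form header, then a
  tab-delimited table between `Begin Raw Data` / `End Raw Data` with columns
  `Gene ID`, `Signal Median`, `Background Median`, `Flag` (linear scale;
  nonzero flag = bad quality).
* **Matrix TSV** — probe/probe-set ids in the first column, array labels in
  the header; log2 scale unless the first line is `# scale: linear`.
* **Annotation TSV** — columns `probe`, `probe_set`, `probe_class`
  (`mirna` / `spikein` / `other`), `species`.
* **Design TSV** — columns `array`, `group`, `dose`, `is_control`.
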