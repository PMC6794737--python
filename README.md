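# doeopt

Design-of-experiments optimization of command-line pipeline parameters.

Tuning a multi-step pipeline (assembler, classifier, variant caller, ...) by
hand or by exhaustive grid search is expensive: the number of parameter
combinations grows exponentially. `doeopt` finds good settings in far fewer
runs using a two-phase strategy:

1. **Screening** — a generalized subset design (GSD) spans the full factor
   space at a coarse resolution (default five levels per numeric factor,
   reduction factor = number of factors). Categorical factors are fixed at
   the best configuration found.
2. **Iterative optimization** — central composite face-centered (CCF)
   designs are placed around the current best point. An OLS response-surface
   model is selected per response (best-subset or greedy forward search,
   ranked by leave-one-out Q2). When the model is predictive (Q2 > 0.5) its
   in-region optimum is executed as a validation run. The design region then
   moves toward the best result (step = 25% of the span), shrinks (factor
   0.9), and is clamped inside the global bounds, until the design stops
   moving or stops improving.

Multiple responses are combined with Derringer–Suich desirability functions:
each response is rescaled linearly to [0, 1] between its acceptability limit
and its target, and the overall score is the geometric mean. If the final
best still violates an acceptability limit, optimization restarts from the
next-best screening configuration.

## Running tests

```sh
python -m pytest -q
```

## CLI

```sh
doeopt validate config.yaml          # parse + sanity-check a configuration
doeopt run config.yaml --outdir out  # two-phase optimization
doeopt gridsearch config.yaml        # exhaustive baseline at screening resolution
```

`doeopt run` writes `audit.csv` (every executed run with factor settings,
responses, desirabilities, status), `best.json` (best configuration, total
run count, halt reasons) and `doeopt.log` to the output directory.

### Configuration

```yaml
design:
  factors:
    KMER: {type: ordinal, min: 20, max: 90}
    MIKC: {type: quantitative, min: 2, max: 15}
    ALG:  {type: categorical, categories: [bwa-mem, minimap2]}
  responses:
    N50:  {criterion: maximize, low_limit: 28000, target: 35000}
    nSeq: {criterion: minimize, high_limit: 95, target: 85}
  reduction_factor: 8        # optional; defaults to the number of factors
  model_selection: greedy    # or best_subset (default for <= 4 factors)
  shrinkage: 0.9
  step_fraction: 0.25
  q2_threshold: 0.5
pipeline:
  assemble: "assemble --k {{KMER}} -c {{MIKC}} --aligner {{ALG}}"
  evaluate: "stats assembly.fa > results.txt"
execution:
  mode: sequential           # or parallel
  results_file: results.txt
  scheduler: {partition: main, time: "01:00:00"}   # emitted as #SBATCH headers
```

Each pipeline step becomes a batch script per run with `{{FACTOR}}`
placeholders substituted; the last step must leave a results file with
`name: value` lines (or a single bare number when only one response is
declared).

### Mock pipelines

`doeopt-mock` evaluates a synthetic objective (quadratic surface with known
optima, optional noise and categorical offsets, declared in a small YAML
spec) and writes a results file, so complete optimizations can be exercised
without any bioinformatics tools or data:

```sh
doeopt-mock --spec objective.yaml --out results.txt --set KMER=38 --set MIKC=8.5
```

Fixture configurations replicating four published benchmark factor spaces
(de-novo assembly, scaffolding, k-mer classification, variant
calling/filtering) ship in `doeopt.fixtures`.

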