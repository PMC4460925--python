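# funpat

Integrated selection, temporal pattern clustering and functional assignment
for time-series RNA-seq data, with a Negative-Binomial benchmark simulator
and an evaluation harness.

## The problem

Time-course RNA-seq experiments ask which genes respond to a treatment *over
time*, not merely between two groups. Testing each gene with a static
two-group method ignores the ordering of time points, and controlling the
false discovery rate across ~10⁴ genes pushes many genuinely responding
genes below the significance threshold (false negatives). Yet a gene that
narrowly misses the FDR cut, shares its temporal expression pattern with a
group of significant genes, *and* shares their functional annotation is very
likely a true positive.

`funpat` implements a pipeline that exploits exactly this reasoning:

1. **Bounded-Area selection.** Each gene is ranked by the area *A* of the
   region bounded by its two piecewise-linear temporal profiles (treatment
   vs control, replicate-averaged, log₂ scale). Replicate variability is
   modelled as a function of mean expression, a Monte-Carlo null
   distribution of *A* under no-difference is built from that noise model,
   and Gamma / Log-normal / Weibull families are fitted to it (best by
   Anderson–Darling; empirical quantiles as fallback). Genes with
   BH-adjusted p ≤ FDR threshold are **seeds**; genes with nominal
   p ≤ a soft threshold are **candidates**. Only two replicates at a single
   time point are required, and a data-poor mode handles single-replicate
   series with adjacent-time pseudo-replicates.
2. **Gene-set pattern clustering.** Within each gene set (e.g. a GO term),
   an EM-style algorithm extracts clusters of genes whose log fold-change
   profiles follow a shared temporal pattern *P* through the affine model
   `x = k·P + q + ε`: per-gene least squares for (k, q), membership by a
   χ² goodness-of-fit test, an exact one-sided runs test, and a positive
   slope-significance test, then inverse-variance re-estimation of *P*.
   A cluster is significant only if it contains a seed.
3. **DAG traversal.** With a hierarchical annotation (the GO DAG), patterns
   are searched in the most specific terms and clustered genes are removed
   from all ancestor terms, so each gene attaches to its most informative
   annotation. A second clustering pass over the per-set patterns yields
   the dataset-wide **Main Patterns**.
4. A gene is called differentially expressed if it is a seed *or* belongs
   to a significant pattern (pattern-rescued) — raising recall without
   giving up FDR control.

The package also ships the benchmark generator used to validate all of the
above: S temporal log fold-change patterns drive 20 DE genes each,
`log θ = k·P_j(t) + q` with `k ~ U[0.5, 2]`, `q ~ N(1.5, 1.8)`, counts drawn
from `NB(R·π, φ = 0.1)` at per-sample depths `R ~ U[10⁶, 10⁷]`, TMM
normalization, and a synthetic three-level gene-set catalog with ground
truth.

## Worked example

```python
from funpat import SimulationConfig, generate, FunPat
from funpat.evaluation import precision_recall

ds = generate(SimulationConfig(seed=1))          # 10000 genes, 13 times, 2x3 replicates
model = FunPat(ds.normalized, ds.design, ds.catalog, ds.dag)
result = model.fit(seed=1)
print(result.summary())
```

```
FunPat time-series analysis
===========================
genes                  10000
seeds (FDR <= 0.05)    113
candidates (p <= 0.05)  701
significant patterns   7 in 6 gene sets
main patterns          7
DE genes               125 (12 pattern-rescued)
null family            gamma
```

113 genes pass the 5% FDR threshold on the area statistic; the per-set
clustering then rescues 12 candidate genes that share a seed-anchored
temporal pattern, for a final list of 125. Scored against the simulation's
ground truth:

```python
p, r = precision_recall(result.de_genes, ds.de_genes, 120)
# precision 0.872, recall 0.908
```

so rescue lifted recall from 0.86 (seeds alone) to 0.91 at ~0.87 precision,
and the seven Main Patterns recovered one cluster per simulated temporal
shape (plus one small fragment). `result.write_reports(out_dir)` writes
`genes.tsv`, `gene_sets.tsv`, `main_patterns.tsv`, `scores.tsv` and
`patterns.json` (optionally per-pattern PDF plots).

The same analyses run from the shell:

```sh
funpat simulate --seed 1 --out data/
funpat run --counts data/counts.tsv --design data/design.tsv \
           --anno data/anno.tsv --dag data/dag.tsv --fdr 0.05 --out reports/
funpat select --counts data/counts.tsv --design data/design.tsv --out scores.tsv
funpat benchmark --datasets 20 --seed 1 --out bench/
```

## Layout

| module                | contents |
| --------------------- | -------- |
| `funpat.core`         | domain types, TSV readers, annotation DAG and propagation |
| `funpat.normalize`    | TMM scaling factors, log transforms, log-ratio profiles |
| `funpat.bounded_area` | area statistic, noise model, Monte-Carlo null, `BoundedArea` model |
| `funpat.clustering`   | affine pattern model, residual tests, EM cluster extraction |
| `funpat.pipeline`     | `FunPat` model / `FunPatResults`, DAG traversal, Main Patterns, reports |
| `funpat.simulate`     | benchmark dataset generator with ground truth |
| `funpat.evaluation`   | metric suite and the `run_benchmark` harness |

See `docs/methods.md` for the statistical details and design choices.
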