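# mixbench

Benchmarking RNA-seq analysis methods with two-source mixture designs.

## The problem

A mixture control experiment takes RNA from two reference sources (e.g. two
cell lines), mixes them at known proportions — 100:0, 75:25, 50:50, 25:75,
0:100, each in triplicate — and sequences every sample. Because each gene's
concentration in a mixed sample is determined by the mixing proportion, the
design carries *built-in truth*: the same genes must differ between any two
distinct mixture points, and the size of every log-fold-change is predictable
from a gene-wise dose-response model. That truth lets you score
differential-expression (DE) methods, normalization choices and deconvolution
estimators against each other without spike-ins or simulations of unknown
fidelity — including under realistic nuisance conditions such as degraded RNA
(emulated here as inflated count dispersion).

`mixbench` provides, as a library plus a `mixbench` command-line tool:

- a **simulator** for the titration design: negative-binomial counts with
  gene-specific dispersion (low empirical-Bayes prior degrees of freedom, the
  regime of biological rather than technical noise), degraded replicate
  duplicates, and full ground truth;
- **preprocessing**: CPM expression filtering, TMM normalization and log-CPM
  (validated against edgeR's `calcNormFactors` in the test suite);
- the **gene-wise non-linear mixture model** and its contrast predictions
  (validated against limma's `fitmixture`);
- a reference **moderated-t DE test** with BH FDR, so the benchmark runs
  end-to-end with no external tools, plus ingestion of any method's results
  from a simple TSV schema;
- **benchmark metrics**: sensitivity, recovery rate, inconsistency rate,
  Venn-region overlaps, and RMSE of estimated vs model-predicted log-FCs;
- **linear-mixture deconvolution**: informative-gene filtering, closed-form
  proportion estimation and profile recovery;
- **5′-position read counting** over non-overlapping exon/intron/intergenic
  annotations, with conservative intron/intergenic derived counts.

## The model

For gene *g* and sample *i* with mixing proportion *p*ᵢ of source A,

```
logCPM_gi = log2( p_i·X_g + (1 − p_i)·Y_g ) + ε_gi,    ε_gi ~ (0, φ_g²)
```

where *X*_g and *Y*_g are the gene's concentrations (CPM scale) in the two
pure sources. The mean is linear in the concentrations but the noise lives on
the log scale, so each gene is a small non-linear least-squares problem;
`MixtureModel.fit()` solves all genes simultaneously with a vectorized
Gauss–Newton iteration (step-halving, parameterized in log2 X and log2 Y so
positivity is free). The fit returns `MixtureResults` with per-gene X̂, Ŷ,
the log-ratio M = log2(X̂/Ŷ), the residual SD φ̂ = √(RSS/(n−2)) and
convergence diagnostics. The predicted log-FC between mixture groups at
proportions *p* and *q* is

```
δ̂_g(p, q) = log2( (p·X̂_g + (1−p)·Ŷ_g) / (q·X̂_g + (1−q)·Ŷ_g) ),
```

and a DE method's accuracy is summarized by
RMSE = √{(1/G) Σ_g (logFC_g − δ̂_g(p,q))²}, with the model refitted on the
samples *outside* the compared groups so predictions are independent of the
data being scored. Deconvolution uses the complementary linear structure
Y = (1−p)·N + p·T on the CPM scale.

## Worked example

```python
from mixbench import (simulate_reference_profiles, make_default_design,
                      simulate_mixture_counts, run_benchmark)
from mixbench.preprocess import normalize
from mixbench.mixture import MixtureModel

ref = simulate_reference_profiles(5000, de_fraction=0.65, lfc_sd=2.0, seed=1)
design = make_default_design()                      # 15 good + 5 degraded samples
counts = simulate_mixture_counts(ref, design, lib_size_mean=2e7, seed=1)

good = design.good_only()
expr = normalize(counts.subset_samples(good.sample_ids))
res = MixtureModel.from_normalized(expr, good).fit()
print(res.summary(4))
```

```
Mixture dose-response model (gene-wise non-linear least squares)
================================================================
genes: 5000    samples: 15    proportions: [0.0, 0.25, 0.5, 0.75, 1.0]
converged: 5000/5000    median iterations: 3
median phi_hat: 0.3508    median |M|: 1.4050
----------------------------------------------------------------
               Xhat     Yhat       M  phi_hat  converged  n_iter
gene_id
gene000000  89.8229  23.9415  1.9076   0.3833       True       4
gene000001 127.6132  45.9449  1.4738   0.7964       True       4
gene000002  87.4118 509.9894 -2.5446   0.2023       True       3
gene000003   9.5697   3.8292  1.3214   0.3666       True       4
```

Every gene converges in a handful of iterations; `M` is the estimated
log2-fold-change between the pure sources (gene000002 is ~5.8× higher in
source B) and `phi_hat` the gene's residual log2-scale noise. Benchmarking
the built-in moderated-t method over two comparisons:

```python
report = run_benchmark(counts, design, comparisons=[(1.0, 0.0), (0.75, 0.25)])
print(report.metrics[["comparison", "sensitivity", "recovery",
                      "inconsistency", "rmse"]].round(4).to_string(index=False))
```

```
comparison  sensitivity  recovery  inconsistency    rmse
   100v000         3084    1.0000         0.0000 13.6420
   075v025         1211    0.3855         0.0182  0.3861
```

Read: the pure-vs-pure comparison calls 3084 genes at FDR < 0.05; in the
subtler 75:25-vs-25:75 comparison the method retains 38.6% of those (recovery)
while only 1.8% of its discoveries are absent from the anchor set
(inconsistency). The RMSE column scores each comparison's log-FCs against the
leave-out model predictions; it is large for 100v000 because predicting the
pure contrast from mixed samples alone extrapolates, and small for
interpolated contrasts.

The same stages are available from the shell:

```
mixbench simulate --genes 2000 --lib-size 2e6 --seed 1 --out run/
mixbench fit --counts run/counts.tsv --design run/design.tsv --out run/fit/
mixbench benchmark --counts run/counts.tsv --design run/design.tsv --out run/bench/
mixbench run --config config.yaml --out run/   # full pipeline + manifest
```

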