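# Methods

## The mixture dose-response model

For gene *g* in a sample with mixing proportion *p* of source A, the
expression concentration must be *p·X_g + (1−p)·Y_g*; measurement error is
taken to be additive on the log2 scale with gene-specific standard deviation
φ_g:

    logCPM_gi = log2(p_i X_g + (1−p_i) Y_g) + ε_gi.

Assumptions: the mixing proportions are known exactly; errors are independent
across samples with mean zero; the per-gene error variance does not depend on
the proportion. The model pools all samples in the series, so X̂ and Ŷ are
more precise than pure-sample means, and every pairwise contrast between
mixture groups has a predicted log-FC
δ̂(p,q) = log2{(pX̂+(1−p)Ŷ)/(qX̂+(1−q)Ŷ)}, with δ̂(1,0) = M = log2(X̂/Ŷ).

### Fitting

Each gene is a 2-parameter non-linear least-squares problem. We optimize over
(a, b) = (log2 X, log2 Y) — positivity for free, and the Jacobian is simply
(pX/S, (1−p)Y/S) with S the mixture mean — using Gauss–Newton steps solved in
closed form from the 2×2 normal equations for all genes simultaneously, with
up to 20 step-halvings per iteration and a step cap of 30 log2 units against
near-singular normal equations. Convergence is declared when the relative SSE
decrease falls below `tol` (default 1e-8) within `max_iter` (default 50)
iterations; non-converged genes are flagged and keep their best iterate
rather than being dropped.

Start values come from a linear regression of 2^logCPM on (p, 1−p) without
intercept, which is exact on noise-free data; genes where a coefficient is
non-positive fall back to the mean logCPM of the highest/lowest-proportion
samples. φ̂ = √(RSS/(n−2)), using n−2 residual degrees of freedom for the two
free parameters. Observations are unweighted: the error-variance model is a
single φ_g per gene, so ordinary least squares is the MLE under normality.
The test suite cross-checks the fit against limma's `fitmixture` (agreement
in M to ~1e-4 on noisy data) and against a Nelder–Mead simplex minimizer
per gene.

For scoring a DE comparison, the model is refitted with the compared
samples excluded (`leave_out_fit`), so δ̂ is independent of the data being
scored. Note the asymmetry this creates: interpolated contrasts (e.g.
075v025) are predicted precisely, while the pure contrast predicted from
mixed samples alone is an extrapolation in which M amplifies small errors —
RMSE values for 100v000 are accordingly much larger, and are reported as
computed.

## Preprocessing

Expression filtering keeps genes with CPM above a threshold (default 1) in at
least `min_samples` samples (default 3), computed on raw library sizes with
no prior count; the exon-level preset (0.125 in ≥10 samples) uses the same
code path. Whether filtering should precede or follow normalization is
ambiguous in common practice; we filter on raw CPM and record that in the
pipeline manifest.

TMM factors follow the published trimmed-mean-of-M-values recipe and its
reference implementation's defaults: reference sample by 75th-percentile CPM
closest to the mean; pairwise M/A values excluding genes with a zero in
either sample; double trim by rank (30% on M, 5% on A, floor(n·trim)+1 rule);
inverse-asymptotic-variance weights; factors rescaled to geometric mean 1.
Agreement with edgeR's `calcNormFactors` is exact to machine precision on
test matrices. log-CPM uses log2((count+0.5)/(lib·factor+1)·1e6).

## The synthetic-data generator

The generator emulates a two-source titration: proportions
(1, 0.75, 0.5, 0.25, 0) × 3 replicates, plus a degraded duplicate of
replicate 2 at every proportion (15 good + 5 degraded samples). What it
reproduces, and what it does not:

- **Abundances.** X is log-normal on the CPM scale (meanlog 4, sdlog 1.8 in
  log2 units), giving the several-orders-of-magnitude dynamic range of real
  transcriptomes. A real mixture experiment has no generative model — its
  noise is real — so this is an emulation choice, not a measured quantity.
- **Differential expression.** A configurable fraction of genes receives
  log2(X/Y) drawn from Normal(0, lfc_sd²) truncated away from
  (−threshold, threshold) (default threshold 1); the rest have X = Y. Real
  cell-line pairs have most genes DE to some degree; tests that need sparse
  truth use 10%, benchmark-scale runs use 65%.
- **Counts.** Negative binomial with variance μ + dispersion·μ², so
  dispersion 0 is Poisson. Gene-wise dispersions follow a scaled
  inverse-chi-square around mean 0.05 (BCV ≈ 0.22) with 5 prior degrees of
  freedom — the strongly gene-specific variability regime of a biological-
  noise-dominated experiment (prior df near 5, not near 70 as in technical-
  replicate data). Degradation multiplies a sample's dispersions by a
  constant (default 4): it reproduces the *variance* signature of degraded
  RNA, not its positional 3′ coverage bias, which does not exist at the
  count level.
- **Libraries.** Log-normal library sizes (CV 0.1) around a target mean;
  the design's real depth is tens of millions, and tests/acceptance runs
  scale this down (2e5–2e7) with the law-of-large-numbers checks sized
  accordingly.
- **Determinism.** Each sample draws from an RNG sub-stream spawn-keyed on
  its row index, so changing one sample's parameters (e.g. the degradation
  multiplier) never perturbs another sample's counts, and multiplier 1 makes
  degraded columns distributionally identical to good replicates.

Passing tests on this generator demonstrate correctness of the *analysis
arithmetic* under the stated stochastic model; they cannot certify behaviour
under artefacts the generator omits (positional bias, batch structure,
mapping errors, isoform-level effects).

## Reference DE method and FDR

The built-in method is a moderated t-test on log-CPM: pooled per-gene
variance shrunk toward the across-gene mean s₀² with prior_df = 4 (the
gene-specific-variability regime), t on df_g + prior_df degrees of freedom.
It is harness plumbing — deliberately simple, standing in for external tools
whose results can be ingested from TSV — not a re-implementation of any
published package. BH adjustment delegates to statsmodels' `fdr_bh` behind
the package's own validated surface; the test suite checks it against a
literal step-up implementation.

## Benchmark metrics

Sensitivity = number of genes at FDR < cutoff (strict inequality). Recovery
= |S_anchor ∩ S_subtle| / |S_anchor|; inconsistency = |S_subtle \ S_anchor| /
|S_subtle|. The anchor defaults to pure-vs-pure, the comparison expected to
detect the most genes. Gene universes are intersected before set arithmetic
(dropped genes are logged); rates with empty denominators are reported as
missing, never as 0. Venn-region counts cover 2–5 result sets.

## Deconvolution

Given pure-sample reference profiles N and T on a common CPM scale, a mixed
sample Y = (1−p)N + pT yields the closed-form least-squares estimate
p̂ = ⟨T−N, Y−N⟩/‖T−N‖², clipped to [0,1], over the informative genes
(pure-sample fold-change > 2 or < 0.5 — genes with similar levels in both
sources only dilute the signal; the fold-change is computed on TMM-normalized
CPM means of the pure samples). The T profile is recovered as
(Y−(1−p̂)N)/p̂ with negatives clipped to zero and counted. Estimation is on
the linear CPM scale because the mixture structure is linear in
concentrations; fitting on the log scale would violate it. The unweighted
estimator is dominated by high-abundance genes, so its effective sample size
is far below the masked-gene count; proportion errors of a few percent at
dispersion 0.01 are expected. Reference-free deconvolution (estimating N and
T jointly) is out of scope.

## 5′-position counting

Reads are reduced to their 5′ base — leftmost coordinate on '+', end−1 on
'−' — and assigned to the unique covering interval of a class-partitioned
annotation (exon/intron/intergenic; UTRs are whatever the caller's annotation
encodes). Coordinates are BED-style 0-based half-open throughout. Assignment
is unstranded with respect to the annotation; the read strand only locates
the 5′ end. Lookup is a binary search over per-chromosome sorted starts
(ties impossible by the non-overlap precondition, validated up front).
Derived counts: intron = gene body − gene exon; intergenic = amalgamated
(gene + preceding intergenic region) − gene body; negative differences are
rejected as inconsistent inputs rather than clipped.

## Problem sizes and conditions used by scripts/acceptance.py

- Model inversion: 500 genes, noise-free, 15 samples.
- M recovery: 2000 genes, φ = 0.1, 15 samples.
- DE benchmark: 5000 genes, 65% DE, dispersion 0.05 with prior df 5,
  library size 2e7, 3 simulation replicates; recovery/inconsistency reported
  for the anchored 075v025 pair (always defined at these conditions),
  sensitivity for all four comparisons. At desk-scale depth the reference
  method finds nothing at 050v025/075v050; those sensitivities are reported
  as computed (possibly 0) rather than hidden.
- Degraded substitution: 2000 genes, multiplier 4, sign test over shared
  genes.
- Deconvolution: 4000 genes (≈2200 informative), dispersion 0.01, 10 seeds ×
  3 proportions.

All randomness derives from the `--seed` argument.

## Known limitations

- The simulator's NB noise model is an emulation of the reported variability
  regime, not a fitted model of any real data set.
- The reference DE method has no precision weights and is underpowered
  relative to the specialized tools it stands in for; benchmark numbers
  characterize the harness, not those tools.
- Extrapolated pure-contrast predictions from leave-out fits are unstable
  for extreme-ratio genes (large RMSE for 100v000 is inherent, not a bug).
- Deconvolution assumes the supplied references and the mixed sample share a
  CPM scale; mixing by RNA mass with unequal source totals shifts the
  effective proportion being estimated.
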