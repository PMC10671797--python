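# robustdaa

Robust differential abundance analysis (DAA) of microbiome count data.

Sequencing counts are compositional: only relative abundances are
observed, and real tables are riddled with outliers (a taxon exploding in
a handful of samples) and heavy-tailed variation that violate the
normal-error assumptions of log-linear DAA methods. `robustdaa`
generalizes the CLR-regression approach to DAA into an M-estimation
framework so that the per-taxon regression can use a robust loss —
Huber, Tukey bisquare, or quantile (check) loss — instead of least
squares, and pairs it with winsorization as a preprocessing alternative.

## The model

For taxon *i* in sample *s*, with counts *Y<sub>is</sub>* multinomial
given library size *N<sub>s</sub>* and log-linear absolute abundance
log *X<sub>is</sub>* = *u<sub>s</sub>* α<sub>0i</sub> +
*c<sub>s</sub>*ᵀ β<sub>0i</sub> + ϵ<sub>is</sub>, the centered log-ratio
values

  W<sub>is</sub> = log Y<sub>is</sub> − (1/m) Σ<sub>j</sub> log Y<sub>js</sub>

follow a linear model in the variable of interest *u* and covariates,
with effect α<sub>i</sub> − ᾱ (the per-sample total cancels, leaving a
shared shift ᾱ). Per taxon, `robustdaa` solves

  θ̃<sub>i</sub> = argmin (1/n) Σ<sub>s</sub> L(W<sub>is</sub> −
  z<sub>s</sub>ᵀ θ)

for a chosen loss L, estimates the asymptotic covariance by the plug-in
sandwich (Σ z z ᵀ)⁻¹ · mean ψ²(r̃) / (mean ψ′(r̃))² with ψ = L′, removes
the shift ᾱ by a kernel-density mode estimate of the raw effects
(valid when most taxa are non-differential), tests each bias-corrected
effect with a t statistic on n − d − 2 degrees of freedom, and controls
FDR by Benjamini–Hochberg. Because the robust losses carry a tuning
constant, p-values can be computed over a grid of tunings and aggregated
with the Cauchy combination rule.

The package also ships the full synthetic benchmark the framework is
validated on: log-normal baseline abundances, log-linear effects
weighted toward rare taxa, multinomial read sampling, heavy-tailed error
options (Student-t df 3, recentered log-normal(0, 0.8), recentered
Weibull(0.5, 0.3)), optional confounding, and outlier injection by
20-fold inflation of randomly chosen nonzero counts.

## Worked example

Simulate five replicates with log-normal (heavy-tailed) errors, sparse
signals and 200 taxa × 100 samples, then analyse one replicate with the
Huber pipeline:

```bash
robustdaa simulate --preset case2_sparse --m 200 --n 100 --mu 1.8 \
    --reps 5 --seed 7 --out sim
robustdaa fit --counts sim/rep_000/counts.tsv \
    --metadata sim/rep_000/metadata.tsv --var group --loss huber \
    --out results.tsv
# 2 differential taxa at FDR 0.05 -> results.tsv
```

The top of `results.tsv` sorted by adjusted p-value:

```
    taxon  alpha_tilde  alpha_hat     se   stat  df  pvalue   padj  reject
 taxon_24       1.0227     1.0388 0.2674 3.8845  98  0.0002 0.0235    True
taxon_173       0.8750     0.8911 0.2341 3.8060  98  0.0002 0.0235    True
```

`alpha_tilde` is the raw CLR effect of the group variable, `alpha_hat`
the mode-corrected effect (an estimated log-fold change of absolute
abundance), and `padj` the BH-adjusted p-value. Comparing methods
against the simulation truth across all five replicates:

```bash
robustdaa evaluate --results-dir sim --methods l2,huber --level 0.05 \
    --out summary.tsv
# method  mean_fdr  mean_power
#  huber  0.090000    0.573382
#     l2  0.066667    0.419292
```

Under heavy-tailed errors the Huber loss buys a substantial power gain
over least squares (the l2 rows correspond to the plain CLR-regression
pipeline) at comparable FDR. The same library API is available in
Python via `robustdaa.run_robust_daa`, `robustdaa.SimConfig` /
`build_dataset`, and friends.

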