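# Methods

## Model and procedure

`robustdaa` tests, for each taxon *i*, H₀: αᵢ = 0 in the log-linear
absolute-abundance model log Xᵢₛ = uₛ αᵢ + cₛᵀ βᵢ + ϵᵢₛ, observed only
through multinomial read counts. After the centered log-ratio (CLR)
transform the per-taxon responses satisfy a linear model whose slope is
the *centered* effect αᵢ − ᾱ, with ᾱ the across-taxa mean effect
absorbed by the compositional constraint. The procedure is:

1. **Per-taxon M-estimation.** θ̃ᵢ minimizes (1/n) Σₛ L(Wᵢₛ − zₛᵀθ) with
   zₛ = (uₛ, 1, cₛ). Available losses: squared (l2, closed form), Huber,
   Tukey bisquare (both by IRLS), quantile check loss (statsmodels
   interior-point solver).
2. **Plug-in sandwich variance.** Σ̂ᵢ = (Σ zₛzₛᵀ)⁻¹ · mean ψ²(r̃ᵢₛ/ŝ) /
   (mean ψ′(r̃ᵢₛ/ŝ))² · ŝ², with ψ = L′ and ŝ the robust residual scale.
   For l2 the scale and the constant in ψ(r) = 2r cancel, giving
   (ZᵀZ)⁻¹ · mean r̃². Note the 1/n (not 1/(n−d−2)) normalization of the
   residual moments; see *Known limitations*.
3. **Mode correction.** ᾱ is estimated as −mode({√n α̃ᵢ})/√n via a
   Gaussian-kernel density estimate and subtracted from every α̃ᵢ. This
   identifies αᵢ under the sparsity assumption that most taxa are
   non-differential.
4. **Testing.** Tᵢ = α̂ᵢ/σ̂ᵢ is referred to a t distribution with
   n − d − 2 degrees of freedom (d = number of covariates, excluding
   intercept and u); two-sided p-values are BH-adjusted. With a tuning
   grid, each grid member runs steps 1–3 independently, and the per-taxon
   p-values are aggregated by the Cauchy combination rule **before** the
   single BH pass (combining after per-grid BH would distort ranks).

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| Huber c | 1.345 | 95% normal-theory efficiency at unit scale; grid: 10 values log-spaced on [1.345, 5] |
| bisquare c0 | 4.685 | same 95% calibration; grid: 10 values log-spaced on [4.685, 20] |
| quantile τ | 0.5 | median regression; grid: 0.25–0.75 in steps of 0.05 (11 values) |
| min_depth | 1000 reads | drop shallow samples before analysis |
| min_prevalence | 0.10 | drop taxa observed in < 10% of samples (prevalence exactly at the threshold is kept) |
| winsor quantile τ | off | 0.97 / 0.90 reproduce the winsorized-l2 variants |
| zero_alpha | 0.1 | library-size association test level of the hybrid zero rule |
| FDR level | 0.05 | `reject` flag; 0.1 common for real-data screens |

**Scale handling.** The tuning constants above are calibrated for
unit-scale residuals, so the IRLS loop re-estimates ŝ =
median(|r̃|)/0.6745 (MAD about zero, the convention of standard robust
regression routines) every iteration and applies ψ to r̃/ŝ. IRLS starts
from OLS, converges at max |Δθ| < 1e-8 or 200 iterations, and the
non-convex bisquare is warm-started from the converged Huber fit at the
default c to avoid bad local minima. At the Huber kink and the bisquare
boundary, ψ′ takes its left limit for determinism. A zero MAD
(degenerate residuals) is floored at 1e-12, yielding a zero variance for
exact fits.

**Quantile-loss variance.** ψ′ of the check loss vanishes almost
everywhere, so the sandwich denominator is replaced by the
sparsity-function route: Σ̂ = τ(1−τ) f̂(0)⁻² (Σ zₛzₛᵀ)⁻¹ with f̂(0) a
Gaussian-kernel (Silverman bandwidth) density estimate of the residuals
at zero. The quantile pipeline's small-sample FDR inflation is a known
weakness of this plug-in, not something the package attempts to mask.

**Mode estimator.** Gaussian KDE with Silverman bandwidth
h = 0.9·min(sd, IQR/1.34)·m^(−1/5), argmax over a 512-point grid
spanning [min − 3h, max + 3h], ties toward the smallest abscissa. If
min(sd, IQR/1.34) = 0 with non-identical values (heavy ties), the other
scale is used; identical values return themselves. The estimator choice
is recorded in the result metadata so alternates can be compared.

## Preprocessing choices

Processing order: filter samples → filter taxa → (optional) winsorize →
zero replacement → CLR. Winsorizing raw counts before zero replacement
means pseudo-counts are never clipped. Zero replacement runs only when
the table actually contains zeros.

- **Hybrid zero rule.** log Nₛ is regressed on [1, u, C] (covariates
  included — the rule should not mistake a covariate-driven depth
  gradient for an effect of u); a two-sided t-test p < 0.1 on u's
  coefficient selects depth-scaled imputation, otherwise the 0.5
  pseudo-count. The library sizes used are those of the retained samples
  *before* taxa filtering or winsorization: depth is a sequencing
  property, not a function of the analysis subset.
- **Imputation constant.** Zeros of taxon *i* become
  0.5·Nₛ/max{Nₖ : Yᵢₖ = 0}, keeping imputed values on the half-count
  scale of the pseudo-count alternative; `half_factor=False` drops the
  0.5 for users who prefer the bare fraction.
- **Winsorization quantile.** The τ-quantile is the inverted-CDF
  (order-statistic) value, not the interpolated one: clipping at an
  interpolated quantile lowers the quantile of the clipped data, so
  winsorization would not be idempotent; with an order statistic it is
  exactly idempotent, and the clip value is always an observed count.
- Winsorized values are kept fractional — downstream CLR only needs
  positivity.

## Synthetic-data generator

The generator emulates a two-group (optionally confounded) 16S-style
study: baseline log-abundances log X*ᵢₛ ~ N(βᵢ*, σᵢ*²) set each taxon's
mean relative abundance π̄ᵢ*; differential taxa are Bernoulli(p_γ) draws
whose effect log(f·μ) is inflated by (5·10⁻³/π̄ᵢ*)^(1/3) for rare taxa
(and f = 2 when n < 100, else 1) so power is not dominated by abundant
taxa; errors are normal(0, σᵢ*²) or heavy-tailed (Student-t₃;
log-normal(0, 0.8) and Weibull(0.5, 0.3) recentered by their
*theoretical* means so draws stay i.i.d.); counts are multinomial in the
true proportions with depths Nₛ ~ round(LogNormal(log 10⁴, 0.5²));
outliers are injected *after* the multinomial draw by 20-fold inflation
of round(ρ·m) uniformly chosen nonzero cells — library sizes are
recomputed, so one injected cell perturbs the CLR of every taxon in that
sample, which is exactly the mechanism under study.

The baseline hyper-distributions (βᵢ* ~ N(0, 2²), σᵢ* ~ U(0.5, 2), the
depth law) are the package's own choices, picked to give a realistic
rank-abundance skew and depth spread; they are fully overridable, e.g.
with parameters estimated from a user's own dataset. What the generator
does **not** emulate: taxon–taxon ecological correlation, zero inflation
beyond multinomial sampling, batch effects, or phylogenetic structure —
so passing benchmarks here demonstrates correctness of the machinery and
the direction of the robustness gains, not performance guarantees on any
particular real cohort.

Replicate seeds derive deterministically from (master seed, setting,
replicate) via `subseed`, so every benchmark is exactly reproducible.

## Benchmark problem sizes

The validation suite runs the efficiency Monte Carlo at its full design
(2000 replicates, n = 500) and the pipeline-level studies at desk scale:
null calibration at m = 100, n = 50 with 200 replicates; FDR control at
m = 500, n = 200 with 50 replicates; the outlier ladder at m = 200,
n = 100 with 16 matched replicates per ρ; the heavy-tail power
comparison at m = 300, n = 200 with 20 matched replicates. Directional
comparisons use matched seeds and paired standard errors, which is what
makes small replicate counts informative.

## Known limitations

- The plug-in variance uses 1/n residual moments as written, not a
  residual-df correction. Together with the noise of the kernel-mode
  correction this makes raw p-values mildly anticonservative in small
  samples (measured ≈0.06 exceedance at the 0.05 threshold for n = 50,
  m = 100); BH-level FDR control at conventional levels still holds in
  the benchmark suite. Users analysing very small cohorts should prefer
  FDR-level interpretation over raw p-values.
- The quantile-loss pipeline trades power and FDR control for median
  interpretability; it is included for completeness, not recommended.
- Mixed-effects / longitudinal designs are out of scope, as are
  normalization-based alternatives (TMM/RLE/CSS/GMPR) and wrappers
  around other DAA tools.
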