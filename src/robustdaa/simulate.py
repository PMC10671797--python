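"""Synthetic microbiome data with known differential-abundance truth.

The generator follows a log-linear absolute-abundance model read out
through multinomial sequencing:

1. baseline log-abundances log X*_is ~ N(beta*_i, sigma*_i^2) define the
   mean relative abundance pi_bar*_i of each taxon;
2. a Bernoulli(p_gamma) indicator gamma_i marks differential taxa, whose
   log-fold effect alpha_i = mu_i gamma_i is inflated for rare taxa
   (pi_bar* <= 5e-3) so that detection power is not dominated by the
   abundant ones;
3. the condition u_s is Bernoulli(0.5), or logistic in two confounders
   (c1 ~ Bern(0.5), c2 ~ N(0,1)) when a confounded design is requested;
4. log X_is = beta_i0 + u_s alpha_i [+ c_s' beta_i] + eps_is with normal
   or heavy-tailed errors (Student-t df 3; log-normal(0, 0.8) recentered;
   Weibull(0.5, 0.3) recentered);
5. counts are multinomial draws of N_s reads from the sample's true
   proportions, optionally followed by 20-fold inflation of randomly
   chosen nonzero cells ("outlier injection").

Baseline hyper-distributions emulate a stool-like rank-abundance skew and
depth spread; every parameter is overridable through :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CountTable, DesignMatrix

RARE_THRESHOLD = 5e-3
ERROR_FAMILIES = ("normal", "t3", "lognormal", "weibull")

#: six signal strengths for power curves, evenly spaced on [1.05, 2]
SIGNAL_GRID = tuple(np.linspace(1.05, 2.0, 6))


def subseed(master: int, *keys: int) -> int:
    """Deterministic child seed below 2**31 from a master seed and indices."""
    ss = np.random.SeedSequence([int(master), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    m: int = 500
    n: int = 100
    p_gamma: float = 0.05
    mu: float = 1.5
    confounded: bool = False
    error_family: str = "normal"
    rho: float = 0.0
    fold: float = 20.0
    # baseline hyper-distributions (log-abundance means/sds and depths)
    beta_star_mean: float = 0.0
    beta_star_sd: float = 2.0
    sigma_star_low: float = 0.5
    sigma_star_high: float = 2.0
    depth_meanlog: float = float(np.log(1e4))
    depth_sdlog: float = 0.5
    # factor applied to mu for small samples; None -> 2 if n < 100 else 1
    small_sample_factor: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_gamma <= 1:
            raise ValueError("p_gamma must be in [0, 1]")
        if self.mu < 1:
            raise ValueError("mu must be >= 1")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        if self.error_family not in ERROR_FAMILIES:
            raise ValueError(f"unknown error family: {self.error_family!r}")


@dataclass
class Baseline:
    beta_star: np.ndarray
    sigma_star: np.ndarray
    pi_bar: np.ndarray


@dataclass
class SimDataset:
    """Generated counts plus the ground truth needed for evaluation."""

    counts: CountTable
    design: DesignMatrix
    truth: pd.DataFrame  # gamma, alpha (and beta1, beta2 when confounded)
    proportions: np.ndarray  # true pi_is, columns sum to 1
    abundance: np.ndarray  # latent X_is
    baseline: Baseline
    outlier_mask: np.ndarray  # boolean (m, n)
    config: SimConfig


def sample_baseline(config: SimConfig, seed=None) -> Baseline:
    """Draw baseline parameters and the mean relative abundances pi_bar*."""
    if config.m < 2:
        raise ValueError("need at least 2 taxa")
    rng = _as_rng(config.seed if seed is None else seed)
    beta_star = rng.normal(config.beta_star_mean, config.beta_star_sd, config.m)
    sigma_star = rng.uniform(config.sigma_star_low, config.sigma_star_high, config.m)
    log_x = beta_star[:, None] + sigma_star[:, None] * rng.standard_normal(
        (config.m, config.n)
    )
    x = np.exp(log_x)
    pi = x / x.sum(axis=0, keepdims=True)
    return Baseline(beta_star=beta_star, sigma_star=sigma_star, pi_bar=pi.mean(axis=1))


def assign_effects(
    pi_bar: np.ndarray,
    mu: float,
    n: int,
    p_gamma: float,
    seed=None,
    small_sample_factor: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Differential indicators gamma_i ~ Bern(p_gamma) and effects alpha_i.

    The per-taxon log effect is mu_i = log(f mu) for abundant taxa
    (pi_bar* > 5e-3) and log(f mu (5e-3 / pi_bar*)^(1/3)) for rare ones,
    with f = 2 for small samples (n < 100) and 1 otherwise.
    """
    pi_bar = np.asarray(pi_bar, dtype=float)
    if (pi_bar <= 0).any():
        raise ValueError("pi_bar must be strictly positive")
    if mu < 1:
        raise ValueError("mu must be >= 1")
    rng = _as_rng(seed)
    f = small_sample_factor if small_sample_factor is not None else (2.0 if n < 100 else 1.0)
    gamma = rng.binomial(1, p_gamma, pi_bar.size)
    mu_i = np.where(
        pi_bar > RARE_THRESHOLD,
        np.log(f * mu),
        np.log(f * mu * (RARE_THRESHOLD / pi_bar) ** (1.0 / 3.0)),
    )
    return gamma, mu_i * gamma


def sample_design(
    n: int, confounded: bool = False, seed=None, max_resample: int = 100
) -> DesignMatrix:
    """Draw the condition u (and confounders c1, c2 when requested).

    Unconfounded: u ~ Bern(0.5).  Confounded: c1 ~ Bern(0.5), c2 ~ N(0,1),
    u ~ Bern(logistic(0.5 c1 + 0.5 c2)).  A degenerate draw (constant u, or
    constant c1 under confounding) is resampled up to ``max_resample`` times.
    """
    rng = _as_rng(seed)
    for _ in range(max_resample):
        if confounded:
            c1 = rng.binomial(1, 0.5, n).astype(float)
            c2 = rng.standard_normal(n)
            p = 1.0 / (1.0 + np.exp(-0.5 * c1 - 0.5 * c2))
            u = rng.binomial(1, p).astype(float)
            if np.ptp(u) == 0 or np.ptp(c1) == 0:
                continue
            return DesignMatrix(u=u, C=np.column_stack([c1, c2]),
                                covariate_names=("c1", "c2"))
        u = rng.binomial(1, 0.5, n).astype(float)
        if np.ptp(u) == 0:
            continue
        return DesignMatrix(u=u)
    raise RuntimeError("could not draw a non-degenerate design")


def sample_errors(
    family: str, shape: tuple[int, int], seed=None, sigma_star: np.ndarray | None = None
) -> np.ndarray:
    """Error matrix eps_is for the log-abundance model.

    normal draws N(0, sigma*_i^2) rowwise (requires ``sigma_star``); t3 is
    Student-t with 3 df; lognormal is LogNormal(0, 0.8) minus its mean
    exp(0.32); weibull is Weibull(shape 0.5, scale 0.3) minus its mean
    0.3 * Gamma(3) = 0.6.  The heavy-tailed families are recentered with the
    theoretical mean so draws remain i.i.d.
    """
    rng = _as_rng(seed)
    if family == "normal":
        if sigma_star is None:
            raise ValueError("normal errors need per-taxon sigma_star")
        sigma_star = np.asarray(sigma_star, dtype=float)
        return sigma_star[:, None] * rng.standard_normal(shape)
    if family == "t3":
        return rng.standard_t(3, shape)
    if family == "lognormal":
        return rng.lognormal(0.0, 0.8, shape) - np.exp(0.8**2 / 2.0)
    if family == "weibull":
        # scale * Gamma(1 + 1/shape) = 0.3 * Gamma(3) = 0.6
        return 0.3 * rng.weibull(0.5, shape) - 0.6
    raise ValueError(f"unknown error family: {family!r}")


def inject_outliers(
    table: CountTable, rho: float, fold: float = 20.0, seed=None
) -> tuple[CountTable, np.ndarray]:
    """Inflate round(rho * m) randomly chosen nonzero counts ``fold``-fold.

    Cells are sampled uniformly without replacement from the nonzero cells
    of the observed table; the returned boolean mask marks the modified
    cells for truth-aware evaluation.  Library sizes change accordingly, so
    an injected outlier perturbs the CLR of every taxon in that sample.
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    mask = np.zeros((table.m, table.n), dtype=bool)
    k = int(round(rho * table.m))
    if k == 0:
        return table.copy(), mask
    vals = table.counts.to_numpy().copy()
    nz_i, nz_s = np.nonzero(vals)
    if k > nz_i.size:
        raise ValueError(f"requested {k} outliers but only {nz_i.size} nonzero cells")
    rng = _as_rng(seed)
    pick = rng.choice(nz_i.size, size=k, replace=False)
    vals[nz_i[pick], nz_s[pick]] *= fold
    mask[nz_i[pick], nz_s[pick]] = True
    out = CountTable(
        pd.DataFrame(vals, index=table.counts.index, columns=table.counts.columns)
    )
    return out, mask


def build_dataset(config: SimConfig) -> SimDataset:
    """Compose baseline, effects, design, errors and multinomial sampling."""
    rng = _as_rng(config.seed)
    base = sample_baseline(config, seed=rng)
    gamma, alpha = assign_effects(
        base.pi_bar, config.mu, config.n, config.p_gamma, seed=rng,
        small_sample_factor=config.small_sample_factor,
    )
    design = sample_design(config.n, config.confounded, seed=rng)

    eps = sample_errors(
        config.error_family, (config.m, config.n), seed=rng,
        sigma_star=base.sigma_star if config.error_family == "normal" else None,
    )
    log_x = base.beta_star[:, None] + alpha[:, None] * design.u[None, :] + eps
    truth = {"gamma": gamma, "alpha": alpha, "beta0": base.beta_star}
    if config.confounded:
        beta1 = rng.normal(1.0, 1.0, config.m)
        beta2 = rng.normal(2.0, 1.0, config.m)
        log_x += beta1[:, None] * design.C[:, 0][None, :]
        log_x += beta2[:, None] * design.C[:, 1][None, :]
        truth["beta1"] = beta1
        truth["beta2"] = beta2

    x = np.exp(log_x)
    pi = x / x.sum(axis=0, keepdims=True)
    depths = np.round(
        rng.lognormal(config.depth_meanlog, config.depth_sdlog, config.n)
    ).astype(int)
    depths = np.maximum(depths, 1)
    counts = np.empty((config.m, config.n))
    for s in range(config.n):
        counts[:, s] = rng.multinomial(depths[s], pi[:, s])

    taxa = [f"taxon_{i+1}" for i in range(config.m)]
    samples = [f"sample_{s+1}" for s in range(config.n)]
    table = CountTable(pd.DataFrame(counts, index=taxa, columns=samples))
    design.sample_ids = samples

    if config.rho > 0:
        table, mask = inject_outliers(table, config.rho, config.fold, seed=rng)
    else:
        mask = np.zeros((config.m, config.n), dtype=bool)

    return SimDataset(
        counts=table,
        design=design,
        truth=pd.DataFrame(truth, index=taxa),
        proportions=pi,
        abundance=x,
        baseline=base,
        outlier_mask=mask,
        config=config,
    )


def evaluate_fdr_power(result, truth_gamma: Sequence[int], level: float = 0.05):
    """Empirical false discovery proportion and power of a result table.

    ``result`` may be a DAAResult or an array of BH-adjusted p-values
    aligned with ``truth_gamma``.  Discoveries are padj <= level; FDR uses
    the max(|D|, 1) convention and power is reported as NaN when there are
    no true signals.
    """
    padj = np.asarray(
        result.table["padj"] if hasattr(result, "table") else result, dtype=float
    )
    gamma = np.asarray(truth_gamma, dtype=int)
    if padj.size != gamma.size:
        raise ValueError("result and truth have different lengths")
    discovered = padj <= level
    n_disc = int(discovered.sum())
    n_false = int((discovered & (gamma == 0)).sum())
    n_signal = int((gamma == 1).sum())
    fdr = n_false / max(n_disc, 1)
    power = (
        float((discovered & (gamma == 1)).sum()) / n_signal if n_signal else float("nan")
    )
    return fdr, power


def metadata_frame(dataset: SimDataset) -> pd.DataFrame:
    """Sample metadata (group plus any confounders) for the DAA driver."""
    meta = pd.DataFrame({"group": dataset.design.u}, index=dataset.counts.sample_ids)
    for j, name in enumerate(dataset.design.covariate_names):
        meta[name] = dataset.design.C[:, j]
    return meta
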