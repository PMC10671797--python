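"""Quality filtering, zero handling, winsorization and the CLR transform.

The preprocessing chain for microbiome count tables is: drop shallow
samples, drop rare taxa, optionally winsorize each taxon at a quantile,
replace zeros (pseudo-count or depth-scaled imputation, chosen by a
library-size association test), then take the centered log-ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import CLRMatrix, CountTable, DegenerateDesignError, DesignMatrix, EmptyDataError

PSEUDO_COUNT = "pseudo_count"
IMPUTATION = "imputation"


def filter_samples(table: CountTable, min_depth: int = 1000) -> CountTable:
    """Keep samples with library size N_s >= ``min_depth``, preserving order."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    keep = table.library_sizes >= min_depth
    if not keep.any():
        raise EmptyDataError(f"no sample has depth >= {min_depth}")
    return CountTable(table.counts.loc[:, keep[keep].index])


def filter_taxa(table: CountTable, min_prevalence: float = 0.10) -> CountTable:
    """Keep taxa observed (nonzero) in at least ``min_prevalence`` of samples.

    A taxon present in strictly less than ``min_prevalence * n`` samples is
    removed; prevalence exactly at the threshold is kept.
    """
    if not 0 < min_prevalence <= 1:
        raise ValueError("min_prevalence must be in (0, 1]")
    prevalence = (table.counts > 0).mean(axis=1)
    keep = prevalence >= min_prevalence
    if not keep.any():
        raise EmptyDataError("prevalence filter removed all taxa")
    return CountTable(table.counts.loc[keep[keep].index])


def select_zero_strategy(
    table: CountTable, design: DesignMatrix, alpha: float = 0.1
) -> str:
    """Choose the zero-handling strategy by testing depth/covariate association.

    Regresses log N_s on [1, u, C] by least squares and takes the two-sided
    t-test p-value of the ``u`` coefficient.  When the library size is
    associated with the variable of interest (p < ``alpha``), a constant
    pseudo-count would induce a spurious signal, so depth-scaled imputation
    is selected instead.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if np.ptp(design.u) == 0:
        raise DegenerateDesignError("variable of interest is constant")
    log_n = np.log(table.library_sizes.to_numpy(dtype=float))
    X = np.column_stack([np.ones(design.n), design.u, design.C])
    res = sm.OLS(log_n, X).fit()
    p_u = float(res.pvalues[1])
    return IMPUTATION if p_u < alpha else PSEUDO_COUNT


def replace_zeros(
    table: CountTable, strategy: str, half_factor: bool = True
) -> CountTable:
    """Make every entry strictly positive.

    ``pseudo_count``: add 0.5 to all counts.  ``imputation``: for each taxon
    with zeros, replace each zero entry (i, s) by ``f * N_s / max{N_k : Y_ik = 0}``
    where f = 0.5 (or 1 with ``half_factor=False``), so samples with larger
    library sizes receive larger imputed fractions; nonzero entries and
    zero-free taxa are untouched.
    """
    counts = table.counts.copy()
    if strategy == PSEUDO_COUNT:
        counts += 0.5
    elif strategy == IMPUTATION:
        factor = 0.5 if half_factor else 1.0
        N = table.library_sizes.to_numpy(dtype=float)
        vals = counts.to_numpy()
        for i in range(vals.shape[0]):
            zero = vals[i] == 0
            if zero.any():
                vals[i, zero] = factor * N[zero] / N[zero].max()
        counts = pd.DataFrame(vals, index=counts.index, columns=counts.columns)
    else:
        raise ValueError(f"unknown zero strategy: {strategy!r}")
    return CountTable(counts)


def winsorize(table: CountTable, tau: float) -> CountTable:
    """Clip each taxon's counts at its empirical ``tau`` quantile.

    Uses the inverted-CDF (order-statistic) quantile, so q_i(tau) is always
    an observed value and winsorization is exactly idempotent; entries above
    q_i(tau) are replaced by q_i(tau).  tau = 1 is the identity.
    """
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    vals = table.counts.to_numpy().copy()
    q = np.quantile(vals, tau, axis=1, method="lower")
    vals = np.minimum(vals, q[:, None])
    return CountTable(
        pd.DataFrame(vals, index=table.counts.index, columns=table.counts.columns)
    )


def clr_transform(table: CountTable) -> CLRMatrix:
    """Centered log-ratio: W_is = log Y_is - mean_j log Y_js, per sample.

    Requires a strictly positive table (apply zero handling first).  Each
    sample column of W sums to zero, and W is invariant to rescaling a
    sample column by any positive constant.
    """
    vals = table.counts.to_numpy()
    if (vals <= 0).any():
        raise ValueError(
            "CLR requires strictly positive counts; apply replace_zeros first"
        )
    logs = np.log(vals)
    W = logs - logs.mean(axis=0, keepdims=True)
    return CLRMatrix(
        W=pd.DataFrame(W, index=table.counts.index, columns=table.counts.columns)
    )
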