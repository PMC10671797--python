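"""Shared fixtures and an independent reference implementation.

``reference_l2_pipeline`` is a deliberately straight-line reimplementation
of the CLR + OLS + mode-correction + t-test + BH recipe, kept free of any
robustdaa imports so it can serve as an oracle for the l2 pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from robustdaa import CountTable, DesignMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20231026)


@pytest.fixture
def small_table():
    """4 taxa x 5 samples with a couple of zeros."""
    counts = pd.DataFrame(
        [
            [10, 0, 30, 12, 7],
            [5, 8, 2, 0, 3],
            [100, 120, 90, 80, 110],
            [1, 2, 3, 4, 5],
        ],
        index=[f"t{i}" for i in range(4)],
        columns=[f"s{j}" for j in range(5)],
    )
    return CountTable(counts)


@pytest.fixture
def simple_design():
    return DesignMatrix(u=np.array([0.0, 1.0, 0.0, 1.0, 1.0]))


def reference_l2_pipeline(counts: np.ndarray, u: np.ndarray, C: np.ndarray):
    """Straight-line CLR + OLS + mode correction + t-test + BH.

    ``counts`` must contain at least one zero (a 0.5 pseudo-count is always
    added).  Returns (alpha_hat, pvalues, padj).
    """
    y = counts + 0.5
    logs = np.log(y)
    W = logs - logs.mean(axis=0, keepdims=True)  # (m, n)
    n = u.size
    d = C.shape[1]
    Z = np.column_stack([u, np.ones(n), C])
    theta, *_ = np.linalg.lstsq(Z, W.T, rcond=None)  # (d+2, m)
    alpha = theta[0]
    resid = W.T - Z @ theta  # (n, m)
    ZtZ_inv = np.linalg.inv(Z.T @ Z)
    sigma2 = ZtZ_inv[0, 0] * (resid**2).mean(axis=0)

    vals = np.sqrt(n) * alpha
    sd = vals.std(ddof=1)
    q75, q25 = np.percentile(vals, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34)
    if spread <= 0:
        spread = max(sd, (q75 - q25) / 1.34)
    h = 0.9 * spread * vals.size ** (-0.2)
    grid = np.linspace(vals.min() - 3 * h, vals.max() + 3 * h, 512)
    dens = sps.norm.pdf((grid[:, None] - vals[None, :]) / h).sum(axis=1)
    mode = grid[int(np.argmax(dens))]
    alpha_hat = alpha - mode / np.sqrt(n)

    tstat = alpha_hat / np.sqrt(sigma2)
    p = 2.0 * sps.t.sf(np.abs(tstat), n - d - 2)

    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    padj = np.empty(m)
    padj[order] = np.minimum(adj, 1.0)
    return alpha_hat, p, padj


def random_positive_table(rng: np.random.Generator, m: int = 25, n: int = 30):
    """Random count matrix with every taxon observed and some zeros."""
    counts = rng.poisson(8.0, size=(m, n)).astype(float)
    counts[rng.random((m, n)) < 0.15] = 0.0
    counts[:, 0] = np.maximum(counts[:, 0], 1.0)  # every taxon observed once
    counts[0, 1] = 0.0  # guarantee at least one zero
    return counts
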