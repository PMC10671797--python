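"""Core data containers for the differential abundance pipeline.

A :class:`CountTable` holds a taxa-by-sample read count matrix together with
its library sizes (per-sample totals).  A :class:`DesignMatrix` holds the
per-sample variable of interest ``u`` and an optional covariate block ``C``;
the model matrix ``Z = [u, 1, C]`` always carries an implicit intercept.
A :class:`CLRMatrix` is the centered log-ratio transform of a strictly
positive count table, with a provenance record of the preprocessing that
produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class EmptyDataError(ValueError):
    """Raised when filtering or validation leaves no usable data."""


class DegenerateDesignError(ValueError):
    """Raised when the model matrix [1, u, C] is rank deficient or too small."""


@dataclass
class CountTable:
    """Taxa-by-sample count matrix.

    Parameters
    ----------
    counts
        DataFrame with taxa as rows and samples as columns.  Raw input
        entries are nonnegative integers; after zero replacement or
        winsorization entries may be fractional but stay nonnegative.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        self.counts = self.counts.astype(float)
        if self.counts.shape[0] < 1 or self.counts.shape[1] < 1:
            raise EmptyDataError("count table has no taxa or no samples")
        vals = self.counts.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("count table contains non-finite entries")
        if (vals < 0).any():
            raise ValueError("count table contains negative entries")

    @property
    def m(self) -> int:
        """Number of taxa."""
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.counts.shape[1]

    @property
    def taxon_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample totals N_s, always recomputed from the current counts."""
        return self.counts.sum(axis=0)

    def copy(self) -> "CountTable":
        return CountTable(self.counts.copy())


@dataclass
class DesignMatrix:
    """Per-sample design: variable of interest ``u`` plus covariates ``C``.

    The model matrix is ``Z = [u, 1, C]`` (u first so that the coefficient
    of interest is always index 0).  ``d`` counts the covariate columns,
    excluding the intercept and ``u``, so the residual degrees of freedom
    of the per-taxon regressions are ``n - d - 2``.
    """

    u: np.ndarray
    C: np.ndarray | None = None
    sample_ids: Sequence | None = None
    covariate_names: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float).ravel()
        n = self.u.size
        if self.C is None:
            self.C = np.empty((n, 0))
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim == 1:
            self.C = self.C[:, None]
        if self.C.shape[0] != n:
            raise ValueError("u and C have inconsistent sample counts")
        if n <= self.d + 2:
            raise DegenerateDesignError(
                f"need n > d + 2 for positive residual df (n={n}, d={self.d})"
            )
        if np.linalg.matrix_rank(self.Z) < self.Z.shape[1]:
            raise DegenerateDesignError(
                "[1, u, C] is rank deficient (constant u or collinear covariates?)"
            )

    @property
    def n(self) -> int:
        return self.u.size

    @property
    def d(self) -> int:
        return self.C.shape[1]

    @property
    def Z(self) -> np.ndarray:
        """Model matrix [u, 1, C] of shape (n, d + 2)."""
        return np.column_stack([self.u, np.ones(self.n), self.C])

    @property
    def df_resid(self) -> int:
        return self.n - self.d - 2


@dataclass
class CLRMatrix:
    """Centered log-ratio values W (taxa x samples) plus provenance."""

    W: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.W.shape[0]

    @property
    def n(self) -> int:
        return self.W.shape[1]
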