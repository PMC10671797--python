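"""Readers and writers for count tables, metadata and result tables.

Counts are taxa-by-sample TSV/CSV with the taxon identifier in the first
column and sample identifiers in the header.  Metadata is a TSV/CSV whose
first column holds sample identifiers matching the count headers.  A
minimal BIOM 2.1 (HDF5) reader is provided when h5py is available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountTable
from .inference import DAAResult


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(path: str | Path) -> CountTable:
    """Read a taxa-by-sample count table from TSV (default) or CSV."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return CountTable(df)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata indexed by the first (sample identifier) column."""
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), index_col=0)


def read_biom(path: str | Path) -> CountTable:
    """Read a BIOM 2.1 HDF5 table (observations x samples, CSR layout)."""
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as f:
        taxa = [t.decode() if isinstance(t, bytes) else str(t) for t in f["observation/ids"][:]]
        samples = [s.decode() if isinstance(s, bytes) else str(s) for s in f["sample/ids"][:]]
        grp = f["observation/matrix"]
        mat = csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(taxa), len(samples)),
        )
    return CountTable(pd.DataFrame(mat.toarray(), index=taxa, columns=samples))


def write_counts(table: CountTable, path: str | Path) -> None:
    path = Path(path)
    table.counts.to_csv(path, sep=_sep_for(path))


def write_result(result: DAAResult, path: str | Path) -> None:
    """Write the per-taxon result TSV plus a JSON sidecar of run metadata."""
    path = Path(path)
    result.table.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(_jsonable(result.metadata), fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
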