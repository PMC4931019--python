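"""File formats: dense CSV matrices, undirected edge lists, membership vectors.

All indices are 0-based, in files as in memory.  Dense matrices are plain
comma-separated numbers with no header; edge lists are two-column TSV with
one row per undirected edge (i < j); memberships are one label per line.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_dense_csv",
    "read_dense_csv",
    "write_edge_list",
    "read_edge_list",
    "write_membership",
    "read_membership",
    "write_results",
]

_FLOAT_FMT = "%.12g"


def write_dense_csv(M: np.ndarray, path: str | Path) -> None:
    M = np.asarray(M)
    fmt = "%d" if np.issubdtype(M.dtype, np.integer) else _FLOAT_FMT
    np.savetxt(path, M, fmt=fmt, delimiter=",")


def read_dense_csv(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def write_edge_list(K: np.ndarray, path: str | Path) -> None:
    """Write the upper-triangle edges (i < j) of a symmetric 0/1 matrix as TSV."""
    K = np.asarray(K)
    i, j = np.nonzero(np.triu(K, k=1))
    np.savetxt(path, np.column_stack([i, j]), fmt="%d", delimiter="\t")


def read_edge_list(path: str | Path, S: int) -> np.ndarray:
    """Rebuild the symmetric adjacency from an undirected edge-list TSV."""
    edges = np.atleast_2d(np.loadtxt(path, delimiter="\t", dtype=int))
    K = np.zeros((S, S), dtype=np.int8)
    if edges.size:
        K[edges[:, 0], edges[:, 1]] = 1
        K[edges[:, 1], edges[:, 0]] = 1
    return K


def write_membership(membership: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(membership, dtype=int), fmt="%d")


def read_membership(path: str | Path) -> np.ndarray:
    return np.atleast_1d(np.loadtxt(path, dtype=int))


def write_results(obj, path: str | Path) -> None:
    """Write a sweep/spectrum table as CSV or a spectral support as JSON.

    Tables keep their column order with floats at 12 significant digits;
    supports round-trip losslessly through JSON.
    """
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif hasattr(obj, "case_label"):  # SpectralSupport
        doc = asdict(obj)
        doc["ellipses"] = [list(e) for e in doc["ellipses"]]
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
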