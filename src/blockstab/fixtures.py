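"""Small deterministic test inputs.

These are tiny graphs with known modularity (two disjoint cliques have
Q = 1 - beta = 1/2 for equal groups; a complete bipartite graph has
Q = -beta = -1/2) plus miniature stand-ins for the three empirical network
shapes (contact, food web, pollination) and one sampled block-structured
adjacency.  Written as plain-text files; byte-identical for a fixed seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import matrix_io
from .topology import BlockSpec, sample_adjacency

__all__ = ["make_fixtures", "two_clique_graph", "complete_bipartite_graph"]


def two_clique_graph(n_per_clique: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Two disjoint cliques of equal size; returns (adjacency, membership)."""
    n = n_per_clique
    block = np.ones((n, n), dtype=np.int8) - np.eye(n, dtype=np.int8)
    K = np.zeros((2 * n, 2 * n), dtype=np.int8)
    K[:n, :n] = block
    K[n:, n:] = block
    membership = np.r_[np.ones(n, dtype=int), np.full(n, 2)]
    return K, membership


def complete_bipartite_graph(n_per_side: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Complete bipartite graph across two equal groups."""
    n = n_per_side
    K = np.zeros((2 * n, 2 * n), dtype=np.int8)
    K[:n, n:] = 1
    K[n:, :n] = 1
    membership = np.r_[np.ones(n, dtype=int), np.full(n, 2)]
    return K, membership


def make_fixtures(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture set and return {name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}

    def emit(name: str, writer, *args) -> None:
        path = outdir / name
        writer(*args, path)
        paths[name] = path

    K, g = two_clique_graph()
    emit("two_clique.csv", matrix_io.write_dense_csv, K)
    emit("two_clique_membership.csv", matrix_io.write_membership, g)

    K, g = complete_bipartite_graph()
    emit("bipartite.csv", matrix_io.write_dense_csv, K)
    emit("bipartite_membership.csv", matrix_io.write_membership, g)

    # contact-style: symmetric Erdos-Renyi graph
    n = 30
    upper = np.triu(rng.random((n, n)) < 0.2, k=1).astype(np.int8)
    emit("contact.csv", matrix_io.write_dense_csv, upper + upper.T)

    # foodweb-style: directed acyclic (cascade) adjacency, A_ij=1: j preys on i
    A = np.triu((rng.random((n, n)) < 0.15), k=1).astype(np.int8)
    emit("foodweb.csv", matrix_io.write_dense_csv, A)

    # pollination-style: rectangular plants x pollinators incidence
    emit(
        "pollination.csv",
        matrix_io.write_dense_csv,
        (rng.random((12, 18)) < 0.25).astype(np.int8),
    )

    # one sampled block-structured adjacency
    spec = BlockSpec(S=60, alpha=0.5, C=0.2, Q=0.3)
    sub = int(rng.integers(2**31))
    emit("block_S60.csv", matrix_io.write_dense_csv, sample_adjacency(spec, sub).entries)
    emit("block_S60_membership.csv", matrix_io.write_membership, spec.membership)
    return paths
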