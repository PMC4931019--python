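"""Block-structured adjacency matrices.

A community of ``S`` species is split into two subsystems: the first
``round(alpha * S)`` species form the smaller group (``alpha <= 1/2``), the
rest the larger one.  Species in the same subsystem are linked with
probability ``C_w`` (within-subsystem connectance), species in different
subsystems with probability ``C_b``.  Equivalently the ensemble can be
parameterized by the overall connectance ``C`` and the modularity

    Q = L_w / L - beta,

where ``L_w`` is the number of within-subsystem edges, ``L`` the total
number of edges, and ``beta = alpha**2 + (1 - alpha)**2`` is the expected
within fraction under the Erdos-Renyi reference model.  ``Q > 0`` means
modular (edges concentrate within groups), ``Q < 0`` anti-modular /
bipartite-leaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BlockSpec",
    "AdjacencyMatrix",
    "within_fraction",
    "connectances_from_modularity",
    "modularity_bounds",
    "sample_adjacency",
    "measure_modularity",
]


class ModularityRangeError(ValueError):
    """Raised when Q is not attainable for the given (alpha, C)."""


class UndefinedModularityError(ValueError):
    """Raised when Q is requested for a graph with no edges."""


def within_fraction(alpha: float, S: int | None = None, exact: bool = False) -> float:
    """Expected fraction ``beta`` of species pairs that are within-subsystem.

    By default the large-S value ``alpha**2 + (1-alpha)**2`` is returned.
    With ``exact=True`` (requires ``S``) the finite-S pair-count version is
    used: ``[C(n1,2) + C(n2,2)] / C(S,2)`` with ``n1 = round(alpha*S)``.
    """
    if exact:
        if S is None:
            raise ValueError("exact within fraction requires S")
        n1 = int(round(alpha * S))
        n2 = S - n1
        pairs_w = n1 * (n1 - 1) / 2 + n2 * (n2 - 1) / 2
        return pairs_w / (S * (S - 1) / 2)
    return alpha**2 + (1.0 - alpha) ** 2


def modularity_bounds(alpha: float, C: float) -> tuple[float, float]:
    """Attainable modularity interval for given subsystem fraction and connectance.

    The bounds are where one of the two connectances hits 0 or 1:

        Q_max = min(1 - beta, beta (1 - C) / C)
        Q_min = max(-beta, -(1 - beta)(1 - C) / C)

    For ``alpha = 1/2`` and ``C < 1/2`` this gives the symmetric interval
    [-1/2, 1/2].
    """
    _check_alpha_C(alpha, C)
    beta = within_fraction(alpha)
    q_max = min(1.0 - beta, beta * (1.0 - C) / C)
    q_min = max(-beta, -(1.0 - beta) * (1.0 - C) / C)
    return q_min, q_max


def connectances_from_modularity(
    alpha: float, C: float, Q: float
) -> tuple[float, float]:
    """Convert (alpha, C, Q) to (C_w, C_b).

    With ``beta`` the expected within fraction,

        C_w = C (Q + beta) / beta
        C_b = C (1 - Q - beta) / (1 - beta).

    Q = 0 recovers the unstructured case ``C_w = C_b = C``; at ``Q_max``
    either ``C_b = 0`` (perfectly modular) or ``C_w = 1``, at ``Q_min``
    either ``C_w = 0`` (perfectly bipartite) or ``C_b = 1``.
    """
    _check_alpha_C(alpha, C)
    q_min, q_max = modularity_bounds(alpha, C)
    tol = 1e-12
    if not (q_min - tol <= Q <= q_max + tol):
        raise ModularityRangeError(
            f"Q={Q} outside attainable range [{q_min:.6g}, {q_max:.6g}] "
            f"for alpha={alpha}, C={C}"
        )
    beta = within_fraction(alpha)
    C_w = C * (Q + beta) / beta
    C_b = C * (1.0 - Q - beta) / (1.0 - beta)
    # clip the round-off at the exact bounds
    return float(np.clip(C_w, 0.0, 1.0)), float(np.clip(C_b, 0.0, 1.0))


@dataclass
class BlockSpec:
    """Parameterization of a two-block adjacency ensemble.

    Attributes
    ----------
    S : int
        Number of species.
    alpha : float
        Fraction of species in the smaller subsystem, in (0, 1/2].
    C : float
        Overall connectance, in (0, 1).
    Q : float
        Modularity, within ``modularity_bounds(alpha, C)``.
    C_w, C_b : float
        Derived within/between-subsystem connectances.
    beta : float
        Expected within fraction under the Erdos-Renyi reference.
    membership : ndarray of int
        Group label (1 or 2) per species; first ``round(alpha*S)`` are 1.
    """

    S: int
    alpha: float
    C: float
    Q: float
    C_w: float = field(init=False)
    C_b: float = field(init=False)
    beta: float = field(init=False)
    membership: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError("S must be at least 2")
        if not 0 < self.alpha <= 0.5:
            raise ValueError("alpha must lie in (0, 1/2]")
        n1 = self.alpha * self.S
        if abs(n1 - round(n1)) > 1e-9:
            warnings.warn(
                f"alpha*S = {n1} is not an integer; group 1 size rounded to "
                f"{int(round(n1))}",
                stacklevel=2,
            )
        self.beta = within_fraction(self.alpha)
        self.C_w, self.C_b = connectances_from_modularity(self.alpha, self.C, self.Q)
        m = int(round(n1))
        self.membership = np.r_[np.ones(m, dtype=int), np.full(self.S - m, 2)]

    @property
    def n_small(self) -> int:
        return int(round(self.alpha * self.S))

    def with_modularity(self, Q: float) -> "BlockSpec":
        """Same ensemble with a different modularity (e.g. the Q=0 reference)."""
        return BlockSpec(S=self.S, alpha=self.alpha, C=self.C, Q=Q)


@dataclass
class AdjacencyMatrix:
    """Symmetric 0/1 adjacency with zero diagonal, optionally tied to its spec."""

    entries: np.ndarray
    spec: BlockSpec | None = None

    def __post_init__(self) -> None:
        K = np.asarray(self.entries)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(K, K.T):
            raise ValueError("adjacency must be symmetric")
        if np.trace(np.abs(K)) != 0:
            raise ValueError("adjacency must have zero diagonal")
        if not np.isin(K, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.entries = K.astype(np.int8)

    @property
    def S(self) -> int:
        return self.entries.shape[0]


def sample_adjacency(spec: BlockSpec, seed: int) -> AdjacencyMatrix:
    """Draw one block-structured adjacency matrix.

    Each unordered pair (i < j, row-major over the upper triangle) is linked
    independently with probability ``C_w`` when the two species share a group
    and ``C_b`` otherwise.  Bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    S = spec.S
    same = spec.membership[:, None] == spec.membership[None, :]
    P = np.where(same, spec.C_w, spec.C_b)
    iu = np.triu_indices(S, k=1)
    draws = rng.random(iu[0].size)  # row-major pair order
    K = np.zeros((S, S), dtype=np.int8)
    K[iu] = draws < P[iu]
    K += K.T
    return AdjacencyMatrix(entries=K, spec=spec)


def measure_modularity(
    K: AdjacencyMatrix | np.ndarray,
    membership: np.ndarray,
    exact: bool = False,
) -> float:
    """Observed modularity of a graph for a given two-group partition.

    Returns ``L_w / L - beta`` where ``beta`` is the Erdos-Renyi expectation
    of the within fraction (large-S by default, finite-S with ``exact=True``).
    """
    A = K.entries if isinstance(K, AdjacencyMatrix) else np.asarray(K)
    membership = np.asarray(membership)
    S = A.shape[0]
    iu = np.triu_indices(S, k=1)
    edges = A[iu] != 0
    L = int(edges.sum())
    if L == 0:
        raise UndefinedModularityError("modularity undefined for an edgeless graph")
    same = (membership[:, None] == membership[None, :])[iu]
    L_w = int((edges & same).sum())
    alpha = min(np.mean(membership == membership[0]), np.mean(membership != membership[0]))
    beta = within_fraction(alpha, S=S, exact=exact)
    return L_w / L - beta


def _check_alpha_C(alpha: float, C: float) -> None:
    if not 0 < alpha <= 0.5:
        raise ValueError("alpha must lie in (0, 1/2]")
    if not 0 < C < 1:
        raise ValueError("C must lie in (0, 1)")
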