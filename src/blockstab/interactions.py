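"""Interaction-strength matrices and community-matrix assembly.

The off-diagonal entries of the interaction matrix ``W`` are drawn in
unordered pairs: ``(W_ij, W_ji)`` comes from a bivariate normal with
identical marginals (mean ``mu``, variance ``sigma2``) and correlation
``rho``.  Negative ``rho`` with mixed signs models predator-prey pairs,
positive ``rho`` competition/mutualism.  The community matrix is the
Hadamard product ``M = W * K`` with a block-structured adjacency ``K``, so
the adjacency decides which interactions are switched on.

The cascade variant assigns every species a uniform(0, 1) "size" and gives
the two members of a pair different means, ``(1 + xi) * mu`` for the effect
of the larger species on the smaller and ``(1 - xi) * mu`` for the reverse;
the average of the two conditional means is always ``mu``.  With ``mu < 0``
and ``xi > 1`` every consumer (the larger species) gains from the
interaction while the resource loses, as in cascade-model food webs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import AdjacencyMatrix, BlockSpec

__all__ = [
    "InteractionSpec",
    "CommunityMatrix",
    "sample_W_random",
    "sample_W_cascade",
    "build_community_matrix",
    "shuffle_null",
    "parameterize_empirical",
]


@dataclass
class InteractionSpec:
    """Moments of the pairwise interaction-strength distribution.

    Parameters
    ----------
    mu : float
        Mean interaction strength.
    sigma2 : float
        Variance of each marginal (>= 0).
    rho : float
        Correlation between ``W_ij`` and ``W_ji``, in [-1, 1].
    xi : float
        Cascade asymmetry (0 = plain random sampling).
    theta : float
        Critical parameter of the empirical schemes; unused otherwise.
    """

    mu: float
    sigma2: float = 1.0
    rho: float = 0.0
    xi: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.xi < 0:
            raise ValueError("xi must be non-negative")


@dataclass
class CommunityMatrix:
    """Dense community matrix with the specs it was built from (if any)."""

    entries: np.ndarray
    block_spec: BlockSpec | None = None
    interaction_spec: InteractionSpec | None = None

    @property
    def S(self) -> int:
        return self.entries.shape[0]


def _pair_draws(n_pairs: int, mu1, mu2, sigma2: float, rho: float, rng):
    """Correlated normal pairs with means (mu1, mu2), common variance, corr rho."""
    sd = np.sqrt(sigma2)
    z1 = rng.normal(size=n_pairs)
    z2 = rng.normal(size=n_pairs)
    a = mu1 + sd * z1
    b = mu2 + sd * (rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2)
    return a, b


def sample_W_random(S: int, spec: InteractionSpec, seed: int) -> np.ndarray:
    """Sample W with every unordered pair drawn from the bivariate normal."""
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(S, k=1)
    upper, lower = _pair_draws(iu[0].size, spec.mu, spec.mu, spec.sigma2, spec.rho, rng)
    W = np.zeros((S, S))
    W[iu] = upper
    W[(iu[1], iu[0])] = lower
    return W


def sample_W_cascade(
    S: int, spec: InteractionSpec, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample W under the cascade (food-web) variant.

    Returns ``(W, sizes)``.  For each pair, the effect of the larger species
    on the smaller has mean ``(1 + xi) * mu`` and the effect of the smaller
    on the larger has mean ``(1 - xi) * mu``; with ``mu < 0`` and ``xi > 1``
    the smaller species is consumed (strongly negative effect received) and
    the larger one benefits.  Sorting species by decreasing size confines
    the positive-mean effects to the upper triangle.
    """
    rng = np.random.default_rng(seed)
    sizes = rng.random(S)
    iu, ju = np.triu_indices(S, k=1)
    # orient each pair: effect received by the smaller species has mean (1+xi)mu
    i_smaller = sizes[iu] < sizes[ju]
    mu_up = np.where(i_smaller, (1.0 + spec.xi) * spec.mu, (1.0 - spec.xi) * spec.mu)
    mu_lo = np.where(i_smaller, (1.0 - spec.xi) * spec.mu, (1.0 + spec.xi) * spec.mu)
    upper, lower = _pair_draws(iu.size, mu_up, mu_lo, spec.sigma2, spec.rho, rng)
    W = np.zeros((S, S))
    W[(iu, ju)] = upper
    W[(ju, iu)] = lower
    return W, sizes


def build_community_matrix(
    W: np.ndarray,
    K: AdjacencyMatrix | np.ndarray,
    block_spec: BlockSpec | None = None,
    interaction_spec: InteractionSpec | None = None,
) -> CommunityMatrix:
    """Hadamard product M = W * K, with the diagonal forced to zero."""
    if isinstance(K, AdjacencyMatrix):
        if block_spec is None:
            block_spec = K.spec
        K = K.entries
    W = np.asarray(W, dtype=float)
    if W.shape != K.shape:
        raise ValueError(f"shape mismatch: W {W.shape} vs K {K.shape}")
    M = W * K
    np.fill_diagonal(M, 0.0)
    return CommunityMatrix(entries=M, block_spec=block_spec, interaction_spec=interaction_spec)


def shuffle_null(M: CommunityMatrix | np.ndarray, seed: int) -> CommunityMatrix:
    """Pair-preserving shuffle: reassign value-pairs to random positions.

    The multiset of unordered value-pairs ``{(M_ij, M_ji)}`` over the
    nonzero pattern is kept; their positions are redrawn uniformly among all
    species pairs (Erdos-Renyi placement, so the shuffled matrix has Q = 0
    in expectation for any partition) and each pair's orientation is
    randomized.  Requires a symmetric nonzero pattern.
    """
    A = M.entries if isinstance(M, CommunityMatrix) else np.asarray(M, dtype=float)
    pattern = A != 0
    if not np.array_equal(pattern, pattern.T):
        raise ValueError("shuffle_null requires a symmetric nonzero pattern")
    rng = np.random.default_rng(seed)
    S = A.shape[0]
    iu = np.triu_indices(S, k=1)
    occupied = pattern[iu]
    vals_up = A[iu][occupied]
    vals_lo = A[(iu[1], iu[0])][occupied]
    n_edges = vals_up.size
    slots = rng.choice(iu[0].size, size=n_edges, replace=False)
    flip = rng.random(n_edges) < 0.5
    new_up = np.where(flip, vals_lo, vals_up)
    new_lo = np.where(flip, vals_up, vals_lo)
    out = np.zeros_like(A)
    out[(iu[0][slots], iu[1][slots])] = new_up
    out[(iu[1][slots], iu[0][slots])] = new_lo
    inter = M.interaction_spec if isinstance(M, CommunityMatrix) else None
    return CommunityMatrix(entries=out, block_spec=None, interaction_spec=inter)


def parameterize_empirical(
    A: np.ndarray,
    scheme: str,
    theta: float,
    seed: int,
    halfnormal_scale: float = 1.0,
    mutualism_high: float = 1.0,
) -> CommunityMatrix:
    """Dress an empirical adjacency with interaction strengths.

    Schemes
    -------
    ``contact``
        ``A`` square symmetric.  For each undirected edge a single value
        ``~ Normal(theta, 0.0025)`` is assigned symmetrically
        (``M_ij = M_ji``).
    ``foodweb``
        ``A`` square directed; ``A_ij = 1`` means j preys on i.  The effect
        of the predator on the prey ``M_ij`` is drawn negative half-normal
        (scale ``halfnormal_scale``); the reciprocal prey-on-predator effect
        is ``-M_ij`` times a uniform(0, 2*theta) draw, so its magnitude is
        theta times the negative one on average.
    ``pollination``
        ``A`` rectangular plants x pollinators.  Mutualistic effects are
        uniform(0, ``mutualism_high``) on the bipartite edges (both
        directions, independent); competitive effects uniform(-theta, 0)
        between all pairs within each guild.
    """
    rng = np.random.default_rng(seed)
    A = np.asarray(A)
    if scheme == "contact":
        if A.ndim != 2 or A.shape[0] != A.shape[1] or not np.array_equal(A, A.T):
            raise ValueError("contact scheme needs a square symmetric adjacency")
        S = A.shape[0]
        M = np.zeros((S, S))
        iu = np.triu_indices(S, k=1)
        edges = A[iu] != 0
        vals = rng.normal(theta, np.sqrt(0.0025), size=int(edges.sum()))
        M[(iu[0][edges], iu[1][edges])] = vals
        M[(iu[1][edges], iu[0][edges])] = vals
    elif scheme == "foodweb":
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("foodweb scheme needs a square adjacency")
        S = A.shape[0]
        M = np.zeros((S, S))
        pred = np.argwhere(A != 0)
        neg = -np.abs(rng.normal(0.0, halfnormal_scale, size=pred.shape[0]))
        M[(pred[:, 0], pred[:, 1])] = neg
        M[(pred[:, 1], pred[:, 0])] = -neg * rng.uniform(0.0, 2.0 * theta, size=pred.shape[0])
        np.fill_diagonal(M, 0.0)
    elif scheme == "pollination":
        if A.ndim != 2:
            raise ValueError("pollination scheme needs a rectangular adjacency")
        n_pl, n_po = A.shape
        S = n_pl + n_po
        M = np.zeros((S, S))
        edges = np.argwhere(A != 0)
        i, j = edges[:, 0], n_pl + edges[:, 1]
        M[(i, j)] = rng.uniform(0.0, mutualism_high, size=i.size)
        M[(j, i)] = rng.uniform(0.0, mutualism_high, size=i.size)
        for lo, hi in ((0, n_pl), (n_pl, S)):
            n = hi - lo
            comp = rng.uniform(-theta, 0.0, size=(n, n))
            np.fill_diagonal(comp, 0.0)
            M[lo:hi, lo:hi] = comp
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return CommunityMatrix(entries=M)
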