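"""Transitive extension and confidence scoring of sparse protein networks.

Known protein-protein interaction networks miss many real interactions.
Under a first-order transitivity assumption (A interacts with B, B with C,
hence A plausibly with C) every finite shortest path of length d between
two proteins carries an implicit-interaction confidence c_d = zeta^(d-1),
where zeta is the per-hop extension probability fixed by requiring the
geometric series of path confidences to sum to one (zeta = 1/2, so
c_1 = 1, c_2 = 0.5, c_3 = 0.25, ...).

Path confidence is combined additively with the Pearson correlation of the
two genes' expression profiles (W), a damped random walk on W is iterated
to its equilibrium to capture global topology, and the final confidence is
C = 0.5 W + 0.5 W T-hat, symmetrized and min-max normalized.  Thresholding
C yields the extended network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import brentq

from .io_formats import (EdgeList, ExpressionMatrix, ScoredNetwork,
                         minmax_normalize, threshold_network)

logger = logging.getLogger(__name__)

__all__ = [
    "ShortestPathMatrix",
    "TransitionMatrix",
    "shortest_paths",
    "solve_zeta",
    "path_confidence",
    "combine_correlation",
    "build_transition",
    "converge_walk",
    "confidence_scores",
    "extend_ppin",
    "extend_ppin_scores",
]


@dataclass
class ShortestPathMatrix:
    """Hop counts between genes; ``np.inf`` marks disconnected pairs."""

    gene_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.gene_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("diagonal hop counts must be 0")


@dataclass
class TransitionMatrix:
    """Row-stochastic random-walk transition matrix with damping factor."""

    gene_ids: list[str]
    T: np.ndarray
    damping: float

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if np.any(self.T < 0):
            raise ValueError("transition probabilities must be nonnegative")
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")


def shortest_paths(ppin: EdgeList, genes: list[str]) -> ShortestPathMatrix:
    """Unweighted shortest hop counts among ``genes``.

    The graph may contain genes outside ``genes`` (a larger network of the
    same species); paths are free to route through them, and the result is
    projected onto the target gene set.  Disconnected pairs get ``inf``.
    """
    g = nx.Graph()
    g.add_nodes_from(genes)
    for a, b, _ in ppin:
        g.add_edge(a, b)
    n = len(genes)
    idx = {gid: i for i, gid in enumerate(genes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for src in genes:
        lengths = nx.single_source_shortest_path_length(g, src)
        i = idx[src]
        for tgt, hops in lengths.items():
            j = idx.get(tgt)
            if j is not None:
                d[i, j] = hops
    return ShortestPathMatrix(gene_ids=list(genes), d=d)


def solve_zeta() -> float:
    """Per-hop extension probability from the series constraint.

    The confidences of paths of every length must sum to one:
    sum_{d>=1} zeta^d = zeta/(1 - zeta) = 1, whose root on (0, 1) is 1/2.
    Solved numerically from the defining equation rather than hard-coded.
    """
    return float(brentq(lambda z: z / (1.0 - z) - 1.0, 1e-9, 1 - 1e-9, xtol=1e-14))


def path_confidence(d: float, zeta: float = 0.5) -> float:
    """Implicit-interaction confidence c_d = zeta^(d-1); 0 for unreachable pairs."""
    if np.isinf(d):
        return 0.0
    if d <= 0:
        raise ValueError("path confidence is defined for d >= 1 (self-pairs excluded)")
    return float(zeta ** (d - 1))


def _pearson_matrix(X: ExpressionMatrix) -> np.ndarray:
    """Gene-gene Pearson correlation; zero-variance genes get 0 rows (warned)."""
    Xv = X.values
    sd = Xv.std(axis=1)
    flat = sd == 0
    if np.any(flat):
        logger.warning("%d zero-variance genes: correlations set to 0", int(flat.sum()))
    safe = Xv.copy()
    safe[flat] = 0.0
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(safe)
    rho = np.nan_to_num(rho, nan=0.0)
    rho[flat, :] = 0.0
    rho[:, flat] = 0.0
    return rho


def combine_correlation(
    X: ExpressionMatrix, D: ShortestPathMatrix, zeta: float = 0.5
) -> ScoredNetwork:
    """Fused evidence W_ij = rho_ij + c(d_ij): correlation plus path confidence."""
    if list(X.gene_ids) != list(D.gene_ids):
        raise ValueError("gene orders of expression and distance matrices differ")
    rho = _pearson_matrix(X)
    n = X.n_genes
    c = np.zeros((n, n))
    finite = np.isfinite(D.d) & ~np.eye(n, dtype=bool)
    c[finite] = zeta ** (D.d[finite] - 1)
    W = rho + c
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2  # exact symmetry against float noise
    return ScoredNetwork(gene_ids=list(X.gene_ids), scores=W, symmetric=True,
                         score_range=(float(W.min()), float(W.max())))


def build_transition(W: ScoredNetwork, damping: float = 0.85) -> TransitionMatrix:
    """Damped random-walk transition matrix over the fused evidence graph.

    T = damping * row-normalized max(W, 0) + (1 - damping)/I teleport; rows
    with no positive mass become uniform (standard dangling-node fix).
    Negative fused scores carry no transition mass but are kept in W itself.
    """
    if not (0.5 < damping < 1.0):
        raise ValueError("damping factor must lie in (0.5, 1)")
    Wp = np.clip(W.scores, 0.0, None)
    n = W.n_genes
    rowsum = Wp.sum(axis=1)
    T = np.full((n, n), (1.0 - damping) / n)
    pos = rowsum > 0
    T[pos] += damping * Wp[pos] / rowsum[pos, None]
    T[~pos] = 1.0 / n
    return TransitionMatrix(gene_ids=list(W.gene_ids), T=T, damping=damping)


def converge_walk(
    T: TransitionMatrix, tol: float = 1e-9, max_iter: int = 64
) -> ScoredNetwork:
    """Equilibrium T-hat = lim T^k by repeated squaring (quadratic convergence)."""
    cur = T.T.copy()
    for _ in range(max_iter):
        nxt = cur @ cur
        delta = float(np.max(np.abs(nxt - cur)))
        cur = nxt
        if delta < tol:
            return ScoredNetwork(gene_ids=list(T.gene_ids), scores=cur,
                                 symmetric=False, score_range=(0.0, 1.0))
    raise RuntimeError(f"random walk did not converge in {max_iter} squarings "
                       f"(last delta {delta:.3g})")


def confidence_scores(W: ScoredNetwork, T_hat: ScoredNetwork) -> ScoredNetwork:
    """Final interaction confidence C = 0.5 W + 0.5 W T-hat, in [0, 1].

    The walk term compensates path-confidence underestimates with global
    topology.  The product is asymmetric, so C is averaged with its
    transpose (all downstream uses are undirected) and then min-max
    normalized to [0, 1] with a zero diagonal.
    """
    if W.gene_ids != T_hat.gene_ids:
        raise ValueError("gene orders differ")
    C = 0.5 * W.scores + 0.5 * (W.scores @ T_hat.scores)
    C = (C + C.T) / 2
    np.fill_diagonal(C, 0.0)
    net = ScoredNetwork(gene_ids=list(W.gene_ids), scores=C, symmetric=True,
                        score_range=(float(C.min()), float(C.max())))
    return minmax_normalize(net)


def extend_ppin(C: ScoredNetwork, cutoff: float = 0.5) -> EdgeList:
    """Extended network: unordered pairs whose confidence reaches the cutoff."""
    return threshold_network(C, cutoff)


def extend_ppin_scores(
    X: ExpressionMatrix,
    ppin: EdgeList,
    damping: float = 0.85,
    zeta: float | None = None,
    global_ppin: EdgeList | None = None,
) -> ScoredNetwork:
    """One-call pipeline from expression + raw network to the C score matrix.

    With ``global_ppin`` given, shortest paths run on that larger network
    (routes through genes outside the target set are allowed) and are
    projected back onto the expression gene set; otherwise the subnet
    network alone is used — the default, appropriate when the subnet is
    not overly sparse.
    """
    if zeta is None:
        zeta = solve_zeta()
    genes = list(X.gene_ids)
    source = global_ppin if global_ppin is not None else ppin.restrict_to(genes)
    D = shortest_paths(source, genes)
    W = combine_correlation(X, D, zeta)
    T = build_transition(W, damping)
    T_hat = converge_walk(T)
    return confidence_scores(W, T_hat)
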