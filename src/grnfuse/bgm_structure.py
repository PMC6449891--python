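"""Directed network learning by structural MCMC over a Bayesian network.

Each gene is a node of a directed acyclic graph; its expression is modelled
by a local linear-Gaussian regression on its parents, with experiments
hard-partitioned into K mixture components so that heterogeneous
experimental conditions each get their own local fit:

    p(X | G) = prod_i sum_k theta_k Psi(D^(k), x_i, pi_i)

where Psi is the analytic marginal likelihood of a conjugate
normal-inverse-gamma Bayesian regression of gene i on its parents within
experiment partition D^(k).  A Gibbs structure prior
p(G | R) ~ exp(-sum_{j != i} R_ji (1 - G_ji)) penalizes omitting edges
with high refined confidence R.  Parent sets are restricted to candidate
genes that share a pathway and rank in the top-k neighbours by R.

Sampling is Metropolis-Hastings over single-edge moves (add / delete /
reverse) with a uniform proposal over admissible moves and the exact
Hastings correction for the changing move count; acyclicity is enforced at
proposal time.  Edge confidence is the model-averaged frequency of the
edge across sampled graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import lgamma

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from .gmm_pathways import MembershipMatrix, _cem_fit
from .io_formats import EdgeList, ExpressionMatrix, ScoredNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentMixture",
    "ParentCandidates",
    "DagStructure",
    "StructureSample",
    "LocalScorer",
    "cluster_experiments",
    "parent_candidates",
    "local_score",
    "structure_log_prior",
    "mcmc_run",
    "run_chains",
    "model_average",
    "grn_edges",
]


@dataclass
class ExperimentMixture:
    """Hard partition of experiment columns into K mixture components."""

    K: int
    assignment: np.ndarray  # experiment index -> component in [0, K)
    weights: np.ndarray  # theta_k = |D^(k)| / J

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != self.K:
            raise ValueError("weights length != K")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mixture weights must sum to 1")
        for k in range(self.K):
            if not np.any(self.assignment == k):
                raise ValueError(f"experiment component {k} is empty")

    def partitions(self) -> list[np.ndarray]:
        return [np.where(self.assignment == k)[0] for k in range(self.K)]


@dataclass
class ParentCandidates:
    """Admissible parent sets per gene (shared pathway + top-k by R)."""

    gene_ids: list[str]
    candidates: list[set[int]]  # per gene, indices of admissible parents

    def __post_init__(self) -> None:
        for i, cs in enumerate(self.candidates):
            if i in cs:
                raise ValueError(f"gene {self.gene_ids[i]} is its own candidate")


@dataclass
class DagStructure:
    """Directed acyclic graph over genes; adjacency[u, v] means u -> v."""

    gene_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = len(self.gene_ids)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape mismatch")
        g = nx.from_numpy_array(self.adjacency.astype(int), create_using=nx.DiGraph)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("structure contains a directed cycle")

    def parent_sets(self) -> list[tuple[int, ...]]:
        return [tuple(np.where(self.adjacency[:, v])[0]) for v in range(len(self.gene_ids))]


@dataclass
class StructureSample:
    """Thinned draws from one MCMC chain plus summary statistics."""

    gene_ids: list[str]
    draws: list[np.ndarray] = field(default_factory=list)
    n_accepted: int = 0
    n_proposed: int = 0

    def edge_frequency(self, burn_in_fraction: float = 0.0) -> np.ndarray:
        start = int(len(self.draws) * burn_in_fraction)
        kept = self.draws[start:]
        if not kept:
            raise ValueError("no draws after burn-in")
        return np.mean([a.astype(float) for a in kept], axis=0)

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / max(self.n_proposed, 1)


def cluster_experiments(
    X: ExpressionMatrix, K_max: int = 5, seed: int = 0
) -> ExperimentMixture:
    """Hard-cluster experiment columns with the mixture/MML machinery.

    The expression matrix is transposed (experiments become samples in
    gene space), the pathway CEM selects K, and experiments are assigned
    by responsibility argmax; empty components are dropped.
    """
    J = X.n_experiments
    if not (1 <= K_max <= J):
        raise ValueError("need 1 <= K_max <= number of experiments")
    _, membership, _ = _cem_fit(
        X.values.T, list(X.experiment_ids), K_max, 1, seed, 1e-6, "diag", None
    )
    labels = membership.hard_labels()
    used = np.unique(labels)
    remap = {old: new for new, old in enumerate(used)}
    labels = np.array([remap[v] for v in labels])
    K = len(used)
    weights = np.bincount(labels, minlength=K).astype(float) / J
    return ExperimentMixture(K=K, assignment=labels, weights=weights)


def parent_candidates(
    tau: MembershipMatrix,
    R: ScoredNetwork,
    k: int = 5,
    membership_cutoff: float = 0.1,
    top_n: int | None = None,
) -> ParentCandidates:
    """Admissible parents: same-pathway genes among the strongest R neighbours.

    A gene belongs to pathway l when tau[i, l] >= membership_cutoff; the
    shared-pathway set is intersected with gene i's top-k neighbours by R
    (ties broken by gene order).  ``top_n`` switches to the global
    alternative: only the N highest-R unordered pairs are admissible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if tau.gene_ids != R.gene_ids:
        raise ValueError("gene orders of tau and R differ")
    I = len(tau.gene_ids)
    member = tau.tau >= membership_cutoff
    shares = member @ member.T > 0
    np.fill_diagonal(shares, False)

    allowed_pairs: set[frozenset] | None = None
    if top_n is not None:
        iu, ju = np.triu_indices(I, 1)
        order = np.lexsort((iu, ju, -R.scores[iu, ju]))
        top = order[:top_n]
        allowed_pairs = {frozenset((int(iu[t]), int(ju[t]))) for t in top}

    cands: list[set[int]] = []
    for i in range(I):
        others = [j for j in range(I) if j != i]
        # stable tie-break: higher R first, then gene order
        ranked = sorted(others, key=lambda j: (-R.scores[i, j], j))
        topk = set(ranked[:k])
        cs = {j for j in topk if shares[i, j]}
        if allowed_pairs is not None:
            cs = {j for j in cs if frozenset((i, j)) in allowed_pairs}
        cands.append(cs)
    return ParentCandidates(gene_ids=list(tau.gene_ids), candidates=cands)


class LocalScorer:
    """Cached local marginal likelihoods log sum_k theta_k Psi(D^(k), x_i, pi_i).

    Psi is the closed-form marginal of a conjugate normal-inverse-gamma
    Bayesian linear regression of gene i on its parents (plus intercept)
    within one experiment partition: prior mean zero, prior precision
    ``prior_precision`` * identity, inverse-gamma shape ``a0`` and scale
    ``b0`` on the noise variance.
    """

    def __init__(
        self,
        X: ExpressionMatrix,
        mix: ExperimentMixture,
        prior_precision: float = 1.0,
        a0: float = 1.0,
        b0: float = 1.0,
    ) -> None:
        self.X = X
        self.mix = mix
        self.prior_precision = prior_precision
        self.a0 = a0
        self.b0 = b0
        self._parts = mix.partitions()
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def _psi(self, y: np.ndarray, Z: np.ndarray) -> float:
        """Log marginal likelihood of one conjugate local regression."""
        n, p = Z.shape
        lam0 = self.prior_precision * np.eye(p)
        lam_n = lam0 + Z.T @ Z
        mu_n = np.linalg.solve(lam_n, Z.T @ y)
        a_n = self.a0 + n / 2.0
        b_n = self.b0 + 0.5 * float(y @ y - mu_n @ lam_n @ mu_n)
        sign0, logdet0 = np.linalg.slogdet(lam0)
        sign_n, logdet_n = np.linalg.slogdet(lam_n)
        return (
            -(n / 2.0) * np.log(2 * np.pi)
            + 0.5 * (logdet0 - logdet_n)
            + self.a0 * np.log(self.b0)
            - a_n * np.log(b_n)
            + lgamma(a_n)
            - lgamma(self.a0)
        )

    def score(self, gene: int, parents: tuple[int, ...] | frozenset | set) -> float:
        parents = tuple(sorted(parents))
        if gene in parents:
            raise ValueError("a gene cannot be its own parent")
        key = (gene, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        logs = np.empty(self.mix.K)
        for k, cols in enumerate(self._parts):
            y = self.X.values[gene, cols]
            Z = np.column_stack(
                [np.ones(len(cols))] + [self.X.values[p, cols] for p in parents]
            )
            if len(cols) < len(parents) + 1:
                logger.warning(
                    "partition %d has %d experiments for %d regressors; "
                    "score is prior-dominated", k, len(cols), len(parents) + 1,
                )
            logs[k] = self._psi(y, Z)
        val = float(logsumexp(logs, b=self.mix.weights))
        self._cache[key] = val
        return val

    def dag_log_score(self, adjacency: np.ndarray) -> float:
        """Decomposable total: sum of local scores over all genes."""
        return sum(
            self.score(v, tuple(np.where(adjacency[:, v])[0]))
            for v in range(self.X.n_genes)
        )


def local_score(
    X: ExpressionMatrix,
    mix: ExperimentMixture,
    gene: int,
    parents: tuple[int, ...] | set,
    **hyper,
) -> float:
    """One-off local marginal likelihood (see :class:`LocalScorer`)."""
    return LocalScorer(X, mix, **hyper).score(gene, parents)


def structure_log_prior(g: DagStructure, R: ScoredNetwork) -> float:
    """Gibbs structure log-prior -sum_i sum_{j != i} R_ji (1 - G_ji).

    The intractable normalizer is omitted; only prior ratios between
    structures are ever used by the sampler.
    """
    Rm = np.array(R.scores, dtype=float)
    np.fill_diagonal(Rm, 0.0)
    A = g.adjacency.astype(float)
    return float(-np.sum(Rm * (1.0 - A)))


def _closure(adj: np.ndarray) -> np.ndarray:
    """Boolean reachability matrix (one or more hops) by repeated squaring."""
    reach = adj.astype(np.uint8)
    while True:
        nxt = ((reach + reach @ reach) > 0).astype(np.uint8)
        if np.array_equal(nxt, reach):
            return reach.astype(bool)
        reach = nxt


def _path_exists_without_edge(adj: np.ndarray, u: int, v: int) -> bool:
    """Is v reachable from u once the direct edge u -> v is removed?"""
    a = adj.copy()
    a[u, v] = False
    frontier = np.where(a[u])[0]
    seen = np.zeros(adj.shape[0], dtype=bool)
    seen[frontier] = True
    while frontier.size:
        if seen[v]:
            return True
        nxt = np.where(a[frontier].any(axis=0) & ~seen)[0]
        seen[nxt] = True
        frontier = nxt
    return bool(seen[v])


def _admissible_moves(
    adj: np.ndarray, cands: ParentCandidates
) -> list[tuple[str, int, int]]:
    """All single-edge moves keeping the graph acyclic and candidate-respecting."""
    reach = _closure(adj)
    moves: list[tuple[str, int, int]] = []
    n = adj.shape[0]
    for v in range(n):
        for u in cands.candidates[v]:
            if not adj[u, v] and not reach[v, u]:
                moves.append(("add", u, v))
    edges = np.argwhere(adj)
    for u, v in edges:
        moves.append(("del", int(u), int(v)))
    for u, v in edges:
        u, v = int(u), int(v)
        if v in cands.candidates[u] and not _path_exists_without_edge(adj, u, v):
            moves.append(("rev", u, v))
    return moves


def _apply_move(adj: np.ndarray, move: tuple[str, int, int]) -> np.ndarray:
    kind, u, v = move
    out = adj.copy()
    if kind == "add":
        out[u, v] = True
    elif kind == "del":
        out[u, v] = False
    else:  # reverse
        out[u, v] = False
        out[v, u] = True
    return out


def mcmc_run(
    X: ExpressionMatrix,
    mix: ExperimentMixture,
    cands: ParentCandidates,
    R: ScoredNetwork,
    n_iter: int = 1000,
    seed: int = 0,
    thin: int = 1,
    scorer: LocalScorer | None = None,
    init: np.ndarray | None = None,
) -> StructureSample:
    """Metropolis-Hastings chain over DAGs, recording every ``thin``-th state.

    Acceptance ratio: exp(delta local score + delta structure prior) times
    the proposal correction |moves(G)| / |moves(G')| for the uniform
    single-edge-move proposal.  Score deltas touch only the one or two
    genes whose parent set changes (decomposability).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    n = X.n_genes
    if scorer is None:
        scorer = LocalScorer(X, mix)
    Rm = np.array(R.scores, dtype=float)
    np.fill_diagonal(Rm, 0.0)
    adj = np.zeros((n, n), dtype=bool) if init is None else init.astype(bool).copy()

    def parents_of(a: np.ndarray, v: int) -> tuple[int, ...]:
        return tuple(np.where(a[:, v])[0])

    sample = StructureSample(gene_ids=list(X.gene_ids))
    moves = _admissible_moves(adj, cands)
    for it in range(n_iter):
        if moves:
            sample.n_proposed += 1
            move = moves[rng.integers(len(moves))]
            kind, u, v = move
            new_adj = _apply_move(adj, move)
            if kind == "add":
                delta = (
                    scorer.score(v, parents_of(new_adj, v))
                    - scorer.score(v, parents_of(adj, v))
                    + Rm[u, v]
                )
            elif kind == "del":
                delta = (
                    scorer.score(v, parents_of(new_adj, v))
                    - scorer.score(v, parents_of(adj, v))
                    - Rm[u, v]
                )
            else:
                delta = (
                    scorer.score(v, parents_of(new_adj, v))
                    - scorer.score(v, parents_of(adj, v))
                    + scorer.score(u, parents_of(new_adj, u))
                    - scorer.score(u, parents_of(adj, u))
                    - Rm[u, v]
                    + Rm[v, u]
                )
            new_moves = _admissible_moves(new_adj, cands)
            log_alpha = delta + np.log(len(moves)) - np.log(len(new_moves))
            if np.log(rng.random()) < log_alpha:
                adj = new_adj
                moves = new_moves
                sample.n_accepted += 1
        if (it + 1) % thin == 0:
            sample.draws.append(adj.copy())
    logger.info("MCMC chain: %d draws, acceptance rate %.3f",
                len(sample.draws), sample.acceptance_rate)
    return sample


def run_chains(
    X: ExpressionMatrix,
    mix: ExperimentMixture,
    cands: ParentCandidates,
    R: ScoredNetwork,
    n_models: int = 10,
    n_iter: int = 1000,
    seed: int = 0,
    thin: int = 1,
) -> list[StructureSample]:
    """Independent chains with distinct seeds, sharing one score cache."""
    scorer = LocalScorer(X, mix)
    return [
        mcmc_run(X, mix, cands, R, n_iter=n_iter, seed=seed + m, thin=thin,
                 scorer=scorer)
        for m in range(n_models)
    ]


def model_average(
    samples: StructureSample | list[StructureSample],
    burn_in_fraction: float = 0.2,
) -> ScoredNetwork:
    """Directed edge confidence: pooled frequency of the edge across draws.

    The first ``burn_in_fraction`` of every chain is discarded before
    pooling.  The returned matrix F is directed; F + F^T is the
    probability of the edge in either orientation (a draw never contains
    both directions of one pair).
    """
    chains = samples if isinstance(samples, list) else [samples]
    pooled: list[np.ndarray] = []
    for ch in chains:
        start = int(len(ch.draws) * burn_in_fraction)
        pooled.extend(ch.draws[start:])
    if not pooled:
        raise ValueError("no draws to average")
    freq = np.mean([a.astype(float) for a in pooled], axis=0)
    return ScoredNetwork(gene_ids=list(chains[0].gene_ids), scores=freq,
                         symmetric=False, score_range=(0.0, 1.0))


def grn_edges(avg: ScoredNetwork, threshold: float = 0.5) -> EdgeList:
    """Final network: unordered pairs whose either-direction confidence
    reaches the threshold (evaluation is direction-blind)."""
    F = avg.scores
    und = F + F.T
    recs = []
    n = len(avg.gene_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if und[i, j] >= threshold:
                recs.append((avg.gene_ids[i], avg.gene_ids[j], float(und[i, j])))
    return EdgeList(recs)
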