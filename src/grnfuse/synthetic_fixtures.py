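"""Synthetic expression, networks and ground truth with known structure.

The generators emulate the statistical assumptions of the fusion method so
every stage is testable without external downloads: gene expression is
drawn from per-pathway multivariate Gaussians (genes with multiple
memberships draw from the mixture of their pathways), the ground-truth
regulatory network is the co-membership graph, and the observed protein
network is that truth subsampled (a retention fraction of edges kept) plus
uniformly sampled spurious edges.  A separate linear-Gaussian DAG
generator supports directed-structure recovery tests.

Everything is reproducible from the scenario seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import EdgeList, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticScenario",
    "generate_expression",
    "generate_truth_and_ppin",
    "edge_holdout_cv",
    "edge_holdout_recovery",
    "generate_linear_dag",
]


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic data set.

    Defaults describe the benchmark-scale scenario used throughout the
    test suite: 30 genes, 40 experiments, 4 pathways, 20% of genes with a
    second pathway membership, a protein network retaining 60% of the true
    co-membership edges plus 5% spurious pairs.  ``mean_separation`` is the
    pairwise distance between pathway mean vectors in units of the
    within-pathway standard deviation; 5 gives well-separated pathways.
    """

    I: int = 30
    J: int = 40
    L: int = 4
    overlap_fraction: float = 0.2
    ppin_retention: float = 0.6
    ppin_noise: float = 0.05
    mean_separation: float = 5.0
    pathway_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("overlap_fraction", "ppin_retention", "ppin_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.L > self.I:
            raise ValueError("more pathways than genes")
        if self.L > self.J:
            raise ValueError("pathway means are placed on orthogonal axes; need J >= L")

    def gene_ids(self) -> list[str]:
        return [f"g{i:03d}" for i in range(self.I)]


def _pathway_means(scn: SyntheticScenario) -> np.ndarray:
    """Pathway means on orthogonal axes, pairwise ``mean_separation`` * sd apart."""
    scale = scn.mean_separation * scn.pathway_sd / np.sqrt(2.0)
    means = np.zeros((scn.L, scn.J))
    for l in range(scn.L):
        means[l, l] = scale
    return means


def generate_expression(
    scn: SyntheticScenario,
) -> tuple[ExpressionMatrix, list[set[int]]]:
    """Expression matrix plus the true (possibly multi-label) memberships.

    Genes are assigned primary pathways round-robin; an ``overlap_fraction``
    of genes (chosen at random) gets one extra pathway.  Each gene's
    profile is drawn from one of its pathways' Gaussians, picked uniformly
    (a draw from the membership mixture).
    """
    rng = np.random.default_rng(scn.seed)
    means = _pathway_means(scn)
    membership: list[set[int]] = [{i % scn.L} for i in range(scn.I)]
    if scn.L > 1:
        n_overlap = int(round(scn.overlap_fraction * scn.I))
        for i in rng.choice(scn.I, size=n_overlap, replace=False):
            extra = rng.integers(scn.L - 1)
            primary = next(iter(membership[i]))
            membership[i].add(int((primary + 1 + extra) % scn.L))
    X = np.empty((scn.I, scn.J))
    for i, paths in enumerate(membership):
        l = int(rng.choice(sorted(paths)))
        X[i] = rng.normal(means[l], scn.pathway_sd)
    expr = ExpressionMatrix(
        gene_ids=scn.gene_ids(),
        experiment_ids=[f"exp{j:03d}" for j in range(scn.J)],
        values=X,
    )
    return expr, membership


def generate_truth_and_ppin(
    scn: SyntheticScenario, membership: list[set[int]]
) -> tuple[EdgeList, EdgeList]:
    """Co-membership truth network and its noisy, subsampled protein network.

    Truth: every unordered pair sharing at least one pathway.  Observed
    network: each truth edge kept with probability ``ppin_retention``; each
    non-truth pair added independently with probability ``ppin_noise``
    (spurious edges never duplicate truth edges).
    """
    rng = np.random.default_rng(scn.seed + 1)
    ids = scn.gene_ids()
    truth_recs, ppin_recs = [], []
    for i in range(scn.I):
        for j in range(i + 1, scn.I):
            if membership[i] & membership[j]:
                truth_recs.append((ids[i], ids[j], 1.0))
                if rng.random() < scn.ppin_retention:
                    ppin_recs.append((ids[i], ids[j], 1.0))
            elif rng.random() < scn.ppin_noise:
                ppin_recs.append((ids[i], ids[j], 1.0))
    logger.info("synthetic truth: %d edges; observed network: %d edges",
                len(truth_recs), len(ppin_recs))
    return EdgeList(truth_recs), EdgeList(ppin_recs)


def edge_holdout_cv(
    ppin: EdgeList, folds: int = 10, repeats: int = 1, seed: int = 0
) -> list[list[list[int]]]:
    """Random edge partitions for hold-out recovery experiments.

    Returns ``repeats`` lists of ``folds`` disjoint edge-index lists whose
    union covers all edges; fold sizes differ by at most one.  The harness
    removes one fold, extends the remaining network, and scores recovery
    of the held-out fold.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    n = len(ppin)
    if n < folds:
        raise ValueError(f"{n} edges cannot fill {folds} folds")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        out.append([sorted(int(e) for e in perm[f::folds]) for f in range(folds)])
    return out


def edge_holdout_recovery(
    expr: ExpressionMatrix,
    ppin: EdgeList,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    cutoff: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out edge recovery of the transitive extension vs a random baseline.

    Per repeat, edges are partitioned into ``folds`` folds; each fold is
    removed in turn, the network is re-extended from the remainder
    (confidence scores from path transitivity, expression correlation and
    the random walk), and the fraction of held-out edges among the newly
    predicted pairs (confidence >= ``cutoff``, absent from the remainder)
    is recorded.  The paired baseline predicts the same number of new
    pairs at random, weighted by the product of endpoint degrees in the
    remaining network (a degree-matched null).  Returns two arrays of
    length ``repeats``: mean recovery per repeat for the extension and
    for the baseline.
    """
    from .ppin_extend import extend_ppin_scores, threshold_network

    gene_ids = list(expr.gene_ids)
    idx = {g: i for i, g in enumerate(gene_ids)}
    records = list(ppin.records)
    assignments = edge_holdout_cv(ppin, folds=folds, repeats=repeats, seed=seed)
    rng = np.random.default_rng(seed + 1)
    rec_ext = np.zeros(repeats)
    rec_base = np.zeros(repeats)
    for r, fold_sets in enumerate(assignments):
        ext_fracs, base_fracs = [], []
        for fold in fold_sets:
            held = {frozenset((records[e][0], records[e][1])) for e in fold}
            remain = EdgeList([rec for e, rec in enumerate(records) if e not in set(fold)])
            remain_pairs = remain.pairs()
            C = extend_ppin_scores(expr, remain)
            predicted = {
                frozenset((a, b))
                for a, b, _ in threshold_network(C, cutoff)
            } - remain_pairs
            ext_fracs.append(len(predicted & held) / len(held) if held else 0.0)
            # degree-matched null: same number of novel pairs, sampled
            # with probability proportional to endpoint degree product
            deg = np.zeros(len(gene_ids))
            for a, b, _ in remain:
                deg[idx[a]] += 1
                deg[idx[b]] += 1
            cand_pairs = [
                frozenset((gene_ids[i], gene_ids[j]))
                for i in range(len(gene_ids))
                for j in range(i + 1, len(gene_ids))
                if frozenset((gene_ids[i], gene_ids[j])) not in remain_pairs
            ]
            wts = np.array([
                (deg[idx[min(p)]] + 1) * (deg[idx[max(p)]] + 1) for p in cand_pairs
            ], dtype=float)
            n_pick = min(len(predicted), len(cand_pairs))
            if n_pick:
                picked = rng.choice(len(cand_pairs), size=n_pick, replace=False,
                                    p=wts / wts.sum())
                base = {cand_pairs[int(t)] for t in picked}
                base_fracs.append(len(base & held) / len(held) if held else 0.0)
            else:
                base_fracs.append(0.0)
        rec_ext[r] = float(np.mean(ext_fracs))
        rec_base[r] = float(np.mean(base_fracs))
    logger.info("edge holdout: extension %.3f vs baseline %.3f (mean over %d repeats)",
                rec_ext.mean(), rec_base.mean(), repeats)
    return rec_ext, rec_base


def generate_linear_dag(
    n_genes: int = 10,
    n_experiments: int = 60,
    edge_prob: float = 0.25,
    edge_weight: float = 0.8,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, EdgeList, np.ndarray]:
    """Linear-Gaussian DAG data for directed-structure recovery tests.

    A random DAG (edges respect a random topological order, each admissible
    pair drawn with ``edge_prob``) generates data as
    child = sum_parents (+/- ``edge_weight``) * parent + N(0, ``noise_sd``^2);
    roots are standard normal.  Returns the expression matrix (genes x
    experiments), the truth edge list, and the directed adjacency.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_genes)
    adj = np.zeros((n_genes, n_genes), dtype=bool)
    weights = np.zeros((n_genes, n_genes))
    for a in range(n_genes):
        for b in range(a + 1, n_genes):
            if rng.random() < edge_prob:
                u, v = int(order[a]), int(order[b])
                adj[u, v] = True
                weights[u, v] = edge_weight * rng.choice([-1.0, 1.0])
    X = np.zeros((n_genes, n_experiments))
    for a in range(n_genes):
        v = int(order[a])
        parents = np.where(adj[:, v])[0]
        X[v] = rng.normal(0.0, noise_sd if parents.size else 1.0, size=n_experiments)
        for p in parents:
            X[v] += weights[p, v] * X[p]
    ids = [f"g{i:03d}" for i in range(n_genes)]
    truth = EdgeList([(ids[u], ids[v], 1.0)
                      for u, v in np.argwhere(adj)])
    expr = ExpressionMatrix(gene_ids=ids,
                            experiment_ids=[f"exp{j:03d}" for j in range(n_experiments)],
                            values=X)
    return expr, truth, adj
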