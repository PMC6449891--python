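import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import integrate, stats

from grnfuse.bgm_structure import (DagStructure, ExperimentMixture, LocalScorer,
                                   ParentCandidates, cluster_experiments,
                                   grn_edges, local_score, mcmc_run,
                                   model_average, parent_candidates, run_chains,
                                   structure_log_prior)
from grnfuse.evaluation import confusion_counts, prf1
from grnfuse.gmm_pathways import MembershipMatrix
from grnfuse.io_formats import ExpressionMatrix, ScoredNetwork
from grnfuse.synthetic_fixtures import generate_linear_dag


def flat_mixture(n_experiments):
    return ExperimentMixture(K=1, assignment=np.zeros(n_experiments, dtype=int),
                             weights=np.array([1.0]))


def all_dags(n):
    """Every DAG adjacency on n labelled nodes (exhaustive oracle)."""
    cells = [(i, j) for i in range(n) for j in range(n) if i != j]
    out = []
    for bits in itertools.product([0, 1], repeat=len(cells)):
        A = np.zeros((n, n), dtype=bool)
        for (i, j), b in zip(cells, bits):
            A[i, j] = bool(b)
        g = nx.from_numpy_array(A.astype(int), create_using=nx.DiGraph)
        if nx.is_directed_acyclic_graph(g):
            out.append(A)
    return out


class TestClusterExperiments:
    def test_single_component(self, small_expr):
        mix = cluster_experiments(small_expr, K_max=1, seed=0)
        assert mix.K == 1
        np.testing.assert_allclose(mix.weights, [1.0])

    def test_two_separated_condition_groups_recovered(self, rng):
        """Columns drawn from two well-separated condition regimes split
        into two components matching generation."""
        I, J = 12, 20
        X = np.empty((I, J))
        X[:, :10] = rng.normal(-3, 1, (I, 10))
        X[:, 10:] = rng.normal(3, 1, (I, 10))
        expr = ExpressionMatrix([f"g{i}" for i in range(I)],
                                [f"e{j}" for j in range(J)], X)
        mix = cluster_experiments(expr, K_max=4, seed=0)
        assert mix.K == 2
        first, second = mix.assignment[:10], mix.assignment[10:]
        assert len(set(first.tolist())) == 1
        assert len(set(second.tolist())) == 1
        assert first[0] != second[0]

    def test_weights_are_partition_fractions(self, small_expr):
        mix = cluster_experiments(small_expr, K_max=2, seed=1)
        counts = np.bincount(mix.assignment, minlength=mix.K)
        np.testing.assert_allclose(mix.weights, counts / small_expr.n_experiments)
        assert mix.weights.sum() == pytest.approx(1.0)


class TestParentCandidates:
    def make_tau(self, tau):
        return MembershipMatrix(np.asarray(tau, float),
                                [f"g{i}" for i in range(len(tau))])

    def test_disjoint_pathways_never_cross(self):
        tau = self.make_tau([[1, 0], [1, 0], [0, 1], [0, 1]])
        R = ScoredNetwork(tau.gene_ids, np.ones((4, 4)) - np.eye(4))
        cands = parent_candidates(tau, R, k=3)
        assert cands.candidates[0] <= {1}
        assert cands.candidates[2] <= {3}

    def test_no_truncation_when_k_large(self):
        tau = self.make_tau([[1.0], [1.0], [1.0], [1.0]])
        R = ScoredNetwork(tau.gene_ids, np.ones((4, 4)) - np.eye(4))
        cands = parent_candidates(tau, R, k=10)
        for i in range(4):
            assert cands.candidates[i] == set(range(4)) - {i}

    def test_matches_brute_force_construction(self, rng):
        I, L, k = 9, 3, 3
        raw = rng.uniform(size=(I, L))
        tau = self.make_tau(raw / raw.sum(axis=1, keepdims=True))
        sym = rng.uniform(size=(I, I))
        Rm = (sym + sym.T) / 2
        np.fill_diagonal(Rm, 0)
        R = ScoredNetwork(tau.gene_ids, Rm)
        cands = parent_candidates(tau, R, k=k, membership_cutoff=0.1)
        member = tau.tau >= 0.1
        for i in range(I):
            ranked = sorted((j for j in range(I) if j != i),
                            key=lambda j: (-Rm[i, j], j))[:k]
            expected = {j for j in ranked
                        if np.any(member[i] & member[j])}
            assert cands.candidates[i] == expected


class TestLocalScore:
    def test_matches_numeric_quadrature_no_parents(self, rng):
        """Closed-form marginal equals direct integration of the conjugate
        normal-inverse-gamma model over (mu, sigma^2)."""
        y = rng.normal(size=5)
        expr = ExpressionMatrix(["g0"], [f"e{j}" for j in range(5)], y[None, :])
        closed = local_score(expr, flat_mixture(5), 0, ())

        def integrand(mu, s2):
            return (stats.norm.pdf(mu, 0, np.sqrt(s2))
                    * stats.invgamma.pdf(s2, 1, scale=1)
                    * np.prod(stats.norm.pdf(y, mu, np.sqrt(s2))))

        val, _ = integrate.dblquad(integrand, 1e-6, 80,
                                   lambda s2: -40, lambda s2: 40,
                                   epsabs=1e-13, epsrel=1e-11)
        assert closed == pytest.approx(np.log(val), abs=1e-6)

    def test_invariant_to_permuting_experiments_within_partition(self, rng):
        X = rng.normal(size=(2, 12))
        expr = ExpressionMatrix(["a", "b"], [f"e{j}" for j in range(12)], X)
        s1 = local_score(expr, flat_mixture(12), 0, (1,))
        perm = rng.permutation(12)
        expr2 = ExpressionMatrix(["a", "b"], [f"e{j}" for j in range(12)],
                                 X[:, perm])
        s2 = local_score(expr2, flat_mixture(12), 0, (1,))
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_true_parent_beats_empty_set(self, rng):
        n = 40
        parent = rng.normal(size=n)
        child = 0.9 * parent + rng.normal(0, 0.3, n)
        expr = ExpressionMatrix(["child", "parent"],
                                [f"e{j}" for j in range(n)],
                                np.vstack([child, parent]))
        mix = flat_mixture(n)
        assert (local_score(expr, mix, 0, (1,))
                > local_score(expr, mix, 0, ()))

    def test_small_partition_is_prior_dominated_not_an_error(self, rng):
        X = rng.normal(size=(3, 4))
        expr = ExpressionMatrix(["a", "b", "c"], list("wxyz"), X)
        mix = ExperimentMixture(K=2, assignment=np.array([0, 0, 0, 1]),
                                weights=np.array([0.75, 0.25]))
        val = local_score(expr, mix, 0, (1, 2))
        assert np.isfinite(val)


class TestStructurePrior:
    def test_graph_covering_all_supported_cells_has_zero_penalty(self):
        """When every cell R charges is present in the graph, the Gibbs
        penalty vanishes (all (1 - G_ji) factors multiply zero scores)."""
        n = 4
        A = np.triu(np.ones((n, n), dtype=bool), 1)  # complete DAG
        Rm = np.zeros((n, n))
        Rm[np.triu_indices(n, 1)] = 0.7  # support only on present cells
        g = DagStructure([f"g{i}" for i in range(n)], A)
        R = ScoredNetwork(g.gene_ids, Rm, symmetric=False)
        assert structure_log_prior(g, R) == pytest.approx(0.0)

    def test_empty_graph_closed_form(self, rng):
        n = 5
        Rm = rng.uniform(size=(n, n))
        Rm = (Rm + Rm.T) / 2
        np.fill_diagonal(Rm, 0)
        g = DagStructure([f"g{i}" for i in range(n)],
                         np.zeros((n, n), dtype=bool))
        R = ScoredNetwork(g.gene_ids, Rm)
        assert structure_log_prior(g, R) == pytest.approx(-Rm.sum())

    def test_matches_double_sum_oracle(self, rng):
        n = 5
        A = np.triu((rng.uniform(size=(n, n)) < 0.4), 1)
        Rm = rng.uniform(size=(n, n))
        Rm = (Rm + Rm.T) / 2
        np.fill_diagonal(Rm, 0)
        g = DagStructure([f"g{i}" for i in range(n)], A)
        R = ScoredNetwork(g.gene_ids, Rm)
        expected = 0.0
        for i in range(n):
            for j in range(n):
                if j != i:
                    expected -= Rm[j, i] * (1 - float(A[j, i]))
        assert structure_log_prior(g, R) == pytest.approx(expected, abs=1e-12)


class TestMcmc:
    def three_gene_problem(self, seed=1):
        rng = np.random.default_rng(seed)
        m = 12
        X = np.zeros((3, m))
        X[0] = rng.normal(size=m)
        X[1] = 0.8 * X[0] + rng.normal(0, 0.5, m)
        X[2] = rng.normal(size=m)
        expr = ExpressionMatrix([f"g{i}" for i in range(3)],
                                [f"e{j}" for j in range(m)], X)
        mix = flat_mixture(m)
        R = ScoredNetwork(expr.gene_ids, np.zeros((3, 3)))
        cands = ParentCandidates(expr.gene_ids, [{1, 2}, {0, 2}, {0, 1}])
        return expr, mix, R, cands

    def test_every_draw_is_acyclic(self):
        expr, mix, R, cands = self.three_gene_problem()
        sample = mcmc_run(expr, mix, cands, R, n_iter=2000, seed=3)
        for A in sample.draws[::50]:
            g = nx.from_numpy_array(A.astype(int), create_using=nx.DiGraph)
            assert nx.is_directed_acyclic_graph(g)

    def test_empty_candidates_keep_empty_graph(self):
        expr, mix, R, _ = self.three_gene_problem()
        cands = ParentCandidates(expr.gene_ids, [set(), set(), set()])
        sample = mcmc_run(expr, mix, cands, R, n_iter=200, seed=0)
        assert all(not A.any() for A in sample.draws)

    def test_marginals_match_exhaustive_dag_posterior(self):
        """Chain edge frequencies on the 3-gene problem agree with the
        exact posterior enumerated over all 25 DAGs (within 0.05)."""
        expr, mix, R, cands = self.three_gene_problem()
        scorer = LocalScorer(expr, mix)
        logp, dags = [], all_dags(3)
        assert len(dags) == 25
        for A in dags:
            lp = sum(scorer.score(v, tuple(np.where(A[:, v])[0]))
                     for v in range(3))
            lp += structure_log_prior(DagStructure(expr.gene_ids, A), R)
            logp.append(lp)
        w = np.exp(np.array(logp) - max(logp))
        w /= w.sum()
        exact = sum(wi * A for wi, A in zip(w, dags))
        sample = mcmc_run(expr, mix, cands, R, n_iter=50000, seed=0,
                          scorer=scorer)
        freq = sample.edge_frequency(burn_in_fraction=0.2)
        assert np.abs(freq - exact).max() < 0.05

    def test_decomposability_of_total_score(self, rng):
        """Full log posterior recomputation equals the sum of cached local
        scores plus the structure prior on random admissible states."""
        expr, mix, R, cands = self.three_gene_problem()
        scorer = LocalScorer(expr, mix)
        for A in all_dags(3)[::5]:
            total = scorer.dag_log_score(A)
            manual = sum(
                scorer.score(v, tuple(np.where(A[:, v])[0])) for v in range(3)
            )
            assert total == pytest.approx(manual, abs=1e-12)

    def test_deterministic_given_seed(self):
        expr, mix, R, cands = self.three_gene_problem()
        s1 = mcmc_run(expr, mix, cands, R, n_iter=500, seed=9)
        s2 = mcmc_run(expr, mix, cands, R, n_iter=500, seed=9)
        for a, b in zip(s1.draws[::100], s2.draws[::100]):
            np.testing.assert_array_equal(a, b)


class TestModelAveraging:
    def test_identical_draws_confidence_one(self):
        A = np.zeros((2, 2), dtype=bool)
        A[0, 1] = True
        from grnfuse.bgm_structure import StructureSample
        s = StructureSample(["a", "b"], draws=[A.copy() for _ in range(10)])
        avg = model_average(s, burn_in_fraction=0.2)
        assert avg.scores[0, 1] == pytest.approx(1.0)

    def test_half_frequency(self):
        A1 = np.zeros((2, 2), dtype=bool)
        A2 = A1.copy()
        A2[0, 1] = True
        from grnfuse.bgm_structure import StructureSample
        s = StructureSample(["a", "b"], draws=[A1, A2] * 5)
        avg = model_average(s, burn_in_fraction=0.0)
        assert avg.scores[0, 1] == pytest.approx(0.5)

    def test_pooled_frequency_is_counting(self, rng):
        from grnfuse.bgm_structure import StructureSample
        draws1 = [rng.uniform(size=(3, 3)) < 0.3 for _ in range(10)]
        draws2 = [rng.uniform(size=(3, 3)) < 0.3 for _ in range(10)]
        chains = [StructureSample(["a", "b", "c"], draws=d)
                  for d in (draws1, draws2)]
        avg = model_average(chains, burn_in_fraction=0.0)
        pooled = draws1 + draws2
        expected = np.mean([a.astype(float) for a in pooled], axis=0)
        np.testing.assert_allclose(avg.scores, expected, atol=1e-12)


class TestStructureRecovery:
    def test_linear_gaussian_dag_recovered(self):
        """10-gene linear-Gaussian DAG, flat prior: mean undirected F1 at
        the 0.5 model-average threshold reaches 0.7 over 5 seeds."""
        f1s = []
        for seed in range(5):
            expr, truth, _ = generate_linear_dag(n_genes=10, n_experiments=60,
                                                 seed=seed)
            mix = flat_mixture(60)
            R = ScoredNetwork(expr.gene_ids, np.zeros((10, 10)))
            cands = ParentCandidates(expr.gene_ids,
                                     [set(range(10)) - {i} for i in range(10)])
            chains = run_chains(expr, mix, cands, R, n_models=4, n_iter=1200,
                                seed=seed)
            pred = grn_edges(model_average(chains), 0.5)
            tp, fp, fn = confusion_counts(pred, truth)
            f1s.append(prf1(tp, fp, fn)[2])
        assert np.mean(f1s) >= 0.7

    def test_informative_prior_never_hurts_on_average(self):
        """R = 1 on true edges never lowers mean undirected F1 relative to
        a flat prior over 5 paired seeds."""
        flat_f1, prior_f1 = [], []
        for seed in range(5):
            expr, truth, adj = generate_linear_dag(n_genes=10,
                                                   n_experiments=60, seed=seed)
            mix = flat_mixture(60)
            cands = ParentCandidates(expr.gene_ids,
                                     [set(range(10)) - {i} for i in range(10)])
            Rt = np.zeros((10, 10))
            for u, v in np.argwhere(adj):
                Rt[u, v] = Rt[v, u] = 1.0
            for name, Rm, sink in (("flat", np.zeros((10, 10)), flat_f1),
                                   ("true", Rt, prior_f1)):
                R = ScoredNetwork(expr.gene_ids, Rm)
                chains = run_chains(expr, mix, cands, R, n_models=3,
                                    n_iter=1000, seed=seed)
                pred = grn_edges(model_average(chains), 0.5)
                tp, fp, fn = confusion_counts(pred, truth)
                sink.append(prf1(tp, fp, fn)[2])
        assert np.mean(prior_f1) >= np.mean(flat_f1) - 1e-9
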