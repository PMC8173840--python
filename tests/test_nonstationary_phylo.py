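"""T92 matrices, nonstationary likelihood, NNI search, RELL ranking."""

from __future__ import annotations

import numpy as np
import pytest

from endosift._pruning import compress_patterns, pruning_site_loglik
from endosift.nonstationary_phylo import (
    NonStatModel,
    SiteLikelihoods,
    nni_hill_climb,
    nni_neighbors,
    optimize_model,
    rell_rank,
    stationary_t92_log_likelihood,
    t92_equilibrium,
    t92_rate_matrix,
    t92_transition_matrix,
    tree_log_likelihood,
    uniform_model,
)
from endosift.phylo_partition import GTRGammaFit
from endosift.seq_io import SeqRecord
from endosift.synthetic_data import simulate_partitioned_alignments
from endosift.trees import Tree, random_topology

from oracles import exhaustive_alignment_loglik


def series_expm(q: np.ndarray, t: float, terms: int = 80) -> np.ndarray:
    """Independent Taylor-series matrix exponential."""
    out = np.eye(4)
    term = np.eye(4)
    for n in range(1, terms):
        term = term @ (q * t) / n
        out = out + term
    return out


class TestT92Matrix:
    def test_zero_time_is_identity(self):
        assert np.array_equal(t92_transition_matrix(0.3, 2.0, 0.0), np.eye(4))

    def test_symmetric_limit_equals_jukes_cantor(self):
        t = 0.4
        p = t92_transition_matrix(0.5, 1.0, t)
        same = 0.25 + 0.75 * np.exp(-4 * t / 3)
        diff = 0.25 - 0.25 * np.exp(-4 * t / 3)
        expected = np.full((4, 4), diff)
        np.fill_diagonal(expected, same)
        assert np.allclose(p, expected, atol=1e-12)

    @pytest.mark.parametrize(
        "theta,kappa,t", [(0.3, 2.0, 0.15), (0.7, 5.0, 1.2), (0.15, 0.5, 0.6)]
    )
    def test_matches_series_matrix_exponential(self, theta, kappa, t):
        p = t92_transition_matrix(theta, kappa, t)
        oracle = series_expm(t92_rate_matrix(theta, kappa), t)
        assert np.abs(p - oracle).max() < 1e-10

    @pytest.mark.parametrize("theta,kappa", [(0.2, 3.0), (0.6, 1.5)])
    def test_rows_sum_to_one_and_chapman_kolmogorov(self, theta, kappa):
        for t in (0.01, 0.3, 2.0):
            p = t92_transition_matrix(theta, kappa, t)
            assert np.abs(p.sum(axis=1) - 1.0).max() < 1e-12
        p1 = t92_transition_matrix(theta, kappa, 0.2)
        p2 = t92_transition_matrix(theta, kappa, 0.5)
        p12 = t92_transition_matrix(theta, kappa, 0.7)
        assert np.allclose(p1 @ p2, p12, atol=1e-12)

    def test_equilibrium_is_stationary(self):
        pi = t92_equilibrium(0.3)
        p = t92_transition_matrix(0.3, 2.0, 0.8)
        assert np.allclose(pi @ p, pi, atol=1e-12)

    def test_out_of_range_theta_rejected(self):
        with pytest.raises(ValueError):
            t92_rate_matrix(0.0, 2.0)
        with pytest.raises(ValueError):
            t92_rate_matrix(1.0, 2.0)


class TestNonstationaryLikelihood:
    def _simulate(self, tree, seed, sites=300):
        cls = GTRGammaFit(
            (1, 2, 1, 1, 2, 1), (0.25, 0.25, 0.25, 0.25), 1.0, 1, 0.0
        )
        alns, _ = simulate_partitioned_alignments(
            tree, 1, [cls], [0], sites_per_gene=sites, seed=seed
        )
        return alns[0].records

    def test_stationary_limit_matches_homogeneous_engine(self, rng):
        """Equal theta on every branch + equilibrium root frequencies must
        reproduce the independent stationary-engine likelihood."""
        tree = random_topology(list("ABCDEF"), rng, (0.05, 0.3))
        aln = self._simulate(tree, seed=1)
        model = uniform_model(tree, theta=0.35, kappa=2.4)
        _, total = tree_log_likelihood(model, aln)
        stationary = stationary_t92_log_likelihood(tree, aln, 0.35, 2.4)
        assert total == pytest.approx(stationary, rel=1e-8)

    def test_pruning_matches_exhaustive_with_per_branch_theta(self):
        rng = np.random.default_rng(4)
        tree = Tree.from_newick("((A:0.2,B:0.4):0.3,C:0.5,D:0.1);")
        aln = self._simulate(tree, seed=2, sites=6)
        theta = {
            n.id: float(rng.uniform(0.1, 0.9))
            for n in tree.postorder()
            if n.parent is not None
        }
        model = NonStatModel(
            tree=tree, kappa=3.0, theta=theta,
            root_freqs=np.array([0.4, 0.1, 0.2, 0.3]),
        )
        sl, total = tree_log_likelihood(model, aln)

        def p_fn(node, cat):
            return t92_transition_matrix(theta[node.id], 3.0, node.length)

        oracle = exhaustive_alignment_loglik(
            tree, aln, p_fn, model.root_freqs, 1
        )
        assert total == pytest.approx(oracle, rel=1e-8)

    def test_per_pattern_weights_account_for_every_site(self, rng):
        tree = random_topology(list("ABCD"), rng)
        aln = self._simulate(tree, seed=3, sites=120)
        sl, _ = tree_log_likelihood(uniform_model(tree), aln)
        assert sl.weights.sum() == 120


class TestOptimizeModel:
    def test_loglik_never_decreases_and_converges(self, rng):
        tree = random_topology(list("ABCDE"), rng, (0.05, 0.3))
        cls = GTRGammaFit(
            (1, 2, 1, 1, 2, 1), (0.35, 0.15, 0.15, 0.35), 1.0, 1, 0.0
        )
        alns, _ = simulate_partitioned_alignments(
            tree, 1, [cls], [0], sites_per_gene=300, seed=5
        )
        aln = alns[0].records
        init = uniform_model(tree, theta=0.5, kappa=1.0)
        _, init_total = tree_log_likelihood(init, aln)
        groups = {n.id: 0 for n in tree.postorder() if n.parent is not None}
        fit = optimize_model(
            tree, aln, init, max_sweeps=25, theta_groups=groups
        )
        assert fit.log_likelihood >= init_total
        assert fit.converged

    def test_planted_high_gc_clade_gets_higher_theta(self):
        """Branch-tied theta fitting recovers the planted composition
        contrast between a GC-drifted clade and the AT-rich background."""
        tree = Tree.from_newick(
            "((A:0.5,B:0.5):0.5,(C:0.3,D:0.3):0.3,(E:0.3,F:0.3):0.3);"
        )
        clade = next(
            n for n in tree.postorder()
            if not n.is_leaf and {c.name for c in n.children} == {"A", "B"}
        )
        clade_ids = {clade.id} | {c.id for c in clade.children}
        cls = GTRGammaFit(
            (1, 2, 1, 1, 2, 1), (0.25, 0.25, 0.25, 0.25), 1.0, 1, 0.0
        )
        alns, _ = simulate_partitioned_alignments(
            tree, 1, [cls], [0], sites_per_gene=1500,
            nonstationary={nid: 0.85 for nid in clade_ids},
            nonstationary_base_theta=0.2, seed=6,
        )
        groups = {
            n.id: (1 if n.id in clade_ids else 0)
            for n in tree.postorder()
            if n.parent is not None
        }
        fit = optimize_model(
            tree, alns[0].records, uniform_model(tree, 0.5, 2.0),
            max_sweeps=10, theta_groups=groups,
        )
        clade_theta = fit.model.theta[clade.id]
        background_theta = next(
            th for nid, th in fit.model.theta.items() if nid not in clade_ids
        )
        assert clade_theta > background_theta + 0.2


class TestNNI:
    def test_quartet_neighbors_are_the_other_two_topologies(self):
        q = Tree.from_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        edge = q.internal_edge_ids()[0]
        n1, n2 = nni_neighbors(q, edge)
        expect = {
            Tree.from_newick("((A:1,C:1):1,B:1,D:1);").splits(),
            Tree.from_newick("((A:1,D:1):1,B:1,C:1);").splits(),
        }
        assert {n1.splits(), n2.splits()} == expect
        assert not n1.same_topology(q) and not n2.same_topology(q)

    def test_nni_is_an_involution(self, rng):
        tree = random_topology(list("ABCDEF"), rng)
        edge = tree.internal_edge_ids()[0]
        n1, _ = nni_neighbors(tree, edge)
        back = [t for e in n1.internal_edge_ids() for t in nni_neighbors(n1, e)]
        assert any(t.same_topology(tree) for t in back)

    def test_six_taxon_tree_has_six_distinct_neighbors(self, rng):
        tree = random_topology(list("ABCDEF"), rng)
        tops = set()
        for e in tree.internal_edge_ids():
            for nb in nni_neighbors(tree, e):
                tops.add(nb.splits())
        assert len(tops) == 6

    def test_terminal_edge_rejected(self):
        q = Tree.from_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        leaf_id = next(n.id for n in q.leaves())
        with pytest.raises(ValueError):
            nni_neighbors(q, leaf_id)


class TestHillClimb:
    def _data(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_topology(list("ABCDEF"), rng, (0.08, 0.3))
        cls = GTRGammaFit(
            (1, 2, 1, 1, 2, 1), (0.3, 0.2, 0.2, 0.3), 1.0, 1, 0.0
        )
        alns, _ = simulate_partitioned_alignments(
            tree, 1, [cls], [0], sites_per_gene=900, seed=seed
        )
        return tree, alns[0].records

    def test_start_at_truth_is_a_local_optimum(self):
        tree, aln = self._data(11)
        res = nni_hill_climb(tree, aln, opt_sweeps=2)
        assert res.n_moves == 0
        assert res.fit.model.tree.same_topology(tree)

    def test_one_nni_away_climbs_back_to_truth(self):
        tree, aln = self._data(12)
        start = nni_neighbors(tree, tree.internal_edge_ids()[0])[0]
        res = nni_hill_climb(start, aln, opt_sweeps=2)
        assert res.fit.model.tree.same_topology(tree)
        assert res.n_moves >= 1

    def test_search_logs_only_nni_reachable_topologies(self):
        """The visited set stays within one NNI of the accepted path —
        the locality property that bounds the search."""
        tree, aln = self._data(13)
        start = nni_neighbors(tree, tree.internal_edge_ids()[0])[0]
        res = nni_hill_climb(start, aln, opt_sweeps=2)
        path = {start.splits(), res.fit.model.tree.splits()}
        allowed = set()
        for s in (start, res.fit.model.tree):
            allowed.add(s.splits())
            for e in s.internal_edge_ids():
                for nb in nni_neighbors(s, e):
                    allowed.add(nb.splits())
        visited = {Tree.from_newick(nwk).splits() for nwk in res.visited}
        assert visited <= allowed


class TestRELL:
    def _sl(self, values, weights=None):
        values = np.asarray(values, dtype=float)
        weights = (
            np.ones(values.size, dtype=np.int64)
            if weights is None
            else np.asarray(weights)
        )
        return SiteLikelihoods(values, weights)

    def test_identical_candidates_split_support_evenly(self, rng):
        v = rng.normal(-2.0, 0.5, size=50)
        df = rell_rank([self._sl(v), self._sl(v)], n_boot=500, seed=0)
        assert df["rell_bp"].tolist() == pytest.approx([0.5, 0.5])
        assert (df["p_sh"] > 0.9).all()

    def test_dominant_candidate_takes_all_support(self, rng):
        good = rng.normal(-1.0, 0.1, size=40)
        bad = good - 1.0  # worse at every site
        df = rell_rank([self._sl(good), self._sl(bad)], n_boot=500, seed=1)
        assert df.loc[0, "rell_bp"] == 1.0
        assert df.loc[1, "rell_bp"] == 0.0
        assert df.loc[0, "rank"] == 1

    def test_mismatched_patterns_rejected(self, rng):
        a = self._sl(rng.normal(size=10))
        b = self._sl(rng.normal(size=12))
        with pytest.raises(ValueError):
            rell_rank([a, b])

    def test_deterministic_given_seed(self, rng):
        sls = [self._sl(rng.normal(size=30)) for _ in range(3)]
        d1 = rell_rank(sls, n_boot=300, seed=7)
        d2 = rell_rank(sls, n_boot=300, seed=7)
        assert d1.equals(d2)

    def test_exchangeable_candidates_rarely_rejected(self):
        """SH-style p-values are calibrated: exchangeable candidates keep
        p >= 0.05 in at least 90% of seeded repetitions."""
        ok = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            base = rng.normal(-2.0, 0.8, size=200)
            sls = [
                self._sl(base + rng.normal(0, 0.05, size=200))
                for _ in range(3)
            ]
            df = rell_rank(sls, n_boot=400, seed=rep)
            if (df["p_sh"] >= 0.05).all():
                ok += 1
        assert ok >= 0.9 * reps
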