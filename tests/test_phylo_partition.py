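"""Codon splitting, GTR+Gamma fitting, PCoA, K-means partition selection."""

from __future__ import annotations

import numpy as np
import pytest

from endosift._pruning import compress_patterns, pruning_site_loglik
from endosift.phylo_partition import (
    CodonAlignment,
    GTRGammaFit,
    _coordinate_ascent,
    _gtr_eigen,
    _transition_matrices,
    build_supermatrix,
    discrete_gamma_rates,
    fit_gtr_gamma,
    gtr_rate_matrix,
    leading_axes,
    nj_guide_tree,
    pcoa_embed,
    PartitionScheme,
    select_partitions,
    split_codon_positions,
)
from endosift.seq_io import SeqRecord
from endosift.synthetic_data import simulate_partitioned_alignments
from endosift.trees import Tree, random_topology

from oracles import enumerate_unrooted_topologies, exhaustive_alignment_loglik


def _aln(rows: dict[str, str], name: str = "g") -> CodonAlignment:
    return CodonAlignment(name, [SeqRecord(k, v) for k, v in rows.items()])


class TestSplitCodonPositions:
    def test_nine_columns_split_by_phase(self):
        aln = _aln({"A": "ACGTTGCAA", "B": "ACGACGACG"})
        subs = split_codon_positions(aln, keep=(1, 2))
        assert {r.id: r.seq for r in subs[1].records} == {
            "A": "ATC", "B": "AAA"
        }
        assert {r.id: r.seq for r in subs[2].records} == {
            "A": "CTA", "B": "CCC"
        }

    def test_keeping_all_positions_conserves_every_column(self):
        rng = np.random.default_rng(0)
        seqs = {
            t: "".join(rng.choice(list("ACGT"), 30)) for t in ("A", "B", "C")
        }
        subs = split_codon_positions(_aln(seqs), keep=(1, 2, 3))
        for taxon, seq in seqs.items():
            rebuilt = sorted(
                "".join(
                    next(r.seq for r in subs[p].records if r.id == taxon)
                    for p in (1, 2, 3)
                )
            )
            assert rebuilt == sorted(seq)

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="gene1"):
            split_codon_positions(_aln({"A": "ACGT", "B": "ACGT"}, "gene1"))

    def test_saturated_third_positions_show_composition_variance(self):
        """Third positions under per-lineage GC drift vary in composition
        across taxa far more than constrained first/second positions —
        the empirical motivation for dropping them."""
        tree = Tree.from_newick(
            "((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5,(E:0.5,F:0.5):0.5);"
        )
        cls = GTRGammaFit(
            (1, 2, 1, 1, 2, 1), (0.25, 0.25, 0.25, 0.25), 1.0, 4, 0.0
        )
        # conserved positions: near-zero branch lengths (slow sites)
        slow = tree.copy()
        for n in slow.postorder():
            n.length *= 0.02
        aln12, _ = simulate_partitioned_alignments(
            slow, 1, [cls], [0], sites_per_gene=198, seed=1
        )
        # third positions: fast and compositionally drifting per clade
        clade_ids = [
            n.id for n in tree.postorder()
            if n.parent is not None and not n.is_leaf
        ]
        theta_map = {nid: th for nid, th in zip(clade_ids, (0.15, 0.5, 0.85))}
        aln3, _ = simulate_partitioned_alignments(
            tree, 1, [cls], [0], sites_per_gene=99,
            nonstationary=theta_map, seed=2,
        )
        rows = {}
        for taxon in "ABCDEF":
            s12 = next(r.seq for r in aln12[0].records if r.id == taxon)
            s3 = next(r.seq for r in aln3[0].records if r.id == taxon)
            codons = "".join(
                s12[2 * i] + s12[2 * i + 1] + s3[i] for i in range(99)
            )
            rows[taxon] = codons
        codon_aln = _aln(rows)
        subs = split_codon_positions(codon_aln, keep=(1, 2, 3))

        def gc_variance(sub):
            gcs = [
                (r.seq.count("G") + r.seq.count("C")) / len(r.seq)
                for r in sub.records
            ]
            return np.var(gcs)

        assert gc_variance(subs[3]) > max(
            gc_variance(subs[1]), gc_variance(subs[2])
        )


class TestDiscreteGamma:
    @pytest.mark.parametrize("alpha", [0.2, 0.7, 1.0, 5.0])
    def test_category_rates_average_to_one(self, alpha):
        rates = discrete_gamma_rates(alpha, 4)
        assert rates.mean() == pytest.approx(1.0, abs=1e-8)
        assert (np.diff(rates) > 0).all()

    def test_rate_matrix_has_unit_mean_rate(self):
        rng = np.random.default_rng(1)
        rates = rng.uniform(0.3, 3, 6)
        freqs = rng.dirichlet([4, 4, 4, 4])
        q = gtr_rate_matrix(rates, freqs)
        assert -(freqs @ np.diag(q)) == pytest.approx(1.0)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)


class TestPruningOracle:
    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_pruning_equals_exhaustive_on_all_topologies(self, n_taxa):
        """Felsenstein pruning agrees with summation over every internal
        state combination on every unrooted topology (3 or 15 trees)."""
        rng = np.random.default_rng(n_taxa)
        names = [f"t{i}" for i in range(n_taxa)]
        for tree in enumerate_unrooted_topologies(names):
            for node in tree.postorder():
                if node.parent is not None:
                    node.length = float(rng.uniform(0.02, 0.8))
            rates = rng.uniform(0.3, 3.0, 6)
            rates[5] = 1.0
            freqs = rng.dirichlet([5, 5, 5, 5])
            alpha = float(rng.uniform(0.3, 2.0))
            records = [
                SeqRecord(t, "".join(rng.choice(list("ACGT"), 8)))
                for t in names
            ]
            taxon_rows, patterns, weights = compress_patterns(records)
            eig = _gtr_eigen(rates, freqs)
            nodes = [n for n in tree.postorder() if n.parent is not None]
            lengths = np.array([n.length for n in nodes])
            cat_rates = discrete_gamma_rates(alpha, 4)
            pm = _transition_matrices(eig, lengths, cat_rates)
            index = {n.id: b for b, n in enumerate(nodes)}

            def p_fn(node, cat):
                return pm[index[node.id], cat]

            site = pruning_site_loglik(
                tree, taxon_rows, patterns, p_fn, freqs, 4
            )
            total = float(weights @ site)
            oracle = exhaustive_alignment_loglik(tree, records, p_fn, freqs, 4)
            assert total == pytest.approx(oracle, rel=1e-8)


class TestFitGTRGamma:
    def test_identical_sequences_hit_frequency_only_likelihood(self):
        seq = "ACGT" * 10
        aln = _aln({t: seq for t in "ABCD"})
        tree = Tree.from_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        fit = fit_gtr_gamma(aln, tree, max_sweeps=3)
        # no substitutions: logL collapses to sum over sites of log(pi)
        expected = sum(
            10 * np.log(fit.freqs[i]) for i in range(4)
        )
        assert fit.log_likelihood == pytest.approx(expected, abs=0.05)

    def test_coordinate_ascent_is_monotone(self):
        history_fun = []

        def fun(x):
            v = -(x[0] - 1.0) ** 2 - (x[1] + 2.0) ** 2
            history_fun.append(v)
            return v

        x, best, history = _coordinate_ascent(
            np.zeros(2), [(-5, 5), (-5, 5)], fun, max_sweeps=10, rel_tol=1e-10
        )
        assert np.all(np.diff(history) >= 0)
        assert best == pytest.approx(0.0, abs=1e-6)
        assert x == pytest.approx([1.0, -2.0], abs=1e-3)

    def test_too_few_taxa_rejected(self):
        aln = _aln({t: "ACG" for t in "ABC"})
        tree = Tree.from_newick("(A:0.1,B:0.1,C:0.1);")
        with pytest.raises(ValueError, match="4 taxa"):
            fit_gtr_gamma(aln, tree)


class TestPCoA:
    def test_identical_rows_coincide(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 1.0]])
        coords, _ = pcoa_embed(x)
        assert np.allclose(coords[0], coords[1], atol=1e-9)

    def test_euclidean_distances_are_preserved(self, rng):
        from scipy.spatial.distance import pdist

        x = rng.normal(size=(10, 4))
        coords, _ = pcoa_embed(x)
        xs = (x - x.mean(0)) / x.std(0)
        assert np.allclose(pdist(xs), pdist(coords), atol=1e-8)

    def test_collinear_points_have_one_dominant_axis(self):
        x = np.array([[0.0, 0.0], [1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        _, eig = pcoa_embed(x)
        assert eig[0] / eig.sum() > 0.99

    def test_agrees_with_skbio_classical_scaling(self, rng):
        from scipy.spatial.distance import pdist, squareform
        from skbio import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        x = rng.normal(size=(9, 5))
        coords, eig = pcoa_embed(x)
        xs = (x - x.mean(0)) / x.std(0)
        dm = DistanceMatrix(
            squareform(pdist(xs)), ids=[str(i) for i in range(9)]
        )
        ref = skbio_pcoa(dm)
        ref_eig = np.sort(ref.eigvals.values[ref.eigvals.values > 1e-8])[::-1]
        assert np.allclose(ref_eig, eig, atol=1e-6)

    def test_constant_column_dropped_with_warning(self, rng):
        x = rng.normal(size=(6, 3))
        x[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            coords, _ = pcoa_embed(x)
        assert coords.shape[0] == 6


class TestSelectPartitions:
    def test_two_planted_blobs_recovered(self, rng):
        a = rng.normal(0.0, 0.3, size=(12, 2))
        b = rng.normal(5.0, 0.3, size=(12, 2))
        coords = np.vstack([a, b])
        scheme = select_partitions(coords, range(1, 6), 10, seed=1)
        assert scheme.k == 2
        labels = [scheme.assignment[i] for i in range(24)]
        assert len(set(labels[:12])) == 1 and len(set(labels[12:])) == 1
        assert labels[0] != labels[12]

    def test_single_blob_selects_k_one(self, rng):
        coords = rng.normal(size=(20, 2))
        scheme = select_partitions(coords, range(1, 6), 10, seed=1)
        assert scheme.k == 1
        assert set(scheme.assignment.values()) == {1}

    def test_reproducible_given_seed(self, rng):
        coords = rng.normal(size=(15, 3))
        a = select_partitions(coords, range(1, 5), 8, seed=3)
        b = select_partitions(coords, range(1, 5), 8, seed=3)
        assert a.assignment == b.assignment and a.k == b.k

    def test_leading_axes_mass_selection(self):
        coords = np.arange(12.0).reshape(3, 4)
        eig = np.array([6.0, 3.0, 0.9, 0.1])
        assert leading_axes(coords, eig, 0.9).shape[1] == 2
        assert leading_axes(coords, eig, 1.0).shape[1] == 4


class TestSupermatrix:
    def test_two_subalignments_one_partition_each(self):
        a = _aln({"A": "AAA", "B": "CCC"}, "g1")
        b = _aln({"A": "GGG", "B": "TTT"}, "g2")
        scheme = PartitionScheme(k=2, assignment={0: 1, 1: 2})
        records, part = build_supermatrix([a, b], scheme)
        assert {r.id: r.seq for r in records} == {
            "A": "AAAGGG", "B": "CCCTTT"
        }
        assert part == "DNA, part1 = 1-3\nDNA, part2 = 4-6\n"

    def test_missing_taxon_is_gap_padded(self):
        a = _aln({"A": "AAA", "B": "CCC"}, "g1")
        b = _aln({"A": "GGG"}, "g2")
        records, _ = build_supermatrix(
            [a, b], PartitionScheme(k=1, assignment={0: 1, 1: 1})
        )
        assert {r.id: r.seq for r in records}["B"] == "CCC---"

    def test_total_length_is_conserved(self, rng):
        alns = [
            _aln(
                {t: "".join(rng.choice(list("ACGT"), 3 * (i + 2))) for t in "AB"},
                f"g{i}",
            )
            for i in range(4)
        ]
        records, _ = build_supermatrix(
            alns, PartitionScheme(k=1, assignment={i: 1 for i in range(4)})
        )
        assert len(records[0].seq) == sum(a.n_sites for a in alns)

    def test_shared_partition_merges_ranges(self):
        a = _aln({"A": "AAA"}, "g1")
        b = _aln({"A": "CCC"}, "g2")
        _, part = build_supermatrix(
            [a, b], PartitionScheme(k=1, assignment={0: 1, 1: 1})
        )
        assert part == "DNA, part1 = 1-3, 4-6\n"


class TestGuideTree:
    def test_nj_guide_tree_covers_taxa(self, rng):
        tree = random_topology(list("ABCDEF"), rng, (0.05, 0.3))
        cls = GTRGammaFit(
            (1, 2, 1, 1, 2, 1), (0.25, 0.25, 0.25, 0.25), 1.0, 4, 0.0
        )
        alns, _ = simulate_partitioned_alignments(
            tree, 1, [cls], [0], sites_per_gene=300, seed=4
        )
        guide = nj_guide_tree(alns[0])
        assert sorted(guide.leaf_names()) == sorted("ABCDEF")
        assert guide.same_topology(tree)
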