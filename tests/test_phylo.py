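import numpy as np
import pytest

from orgsnp import phylo
from orgsnp.cohort import CohortTable
from orgsnp.core import SnpRecord


def matrix_from(rows: dict[str, str], sites=None) -> phylo.CharacterMatrix:
    taxa = list(rows)
    states = np.array([list(s) for s in rows.values()])
    return phylo.CharacterMatrix(
        taxa, sites or list(range(1, states.shape[1] + 1)), states
    )


class TestBuildMatrix:
    def test_mito_fixture_dimensions_and_shared_sites(self, mito_table):
        m = phylo.build_matrix(mito_table, reference_taxon="KHA")
        assert (m.n_taxa, m.n_sites) == (10, 37)
        # the 16 nine-cultivar SNPs: identical across cultivars, differing
        # only from the reference row
        kha = m.taxa.index("KHA")
        cultivar_rows = [i for i in range(10) if i != kha]
        n_shared_all = 0
        for j in range(m.n_sites):
            col = m.states[cultivar_rows, j]
            if len(set(col)) == 1 and col[0] != m.states[kha, j]:
                n_shared_all += 1
        assert n_shared_all == 16

    def test_plastid_fixture_dimensions(self, plastid_table):
        m = phylo.build_matrix(plastid_table, reference_taxon="KHA")
        assert (m.n_taxa, m.n_sites) == (10, 20)

    def test_empty_cohort_gives_zero_sites(self):
        table = CohortTable([], [f"C{i}" for i in range(9)], "mito")
        m = phylo.build_matrix(table)
        assert (m.n_taxa, m.n_sites) == (10, 0)

    def test_conflicting_reference_alleles_rejected(self):
        recs = [
            SnpRecord("A", "mito", 5, "C", "T", 1, 10, 0, 10),
            SnpRecord("B", "mito", 5, "G", "T", 1, 10, 0, 10),
        ]
        with pytest.raises(ValueError, match="conflicting reference"):
            phylo.build_matrix(CohortTable(recs, ["A", "B"], "mito"))


class TestFitch:
    def test_invariant_matrix_has_zero_length(self):
        m = matrix_from({"a": "AAA", "b": "AAA", "c": "AAA", "d": "AAA"})
        tree = phylo.Tree.from_newick("((a,b),(c,d));")
        assert phylo.fitch_length(m, tree) == 0

    @pytest.mark.parametrize("newick,expected", [
        ("((a,b),(c,d));", 1),
        ("((a,c),(b,d));", 2),
        ("((a,d),(b,c));", 2),
    ])
    def test_single_site_three_topologies(self, newick, expected):
        m = matrix_from({"a": "A", "b": "A", "c": "C", "d": "C"})
        assert phylo.fitch_length(m, phylo.Tree.from_newick(newick)) == expected

    def test_leaf_mismatch_rejected(self):
        m = matrix_from({"a": "A", "b": "C", "x": "G", "y": "T"})
        tree = phylo.Tree.from_newick("((a,b),(c,d));")
        with pytest.raises(ValueError, match="match"):
            phylo.fitch_length(m, tree)

    def test_heuristic_equals_exhaustive_on_fixture_subsample(self, mito_table):
        """Heuristic search reaches the global parsimony optimum over all
        topologies for a 7-taxon subsample of the published matrix."""
        full = phylo.build_matrix(mito_table, reference_taxon="KHA")
        taxa = ["SUK-A", "DEK", "PER", "SHA", "MOS-A", "SUK-Q", "KHA"]
        m = full.subset_taxa(taxa)
        exhaustive = min(
            phylo.fitch_length(m, t) for t in phylo.enumerate_topologies(taxa)
        )
        heuristic, tree = phylo.parsimony_search(m, seed=0)
        assert heuristic == exhaustive
        assert phylo.fitch_length(m, tree) == heuristic

    def test_heuristic_equals_exhaustive_on_random_matrices(self, rng):
        for trial in range(3):
            taxa = list("abcdefg")
            states = np.array(list("ACGT"))[rng.integers(0, 4, (7, 15))]
            m = phylo.CharacterMatrix(taxa, list(range(15)), states)
            exhaustive = min(
                phylo.fitch_length(m, t)
                for t in phylo.enumerate_topologies(taxa)
            )
            heuristic, _ = phylo.parsimony_search(m, seed=trial)
            assert heuristic == exhaustive


class TestJC69:
    def test_two_taxon_mle_matches_closed_form(self):
        """At p=0.1 the optimised branch length equals
        -(3/4) ln(1 - 4p/3) = 0.10732 to 1e-6."""
        m = matrix_from({"x": "A" * 9 + "C", "y": "A" * 10})
        tree = phylo.Tree()
        a, b = tree.add_node("x"), tree.add_node("y")
        tree.add_edge(a, b, 0.5)
        phylo.optimize_branch_lengths(m, tree)
        fitted = tree.lengths[frozenset((a, b))]
        assert fitted == pytest.approx(phylo.jc69_distance(0.1), abs=1e-6)
        assert fitted == pytest.approx(0.10732, abs=1e-5)

    def test_jc69_distance_domain(self):
        assert phylo.jc69_distance(0.0) == 0.0
        with pytest.raises(ValueError):
            phylo.jc69_distance(0.8)

    def test_ml_recovers_generating_split(self):
        gen = phylo.Tree.from_newick(
            "((a:0.05,b:0.05):0.2,(c:0.05,d:0.05):0.2);"
        )
        m = phylo.simulate_characters(gen, 500, seed=2)
        tree, ll = phylo.ml_tree(m, seed=0)
        assert frozenset({"c", "d"}) in tree.bipartitions() or \
            frozenset({"a", "b"}) in tree.bipartitions()

    def test_branch_optimisation_never_decreases_likelihood(self):
        gen = phylo.Tree.from_newick(
            "((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);"
        )
        m = phylo.simulate_characters(gen, 200, seed=3)
        _, tree = phylo.parsimony_search(m, seed=0)
        for key in tree.lengths:
            tree.lengths[key] = 0.05
        before = phylo.log_likelihood(m, tree)
        after = phylo.optimize_branch_lengths(m, tree)
        assert after >= before

    def test_all_invariant_matrix_warns(self):
        m = matrix_from({t: "AAAA" for t in "abcd"})
        with pytest.warns(UserWarning, match="invariant"):
            phylo.ml_tree(m, seed=0)


class TestBootstrap:
    def test_supports_within_range_and_strong_signal(self):
        gen = phylo.Tree.from_newick(
            "((a:0.05,b:0.05):0.3,(c:0.05,d:0.05):0.3);"
        )
        m = phylo.simulate_characters(gen, 300, seed=4)
        tree, _ = phylo.ml_tree(m, seed=0)
        supports = phylo.bootstrap(m, tree, n_replicates=50, seed=1)
        assert all(0 <= v <= 100 for v in supports.values())
        assert max(supports.values()) >= 95

    def test_newick_export_carries_supports(self):
        gen = phylo.Tree.from_newick(
            "((a:0.05,b:0.05):0.3,(c:0.05,d:0.05):0.3);"
        )
        m = phylo.simulate_characters(gen, 200, seed=5)
        tree, _ = phylo.ml_tree(m, seed=0)
        supports = phylo.bootstrap(m, tree, n_replicates=20, seed=2)
        newick = tree.to_newick(supports=supports)
        back = phylo.Tree.from_newick(newick)
        assert back.bipartitions() == tree.bipartitions()


class TestILD:
    def test_congruent_partitions_not_significant(self):
        gen = phylo.Tree.from_newick(
            "((a:0.1,b:0.1):0.2,(c:0.1,d:0.1):0.2,(e:0.1,f:0.1):0.2);"
        )
        m = phylo.simulate_characters(gen, 60, seed=6)
        a, b = m.take_sites(range(30)), m.take_sites(range(30, 60))
        d, p = phylo.ild_test(a, b, n_permutations=100, seed=7)
        assert d == 0
        assert p >= 0.5

    def test_conflicting_partitions_detected(self):
        gen_a = phylo.Tree.from_newick(
            "((a:0.05,b:0.05):0.5,(c:0.05,d:0.05):0.5,(e:0.05,f:0.05):0.5);"
        )
        gen_b = phylo.Tree.from_newick(
            "((a:0.05,c:0.05):0.5,(b:0.05,e:0.05):0.5,(d:0.05,f:0.05):0.5);"
        )
        ma = phylo.simulate_characters(gen_a, 40, seed=8)
        mb = phylo.simulate_characters(gen_b, 40, seed=9)
        d, p = phylo.ild_test(ma, mb, n_permutations=100, seed=10)
        assert d > 0
        assert p < 0.05

    def test_p_in_unit_interval_and_d_permutation_invariant(self):
        gen = phylo.Tree.from_newick(
            "((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);"
        )
        m = phylo.simulate_characters(gen, 40, seed=11)
        a, b = m.take_sites(range(20)), m.take_sites(range(20, 40))
        d1, p1 = phylo.ild_test(a, b, n_permutations=20, seed=12)
        d2, p2 = phylo.ild_test(a, b, n_permutations=60, seed=13)
        assert d1 == d2  # observed statistic independent of permutations
        for p in (p1, p2):
            assert 0 < p <= 1

    def test_taxon_mismatch_rejected(self):
        a = matrix_from({"a": "AC", "b": "AC", "c": "CA", "d": "CA"})
        b = matrix_from({"a": "AC", "b": "AC", "x": "CA", "y": "CA"})
        with pytest.raises(ValueError, match="taxa"):
            phylo.ild_test(a, b)


class TestCombinedMatrix:
    def test_concatenation_preserves_taxa_and_sites(self, mito_table,
                                                    plastid_table):
        ma = phylo.build_matrix(mito_table, reference_taxon="KHA")
        mb = phylo.build_matrix(plastid_table, reference_taxon="KHA")
        mb = mb.subset_taxa(ma.taxa)
        combined = ma.concatenate(mb)
        assert combined.n_sites == 37 + 20
        assert combined.taxa == ma.taxa

    def test_combined_ml_tree_runs_on_fixture_data(self, mito_table,
                                                   plastid_table):
        ma = phylo.build_matrix(mito_table, reference_taxon="KHA")
        mb = phylo.build_matrix(plastid_table, reference_taxon="KHA")
        combined = ma.concatenate(mb.subset_taxa(ma.taxa))
        tree, ll = phylo.ml_tree(combined, seed=1)
        assert set(tree.labels.values()) == set(combined.taxa)
        assert ll < 0

    def test_matrix_tsv_round_trip(self, tmp_path, plastid_table):
        m = phylo.build_matrix(plastid_table)
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = phylo.CharacterMatrix.from_tsv(path)
        assert back.taxa == m.taxa
        assert (back.states == m.states).all()
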