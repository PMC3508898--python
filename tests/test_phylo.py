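import math

import dendropy
import numpy as np
import pytest

from ggamma import phylo
from ggamma.seq_io import AlignedBlock
from ggamma.synthetic_data import SynthConfig, make_cohort

from _oracles import (
    edge_lengths,
    enumerate_topologies,
    path_distance_matrix,
    tree_bipartitions,
)


def make_block(rows):
    return AlignedBlock.from_rows(rows)


class TestExtractCentralDomain:
    def test_window_contains_gbeta_contact_columns(self, small_cohort):
        block, dropped = phylo.extract_central_domain(small_cohort.alignment)
        assert dropped == []
        # upstream=45 puts the anchor start at window offset 45; every row
        # must carry a [D/E]PL[L/I] there, and the 45+4+2 window spans
        # template positions 6..56, i.e. all seven Gβ-contact columns
        import re
        for rid, row in block.records:
            assert re.fullmatch(r"[DE]PL[LI]", row[45:49]), rid
        assert block.ncols == 51

    def test_clipped_at_alignment_start(self):
        block = make_block([("a", "DPLLVNWKQT"), ("b", "DPLLVNWKQT")])
        central, _ = phylo.extract_central_domain(block, upstream=45,
                                                  downstream=2)
        assert central.ncols == 6   # columns 1..6

    def test_rows_without_anchor_dropped(self):
        block = make_block([("a", "MKDPLLVNWK"), ("b", "MKAAAAVNWK")])
        central, dropped = phylo.extract_central_domain(block)
        assert dropped == ["b"]
        assert central.ids == ["a"]

    def test_no_anchor_anywhere_errors(self):
        block = make_block([("a", "MKAAAAVNWK")])
        with pytest.raises(ValueError):
            phylo.extract_central_domain(block)


class TestDistances:
    def test_identical_rows_zero(self):
        dm = phylo.distances(make_block([("a", "MKVA"), ("b", "MKVA")]))
        assert dm.matrix[0, 1] == 0.0

    def test_hand_counted_p_distance(self):
        dm = phylo.distances(make_block([("a", "AAAA"), ("b", "AAAV")]))
        assert dm.matrix[0, 1] == pytest.approx(0.25)

    def test_poisson_closed_form(self):
        dm = phylo.distances(make_block([("a", "AAAA"), ("b", "AAAV")]),
                             model="poisson")
        assert dm.matrix[0, 1] == pytest.approx(-math.log(0.75))

    def test_gapped_pairs_deleted_and_x_never_matches(self):
        dm = phylo.distances(make_block([("a", "A-XA"), ("b", "AWXA")]))
        # compared columns: 1,3,4 ; column 3 is X/X -> mismatch
        assert dm.matrix[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_columns_errors_naming_pair(self):
        block = make_block([("a", "AA--"), ("b", "--WW")])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            phylo.distances(block)

    def test_saturation_capped_and_flagged(self):
        block = make_block([("a", "A" * 30), ("b", "W" * 30)])
        dm = phylo.distances(block, model="poisson")
        assert ("a", "b") in dm.saturated
        assert dm.matrix[0, 1] == pytest.approx(-math.log(1 - 0.95))


def dm_from(ids, matrix, model="p-distance"):
    return phylo.DistanceMatrix(ids=tuple(ids),
                                matrix=np.asarray(matrix, dtype=float),
                                model=model)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = dm_from("abc", [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = dm_to_patristic(phylo.nj_tree(dm))
        assert tree[("a", "b")] == pytest.approx(3.0)
        assert tree[("a", "c")] == pytest.approx(4.0)
        assert tree[("b", "c")] == pytest.approx(5.0)

    def test_fewer_than_three_taxa_errors(self):
        with pytest.raises(ValueError):
            phylo.nj_tree(dm_from("ab", [[0, 1], [1, 0]]))

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_recovers_additive_matrices(self, n_taxa):
        labels = [f"t{i}" for i in range(n_taxa)]
        for edges in enumerate_topologies(labels):
            lengths = edge_lengths(edges)
            matrix = path_distance_matrix(edges, lengths, labels)
            tree = phylo.nj_tree(dm_from(labels, matrix))
            assert phylo.bipartitions(tree) == \
                tree_bipartitions(edges, labels)
            recovered = dm_to_patristic(tree)
            for i, a in enumerate(labels):
                for j in range(i + 1, n_taxa):
                    assert recovered[(a, labels[j])] == \
                        pytest.approx(matrix[i, j])

    def test_column_duplication_leaves_topology_unchanged(self, small_cohort):
        block, _ = phylo.extract_central_domain(small_cohort.alignment)
        doubled = AlignedBlock.from_rows(
            [(rid, s + s) for rid, s in block.records])
        t1 = phylo.nj_tree(phylo.distances(block))
        t2 = phylo.nj_tree(phylo.distances(doubled))
        assert phylo.bipartitions(t1) == phylo.bipartitions(t2)


def dm_to_patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            d = pdm.patristic_distance(t1, t2)
            out[(t1.label, t2.label)] = d
            out[(t2.label, t1.label)] = d
    return out


class TestBootstrap:
    @pytest.fixture(scope="class")
    @staticmethod
    def divergent_cohort():
        config = SynthConfig(seed=31, n_per_type={"A": 4, "B": 4, "C": 4},
                             divergence=0.05, between_type_divergence=0.5)
        cohort = make_cohort(config)
        block, _ = phylo.extract_central_domain(cohort.alignment)
        groups = {t.id: t.true_type for t in cohort.truth}
        return block, groups

    def test_separated_types_fully_supported(self, divergent_cohort):
        block, groups = divergent_cohort
        res = phylo.bootstrap_support(block, groups, n_replicates=40, seed=8)
        assert set(res.group_support) == {"A", "B", "C"}
        for label, support in res.group_support.items():
            assert support >= 0.95, label

    def test_identical_seed_identical_supports(self, divergent_cohort):
        block, groups = divergent_cohort
        r1 = phylo.bootstrap_support(block, groups, n_replicates=25, seed=5)
        r2 = phylo.bootstrap_support(block, groups, n_replicates=25, seed=5)
        assert r1.group_support == r2.group_support
        assert phylo.bipartitions(r1.tree) == phylo.bipartitions(r2.tree)

    def test_supports_bounded(self, divergent_cohort):
        block, groups = divergent_cohort
        res = phylo.bootstrap_support(block, groups, n_replicates=10, seed=1)
        assert all(0.0 <= s <= 1.0 for s in res.group_support.values())

    def test_singleton_group_reported_absent(self, divergent_cohort):
        block, _ = divergent_cohort
        groups = {rid: ("solo" if i == 0 else "rest")
                  for i, rid in enumerate(block.ids)}
        res = phylo.bootstrap_support(block, groups, n_replicates=5, seed=2)
        assert "solo" not in res.group_support
        assert "rest" not in res.group_support   # complement of a singleton

    def test_unlabeled_taxon_errors(self, divergent_cohort):
        block, groups = divergent_cohort
        bad = dict(groups)
        bad.pop(block.ids[0])
        with pytest.raises(ValueError, match=block.ids[0]):
            phylo.bootstrap_support(block, bad, n_replicates=2, seed=0)


def newick(s, tns):
    return dendropy.Tree.get(data=s, schema="newick", taxon_namespace=tns)


class TestMajorityConsensus:
    def test_identical_trees_full_support(self):
        tns = dendropy.TaxonNamespace()
        trees = [newick("((a,b),(c,d),(e,f));", tns) for _ in range(10)]
        cons = phylo.majority_consensus(trees)
        assert phylo.bipartitions(cons) == phylo.bipartitions(trees[0])
        labels = [nd.label for nd in cons.preorder_node_iter()
                  if nd.label is not None]
        assert set(labels) == {"100"}

    def test_sixty_percent_bipartition_retained(self):
        tns = dendropy.TaxonNamespace()
        t1 = [newick("((a,b),(c,d));", tns) for _ in range(6)]
        t2 = [newick("((a,c),(b,d));", tns) for _ in range(4)]
        cons = phylo.majority_consensus(t1 + t2)
        bips = phylo.bipartitions(cons)
        assert bips == {frozenset({"c", "d"})}
        labels = [nd.label for nd in cons.preorder_node_iter() if nd.label]
        assert labels == ["60"]

    def test_incompatible_splits_at_half_both_dropped(self):
        tns = dendropy.TaxonNamespace()
        t1 = [newick("((a,b),(c,d));", tns) for _ in range(5)]
        t2 = [newick("((a,c),(b,d));", tns) for _ in range(5)]
        cons = phylo.majority_consensus(t1 + t2, threshold=0.5)
        assert phylo.bipartitions(cons) == set()

    def test_leaf_set_mismatch_errors(self):
        tns = dendropy.TaxonNamespace()
        t1 = newick("((a,b),(c,d));", tns)
        t2 = newick("((a,b),(c,e));", tns)
        with pytest.raises(ValueError):
            phylo.majority_consensus([t1, t2])
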