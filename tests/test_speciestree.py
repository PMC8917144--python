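"""Quartet scoring, species-tree search, multilocus bootstrap, rooting."""

import itertools

import numpy as np
import pytest

import sbkit.trees as tr
from sbkit import speciestree as st


def rand_tree(n, rng, labels=None):
    labels = labels or [f"t{i}" for i in range(n)]
    return tr.read_newick(tr.to_newick(tr.random_topology(n, rng), labels))


def induced_quartet(tree, quad):
    """Prune-based oracle for the induced quartet topology."""
    a = tree.clone(depth=1)
    a.retain_taxa_with_labels(quad)
    a.suppress_unifurcations()
    for nd in a.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        tips = frozenset(l.taxon.label for l in nd.leaf_iter())
        if len(tips) == 2:
            return frozenset((tips, frozenset(set(quad) - tips)))
    return None


def brute_quartet_score(cand, gene_trees, labels):
    s = 0
    for g in gene_trees:
        for quad in itertools.combinations(labels, 4):
            qa = induced_quartet(g, quad)
            if qa is not None and qa == induced_quartet(cand, quad):
                s += 1
    return s


class TestQuartetScore:
    def test_identical_four_and_five_taxon_trees(self):
        t4 = tr.read_newick("((a,b),(c,d));")
        assert st.quartet_score(t4, [t4.clone(depth=1)]) == 1
        t5 = tr.read_newick("((a,b),(c,(d,e)));")
        assert st.quartet_score(t5, [t5.clone(depth=1)]) == 5  # C(5,4)

    def test_matches_direct_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        labels = [f"t{i}" for i in range(6)]
        for _ in range(20):
            gts = [rand_tree(6, rng) for _ in range(20)]
            cand = rand_tree(6, rng)
            assert st.quartet_score(cand, gts) == brute_quartet_score(
                cand, gts, labels
            )

    def test_invariant_to_gene_tree_order(self):
        rng = np.random.default_rng(3)
        gts = [rand_tree(6, rng) for _ in range(10)]
        cand = rand_tree(6, rng)
        assert st.quartet_score(cand, gts) == st.quartet_score(cand, gts[::-1])


class TestInferSpeciesTree:
    def test_identical_gene_trees_recovered_with_capped_lengths(self):
        t = tr.read_newick("((a,b),((c,d),(e,f)));")
        gts = [t.clone(depth=1) for _ in range(5)]
        out = st.infer_species_tree(gts, mode="exhaustive")
        assert set(tr.bipartition_masks(out._search_adj, 6).values()) == set(
            tr.bipartition_masks(
                tr.adjacency_from_dendropy(t, out._quartet_table.index), 6
            ).values()
        )
        for q in out.quartet_agreement.values():
            assert q == 1.0
        for e in out.preorder_edge_iter():
            if e.tail_node is not None and not e.head_node.is_leaf():
                assert e.length == st.COAL_LEN_CAP

    def test_coalescent_length_formula_boundaries(self):
        assert st.coalescent_length(1 / 3) == 0.0
        assert st.coalescent_length(1.0) == st.COAL_LEN_CAP
        assert st.coalescent_length(0.9) == pytest.approx(-np.log(1.5 * 0.1))

    def test_exhaustive_attains_oracle_maximum(self):
        # exhaustive search must reach the best score over ALL topologies,
        # where each topology is scored by the independent oracle
        rng = np.random.default_rng(4)
        labels = [f"t{i}" for i in range(6)]
        for rep in range(3):
            gts = [rand_tree(6, rng) for _ in range(10)]
            out = st.infer_species_tree(gts, mode="exhaustive")
            best_oracle = max(
                brute_quartet_score(
                    tr.read_newick(tr.to_newick(adj, labels)), gts, labels
                )
                for adj in tr.enumerate_topologies(6)
            )
            assert out.quartet_score_value == best_oracle

    def test_heuristic_matches_exhaustive_best_score(self):
        rng = np.random.default_rng(5)
        for rep in range(20):
            gts = [rand_tree(6, rng) for _ in range(15)]
            ex = st.infer_species_tree(gts, mode="exhaustive")
            he = st.infer_species_tree(gts, mode="heuristic")
            assert he.quartet_score_value <= ex.quartet_score_value
        # and the hill-climb finds the optimum in most replicates when the
        # signal is consistent
        t = tr.read_newick("(((a,b),(c,d)),((e,f),(g,h)));")
        gts = [t.clone(depth=1) for _ in range(10)]
        he = st.infer_species_tree(gts, mode="heuristic")
        ex = st.infer_species_tree(gts, mode="exhaustive")
        assert he.quartet_score_value == ex.quartet_score_value

    def test_too_few_taxa_rejected(self):
        t = tr.read_newick("((a,b),c);")
        with pytest.raises(ValueError):
            st.infer_species_tree([t, t.clone(depth=1)])


class TestMultilocusBootstrap:
    def test_identical_gene_trees_give_full_support(self, rng):
        t = tr.read_newick("((a,b),((c,d),e));")
        gts = [t.clone(depth=1) for _ in range(12)]
        _, supports = st.multilocus_bootstrap(gts, B=25, rng=rng, mode="exhaustive")
        assert supports and all(s == 1.0 for s in supports.values())

    def test_majority_topology_dominates_eighty_twenty(self, rng):
        # genes split 80/20 between two 4-taxon topologies: P(majority
        # flips in a resample of 100 genes) is astronomically small
        t_major = tr.read_newick("((a,b),(c,d));")
        t_minor = tr.read_newick("((a,c),(b,d));")
        gts = [t_major.clone(depth=1) for _ in range(80)] + [
            t_minor.clone(depth=1) for _ in range(20)
        ]
        _, supports = st.multilocus_bootstrap(gts, B=200, rng=rng, mode="exhaustive")
        assert min(supports.values()) > 0.95

    def test_supports_invariant_to_gene_order(self):
        t_major = tr.read_newick("((a,b),(c,d));")
        t_minor = tr.read_newick("((a,c),(b,d));")
        gts = [t_major.clone(depth=1) for _ in range(8)] + [
            t_minor.clone(depth=1) for _ in range(2)
        ]
        _, s1 = st.multilocus_bootstrap(
            gts, B=50, rng=np.random.default_rng(0), mode="exhaustive"
        )
        _, s2 = st.multilocus_bootstrap(
            gts[::-1], B=50, rng=np.random.default_rng(0), mode="exhaustive"
        )
        assert s1 == s2

    def test_zero_replicates_rejected(self, rng):
        t = tr.read_newick("((a,b),(c,d));")
        with pytest.raises(ValueError):
            st.multilocus_bootstrap([t], B=0, rng=rng)


class TestRootAndCollapse:
    def test_collapse_boundary_strictly_below_min_len(self):
        nwk = "((a:1,b:1):0.049,(c:1,d:1):0.05,o:1);"
        tree = tr.read_newick(nwk)
        out = st.root_and_collapse(tree, "o", min_len=0.05)
        # the 0.049 branch collapses, the 0.05 branch stays
        internal = [
            nd for nd in out.preorder_node_iter()
            if not nd.is_leaf() and nd.parent_node is not None
            and nd.edge.length is not None
        ]
        lengths = sorted(
            nd.edge.length for nd in internal
            if len(nd.leaf_nodes()) == 2 and nd.edge.length > 0
        )
        assert 0.05 in lengths and 0.049 not in lengths
        assert len(out.leaf_nodes()) == 5

    def test_no_short_branch_keeps_topology(self):
        tree = tr.read_newick("((a:1,b:1):0.5,((c:1,d:1):0.6,e:1):0.7,o:1);")
        before = len(tree.leaf_nodes())
        out = st.root_and_collapse(tree, "o")
        assert len(out.leaf_nodes()) == before
        tips = frozenset(l.taxon.label for l in out.leaf_node_iter())
        assert tips == frozenset("abcdeo")

    def test_missing_outgroup_errors(self):
        tree = tr.read_newick("((a,b),(c,d));")
        with pytest.raises(ValueError):
            st.root_and_collapse(tree, "zzz")
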