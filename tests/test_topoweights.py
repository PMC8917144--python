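"""Windowing, window trees and topology-weight properties."""

import numpy as np
import pytest

import sbkit.trees as tr
from sbkit import topoweights as tw
from sbkit.seqs import GeneAlignment
from sbkit.simdata import GeneLayout


def layouts(n, chrom="chr16", L=100):
    return [
        GeneLayout(f"g{i:03d}", chrom, i * (L + 10), i * (L + 10) + L, True)
        for i in range(n)
    ]


class TestMakeWindows:
    def test_eight_genes_two_windows(self):
        w = tw.make_windows(layouts(8), 4)
        assert w == [[f"g{i:03d}" for i in range(4)],
                     [f"g{i:03d}" for i in range(4, 8)]]

    def test_nine_genes_drop_remainder(self):
        w = tw.make_windows(layouts(9), 4)
        assert len(w) == 2 and all(len(x) == 4 for x in w)

    def test_order_invariant_to_shuffling(self, rng):
        ls = layouts(12)
        shuffled = list(ls)
        rng.shuffle(shuffled)
        assert tw.make_windows(ls, 4) == tw.make_windows(shuffled, 4)

    def test_bad_window_size(self):
        with pytest.raises(ValueError):
            tw.make_windows(layouts(4), 0)


class TestWindowTree:
    def test_concatenation_length_and_topology(self, rng):
        seqs = np.zeros((4, 50), dtype=np.uint8)
        seqs[2:, :20] = 3
        seqs[1, 49] = 1
        seqs[3, 48] = 2
        aln = GeneAlignment("g0", list("abcd"), seqs)
        copies = [GeneAlignment(f"g{i}", list("abcd"), seqs.copy()) for i in range(4)]
        single = tw.window_tree([aln])
        four = tw.window_tree(copies)
        assert sum(len(a.seqs[0]) for a in copies) == 200
        bip = lambda t: {
            frozenset(l.taxon.label for l in nd.leaf_iter())
            for nd in t.preorder_node_iter() if not nd.is_leaf()
        }
        assert bip(single) == bip(four)

    def test_inconsistent_sample_sets_rejected(self):
        a = GeneAlignment("g0", list("abcd"), np.zeros((4, 10), dtype=np.uint8))
        b = GeneAlignment("g1", list("abce"), np.zeros((4, 10), dtype=np.uint8))
        with pytest.raises(ValueError):
            tw.window_tree([a, b])


class TestTopologyWeights:
    def test_reciprocally_monophyletic_groups_weight_one(self):
        tree = tr.read_newick("(((a1,a2),(b1,b2)),((c1,c2),(d1,d2)));")
        gm = {"A": ["a1", "a2"], "B": ["b1", "b2"],
              "C": ["c1", "c2"], "D": ["d1", "d2"]}
        weights, names, used = tw.topology_weights(tree, gm)
        assert used == 16
        top = max(weights.values())
        assert top == 1.0
        winner = [t for t, v in weights.items() if v == top][0]
        assert tw.topology_id(winner, names) == "((A,B),(C,D))"

    def test_weights_sum_to_one_and_three_components(self, rng):
        tree = tr.read_newick(
            tr.to_newick(tr.random_topology(12, rng), [f"t{i}" for i in range(12)])
        )
        gm = {c: [f"t{3 * i + j}" for j in range(3)] for i, c in enumerate("ABCD")}
        weights, _, _ = tw.topology_weights(tree, gm)
        assert len(weights) == 3
        assert sum(weights.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in weights.values())

    def test_sampled_matches_exhaustive_within_tolerance(self, rng):
        for rep in range(5):
            tree = tr.read_newick(
                tr.to_newick(tr.random_topology(12, rng), [f"t{i}" for i in range(12)])
            )
            gm = {c: [f"t{3 * i + j}" for j in range(3)] for i, c in enumerate("ABCD")}
            ex, _, _ = tw.topology_weights(tree, gm, mode="exhaustive")
            sa, _, _ = tw.topology_weights(tree, gm, mode="sample", m=2000, rng=rng)
            for t in ex:
                assert abs(ex[t] - sa[t]) <= 0.03

    def test_saturated_sampling_equals_exhaustive_exactly(self, rng):
        tree = tr.read_newick("(((a1,a2),(b1,b2)),((c1,c2),(d1,d2)));")
        gm = {"A": ["a1", "a2"], "B": ["b1", "b2"],
              "C": ["c1", "c2"], "D": ["d1", "d2"]}
        ex, _, _ = tw.topology_weights(tree, gm, mode="exhaustive")
        sa, _, _ = tw.topology_weights(tree, gm, mode="sample", m=16, rng=rng)
        assert ex == sa

    def test_weights_invariant_to_rotation(self):
        t1 = tr.read_newick("(((a1,a2),(b1,b2)),((c1,c2),(d1,d2)));")
        t2 = tr.read_newick("((((b2,b1),(a2,a1))),((d1,d2),(c2,c1)));")
        gm = {"A": ["a1", "a2"], "B": ["b1", "b2"],
              "C": ["c1", "c2"], "D": ["d1", "d2"]}
        w1, _, _ = tw.topology_weights(t1, gm)
        w2, _, _ = tw.topology_weights(t2, gm)
        assert w1 == w2

    def test_absent_group_rejected(self):
        tree = tr.read_newick("((a1,b1),(c1,o1));")
        with pytest.raises(ValueError):
            tw.topology_weights(tree, {"A": ["a1"], "B": ["b1"], "C": ["zz"]})

    def test_five_groups_give_fifteen_topologies(self):
        assert len(tw.group_topologies(5)) == 15
        assert len(tw.group_topologies(4)) == 3


class TestSummaries:
    def make_rows(self, winners):
        topos = ["X", "Y", "Z"]
        rows = []
        for i, w in enumerate(winners):
            weights = {t: (0.6 if t == w else 0.2) for t in topos}
            if w is None:
                weights = {"X": 0.4, "Y": 0.4, "Z": 0.2}
            rows.append(
                tw.TopologyWeightRow(f"w{i}", [f"g{i}"], weights, w, 16)
            )
        return rows

    def test_counts_and_conservation(self):
        rows = self.make_rows(["X", "X", "Y", None, "X"])
        s = tw.summarize_windows(rows)
        assert s["counts"] == {"X": 3, "Y": 1, "Z": 0}
        assert s["ties"] == 1
        assert sum(s["counts"].values()) + s["ties"] == s["n_windows"]
        assert s["ratios"]["X / Y"] == 3.0

    def test_all_one_winner(self):
        rows = self.make_rows(["X"] * 4)
        s = tw.summarize_windows(rows)
        assert s["counts"]["X"] == 4 and s["counts"]["Y"] == 0


class TestSimulatedSupergeneWindows:
    def test_introgression_topology_wins_windows(self):
        from sbkit import simdata as sd

        wins = 0
        n_seeds = 4
        for seed in range(n_seeds):
            cfg = sd.preset_introgression(
                seed=seed, n_genes=40, n_supergene=25,
                n_diploid_contaminants=0, n_collapsed_repeat_regions=0,
            )
            alns, _, _ = sd.simulate_alignments(cfg)
            sg_idx = list(cfg.supergene.supergene_gene_indices)
            by_gene = {alns[i].gene_id: alns[i] for i in sg_idx}
            lays = [
                sd.GeneLayout(alns[i].gene_id, "chr16", j * 5200, j * 5200 + 5000, True)
                for j, i in enumerate(sg_idx)
            ]
            windows = tw.make_windows(lays, 4)
            assert len(windows) == 6  # 25 genes -> 6 windows, 1 dropped
            labels = alns[0].labels
            gm = {
                "donorSB": [l for l in labels if l.startswith("inv_SB")],
                "recipSB": [l for l in labels if l.startswith("rich_SB")],
                "sb": [l for l in labels
                       if l.startswith(("inv_Sb", "rich_Sb"))],
                "outgroup": [l for l in labels if l.startswith("gem_")],
            }
            rows = tw.weigh_windows(by_gene, windows, gm, seed=seed)
            s = tw.summarize_windows(rows)
            intro = "((donorSB,sb),(outgroup,recipSB))"
            trans = "((donorSB,recipSB),(outgroup,sb))"
            if s["counts"][intro] > s["counts"][trans]:
                wins += 1
        assert wins >= n_seeds - 1
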