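"""Quartet-based coalescent summary of gene trees.

The objective is the classic coalescent-consistent quartet score: the
number of induced 4-taxon topologies in the gene trees that agree with a
candidate tree.  The search is exhaustive for <= 8 tips and otherwise a
deterministic NNI hill-climb from a neighbor-joining start on mean
internode-count distances (a re-implementation of the objective, not of
any particular search engine).

Internal branch lengths are reported in coalescent units via
``d = -ln(1.5 (1 - q))`` where q is the fraction of resolved induced
quartets around the edge that agree with it (capped at 10 when q = 1);
terminal branches carry a nominal length of 1.  Support comes from a
multilocus bootstrap (resampling genes, not sites).
"""

from __future__ import annotations

import itertools
import logging

import dendropy
import numpy as np

from . import trees as tr

log = logging.getLogger(__name__)

COAL_LEN_CAP = 10.0


# ---------------------------------------------------------------------------
# gene-tree quartet tables
# ---------------------------------------------------------------------------

class QuartetTable:
    """Per-gene induced quartet codes over a fixed sorted label list."""

    def __init__(self, labels, codes):
        self.labels = list(labels)
        self.index = {l: i for i, l in enumerate(self.labels)}
        self.codes = codes  # (n_genes, n_quartets) int8; 3 = unresolved/absent
        self.combos = tr.quartet_combos(len(self.labels))
        # per-quartet histogram of resolved gene codes; a candidate's score
        # is then a single gather, independent of the number of gene trees
        hist = np.zeros((codes.shape[1], 4), dtype=np.int32)
        for c in range(3):
            hist[:, c] = (codes == c).sum(axis=0)
        self._hist = hist  # column 3 (unresolved) stays 0
        self._arange = np.arange(codes.shape[1])

    @property
    def n_genes(self):
        return self.codes.shape[0]

    def score_codes(self, cand_codes: np.ndarray) -> int:
        return int(self._hist[self._arange, cand_codes].sum())

    def score_adjacency(self, adj) -> int:
        return self.score_codes(tr.tree_quartet_codes(adj, len(self.labels)))


def _tree_tip_labels(tree) -> list:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def build_quartet_table(gene_trees, labels=None) -> QuartetTable:
    if labels is None:
        labels = sorted(set(itertools.chain.from_iterable(
            _tree_tip_labels(t) for t in gene_trees)))
    labels = list(labels)
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    combos = tr.quartet_combos(n)
    codes = np.full((len(gene_trees), combos.shape[0]), tr.UNRESOLVED, dtype=np.int8)
    for g, tree in enumerate(gene_trees):
        tips = [l for l in _tree_tip_labels(tree) if l in index]
        sub_global = sorted(index[l] for l in tips)
        if len(sub_global) < 4:
            continue
        if len(sub_global) == n:
            adj = tr.adjacency_from_dendropy(tree, index)
            codes[g] = tr.quartet_codes(tr.topo_distances(adj, n), combos)
        else:
            # gene tree missing taxa: compute on the subset, scatter by rank
            local_labels = [labels[i] for i in sub_global]
            local_index = {l: i for i, l in enumerate(local_labels)}
            adj = tr.adjacency_from_dendropy(tree, local_index)
            sub_codes = tr.quartet_codes(
                tr.topo_distances(adj, len(local_labels)),
                tr.quartet_combos(len(local_labels)),
            )
            gmap = np.array(sub_global)
            gq = gmap[tr.quartet_combos(len(local_labels))]
            codes[g, tr.quartet_rank(gq, n)] = sub_codes
    return QuartetTable(labels, codes)


def quartet_score(candidate: dendropy.Tree, gene_trees) -> int:
    """Number of gene-tree-induced resolved quartets agreeing with the
    candidate (unresolved / absent quartets contribute 0)."""
    cand_labels = sorted(_tree_tip_labels(candidate))
    table = build_quartet_table(gene_trees, labels=cand_labels)
    adj = tr.adjacency_from_dendropy(candidate, table.index)
    return table.score_adjacency(adj)


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def _mean_internode_distance(gene_trees, labels):
    n = len(labels)
    index = {l: i for i, l in enumerate(labels)}
    tot = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for tree in gene_trees:
        tips = [l for l in _tree_tip_labels(tree) if l in index]
        li = {l: i for i, l in enumerate(tips)}
        adj = tr.adjacency_from_dendropy(tree, li)
        D = tr.topo_distances(adj, len(tips))
        gl = np.array([index[l] for l in tips])
        tot[np.ix_(gl, gl)] += D
        cnt[np.ix_(gl, gl)] += 1
    if (cnt[~np.eye(n, dtype=bool)] == 0).any():
        raise ValueError("some taxon pair never co-occurs in a gene tree")
    with np.errstate(invalid="ignore"):
        D = tot / np.maximum(cnt, 1)
    np.fill_diagonal(D, 0.0)
    return D


def _exhaustive_best(table: QuartetTable):
    best_adj, best_score, ties = None, -1, 0
    n = len(table.labels)
    for adj in tr.enumerate_topologies(n):
        s = table.score_adjacency(adj)
        if s > best_score:
            best_adj, best_score, ties = adj, s, 0
        elif s == best_score:
            ties += 1
    if ties:
        log.info("exhaustive search: %d topologies tie at score %d", ties, best_score)
    return best_adj, best_score


def _nni_climb(table: QuartetTable, adj):
    n = len(table.labels)
    score = table.score_adjacency(adj)
    improved = True
    while improved:
        improved = False
        for cand in tr.nni_neighbors(adj, n):
            s = table.score_adjacency(cand)
            if s > score:
                adj, score = cand, s
                improved = True
                break  # first improvement
    return adj, score


def _edge_q(table: QuartetTable, adj):
    """Per internal edge: fraction of resolved induced quartets around the
    edge agreeing with it."""
    n = len(table.labels)
    out = {}
    for u, v in tr.internal_edges(adj, n):
        sides = []
        ok = True
        for a, b in ((u, v), (v, u)):
            comps = []
            for nb in adj[a]:
                if nb == b:
                    continue
                comp = _component_tips(adj, nb, a, n)
                comps.append(comp)
            if len(comps) != 2:
                ok = False
                break
            sides.append(comps)
        if not ok:
            continue
        (a1, a2), (b1, b2) = sides
        quads = np.array(
            [
                (w, x, y, z)
                for w in a1 for x in a2 for y in b1 for z in b2
            ],
            dtype=np.int64,
        )
        srt = np.sort(quads, axis=1)
        ranks = tr.quartet_rank(srt, n)
        # expected code: pairing (a1,a2) | (b1,b2) expressed on sorted order
        order = np.argsort(quads, axis=1)
        min_col = order[:, 0]
        partner = np.where(min_col < 2, 1 - min_col, 5 - min_col)
        partner_pos = np.argmax(order == partner[:, None], axis=1)
        expected = (partner_pos - 1).astype(np.int8)
        obs = table.codes[:, ranks]
        resolved = obs != tr.UNRESOLVED
        agree = (obs == expected[None, :]) & resolved
        n_res = int(resolved.sum())
        out[(u, v)] = (agree.sum() / n_res) if n_res else np.nan
    return out


def _component_tips(adj, start, blocked, n_tips):
    tips = []
    stack = [start]
    seen = {blocked, start}
    while stack:
        x = stack.pop()
        if x < n_tips:
            tips.append(x)
        for y in adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return tips


def coalescent_length(q: float) -> float:
    """ASTRAL-convention internal branch length from quartet agreement."""
    if not np.isfinite(q) or q >= 1.0:
        return COAL_LEN_CAP
    return float(np.clip(-np.log(1.5 * (1.0 - q)), 0.0, COAL_LEN_CAP))


def _adj_to_tree(adj, table, taxon_namespace=None, supports=None):
    n = len(table.labels)
    qs = _edge_q(table, adj)
    lengths = {}
    for u, v in tr.edges(adj):
        if (u, v) in qs or (v, u) in qs:
            q = qs.get((u, v), qs.get((v, u)))
            lengths[frozenset((u, v))] = coalescent_length(q)
        else:
            lengths[frozenset((u, v))] = 1.0  # terminal: nominal
    newick = tr.to_newick(adj, table.labels, lengths, supports)
    tree = tr.read_newick(newick, taxon_namespace)
    tree.quartet_agreement = {
        frozenset(e): q for e, q in qs.items()
    }
    return tree


def infer_species_tree(
    gene_trees,
    mode: str = "heuristic",
    outgroup=None,
    labels=None,
    taxon_namespace=None,
    _start_adj=None,
):
    """Maximum-quartet-score summary tree.

    exhaustive mode enumerates all unrooted topologies (<= 8 tips; ties
    broken by enumeration order and logged); heuristic mode hill-climbs by
    NNI from an internode-distance NJ start.  The returned tree is unrooted
    (root it with :func:`root_and_collapse`); internal branch lengths are
    coalescent units from quartet agreement.
    """
    gene_trees = list(gene_trees)
    if len(gene_trees) < 2:
        raise ValueError("need at least 2 gene trees")
    table = build_quartet_table(gene_trees, labels=labels)
    n = len(table.labels)
    if n < 4:
        raise ValueError("fewer than 4 shared taxa")
    if mode == "exhaustive":
        if n > 8:
            raise ValueError("exhaustive mode requires <= 8 tips")
        adj, score = _exhaustive_best(table)
    elif mode == "heuristic":
        if _start_adj is not None:
            adj0 = _start_adj
        else:
            D = _mean_internode_distance(gene_trees, table.labels)
            adj0, _ = tr.neighbor_joining(D)
        adj, score = _nni_climb(table, adj0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    tree = _adj_to_tree(adj, table, taxon_namespace)
    tree.quartet_score_value = score
    tree._search_adj = adj
    tree._quartet_table = table
    return tree


def multilocus_bootstrap(
    gene_trees,
    B: int,
    rng: np.random.Generator,
    mode: str = "heuristic",
    labels=None,
    point_tree=None,
):
    """Gene-resampling bootstrap: supports for the point tree's bipartitions.

    Replicate searches start from the point-estimate topology (heuristic
    mode), which makes B=100 tractable without changing the objective.
    Returns (annotated point tree, {bipartition mask: support}).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    gene_trees = list(gene_trees)
    if point_tree is None:
        point_tree = infer_species_tree(gene_trees, mode=mode, labels=labels)
    table = point_tree._quartet_table
    n = len(table.labels)
    point_adj = point_tree._search_adj
    ref_masks = tr.bipartition_masks(point_adj, n)
    hits = {m: 0 for m in ref_masks.values()}
    # canonical gene order: supports depend on the gene-tree multiset,
    # not on input order
    order = sorted(range(table.n_genes), key=lambda g: table.codes[g].tobytes())
    codes = table.codes[order]
    for _ in range(B):
        idx = rng.integers(0, table.n_genes, size=table.n_genes)
        sub = QuartetTable(table.labels, codes[idx])
        if mode == "exhaustive" and n <= 8:
            radj, _ = _exhaustive_best(sub)
        else:
            radj, _ = _nni_climb(sub, point_adj)
        rep = set(tr.bipartition_masks(radj, n).values())
        for m in hits:
            if m in rep:
                hits[m] += 1
    supports_by_edge = {
        frozenset(e): hits[m] / B for e, m in ref_masks.items()
    }
    annotated = _adj_to_tree(
        point_adj, table, None, supports=supports_by_edge
    )
    annotated.quartet_score_value = point_tree.quartet_score_value
    annotated._search_adj = point_adj
    annotated._quartet_table = table
    support_by_mask = {m: hits[m] / B for m in hits}
    return annotated, support_by_mask


# ---------------------------------------------------------------------------
# rooting and polytomy collapse
# ---------------------------------------------------------------------------

def root_and_collapse(
    tree: dendropy.Tree, outgroup, min_len: float = 0.05
) -> dendropy.Tree:
    """Root on the outgroup edge and contract internal branches shorter
    than ``min_len`` into polytomies.  The tip set is preserved."""
    if isinstance(outgroup, str):
        outgroup = [outgroup]
    t = tree.clone(depth=1)
    taxa = [t.taxon_namespace.get_taxon(o) for o in outgroup]
    if any(x is None for x in taxa):
        missing = [o for o, x in zip(outgroup, taxa) if x is None]
        raise ValueError(f"outgroup tip(s) absent: {missing}")
    tip_labels = {lf.taxon.label for lf in t.leaf_node_iter()}
    absent = [o for o in outgroup if o not in tip_labels]
    if absent:
        raise ValueError(f"outgroup tip(s) absent: {absent}")
    # root at an ingroup tip so the outgroup MRCA is well-defined
    ingroup_tip = next(
        lf for lf in t.leaf_node_iter() if lf.taxon.label not in outgroup
    )
    t.reroot_at_edge(ingroup_tip.edge, update_bipartitions=False)
    first = t.find_node_with_taxon_label(outgroup[0])
    if len(taxa) == 1:
        og_node = first
    else:
        og_node = t.mrca(taxa=taxa)
        og_tips = {lf.taxon.label for lf in og_node.leaf_iter()}
        if og_tips != set(outgroup):
            log.warning("outgroup not monophyletic; rooting at %s", outgroup[0])
            og_node = first
    edge = og_node.edge
    ln = edge.length or 0.0
    t.reroot_at_edge(edge, length1=ln / 2.0, length2=ln / 2.0,
                     update_bipartitions=False)
    t.suppress_unifurcations()
    # collapse short internal branches
    for nd in list(t.postorder_node_iter()):
        if nd.is_leaf() or nd is t.seed_node or nd.parent_node is None:
            continue
        if nd.edge.length is not None and nd.edge.length < min_len:
            nd.edge.collapse()
    return t
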