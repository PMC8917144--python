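"""Low-level unrooted-tree machinery shared by the tree-building modules.

Trees here are plain adjacency maps over integer node ids: tips are
``0 .. n_tips-1`` (indices into a caller-supplied label list), internal
nodes follow.  dendropy handles rooted-tree bookkeeping at the module
boundaries; this module does the numeric work -- neighbor joining,
induced-quartet extraction via the four-point condition, NNI moves and
exhaustive topology enumeration -- where a lightweight representation wins.

Induced quartet topologies are encoded as int8 codes over the sorted
quartet (w < x < y < z):

=====  ==================
code   resolution
=====  ==================
0      wx | yz
1      wy | xz
2      wz | xy
3      unresolved (star)
=====  ==================
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

UNRESOLVED = 3

Adjacency = dict  # node id -> list of neighbor ids


def new_taxon_namespace():
    """Case-sensitive taxon namespace (SB and Sb must not collide)."""
    import dendropy

    return dendropy.TaxonNamespace(is_case_sensitive=True)


def read_newick(data: str, taxon_namespace=None):
    """Parse one newick tree with case-sensitive, underscore-preserving
    taxon labels (dendropy's defaults would merge SB/Sb sample names)."""
    import dendropy

    return dendropy.Tree.get(
        data=data,
        schema="newick",
        taxon_namespace=taxon_namespace
        if taxon_namespace is not None
        else new_taxon_namespace(),
        preserve_underscores=True,
        case_sensitive_taxon_labels=True,
        suppress_internal_node_taxa=True,
    )


# ---------------------------------------------------------------------------
# construction / conversion
# ---------------------------------------------------------------------------

def copy_adjacency(adj: Adjacency) -> Adjacency:
    return {u: list(vs) for u, vs in adj.items()}


def star_adjacency(n_tips: int) -> Adjacency:
    """Single internal node joined to every tip (the n-taxon star)."""
    hub = n_tips
    adj = {hub: list(range(n_tips))}
    for t in range(n_tips):
        adj[t] = [hub]
    return adj


def edges(adj: Adjacency):
    seen = set()
    for u, vs in adj.items():
        for v in vs:
            e = (u, v) if u < v else (v, u)
            if e not in seen:
                seen.add(e)
                yield e


def internal_edges(adj: Adjacency, n_tips: int):
    for u, v in edges(adj):
        if u >= n_tips and v >= n_tips:
            yield (u, v)


def _next_node_id(adj: Adjacency) -> int:
    return max(adj) + 1


def insert_tip_on_edge(adj: Adjacency, tip: int, edge: tuple[int, int]) -> Adjacency:
    """Return a copy of *adj* with *tip* attached to the middle of *edge*."""
    u, v = edge
    new = copy_adjacency(adj)
    w = _next_node_id(new)
    new[u][new[u].index(v)] = w
    new[v][new[v].index(u)] = w
    new[w] = [u, v, tip]
    new[tip] = [w]
    return new


def enumerate_topologies(n_tips: int):
    """Yield every unrooted binary topology on ``n_tips`` labelled tips.

    Stepwise addition: (2n-5)!! topologies, so callers should keep
    ``n_tips <= 8`` (10395 trees).
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    h = n_tips  # internal ids start above the tip range
    base = {h: [0, 1, 2], 0: [h], 1: [h], 2: [h]}
    stack = [(base, 3)]
    while stack:
        adj, k = stack.pop()
        if k == n_tips:
            yield adj
            continue
        for e in list(edges(adj)):
            stack.append((insert_tip_on_edge(adj, k, e), k + 1))


def random_topology(n_tips: int, rng: np.random.Generator) -> Adjacency:
    """Uniform random unrooted binary topology by random stepwise addition."""
    h = n_tips
    adj = {h: [0, 1, 2], 0: [h], 1: [h], 2: [h]}
    for k in range(3, n_tips):
        es = list(edges(adj))
        adj = insert_tip_on_edge(adj, k, es[rng.integers(len(es))])
    return adj


def adjacency_from_dendropy(tree, label_index: dict[str, int]) -> Adjacency:
    """Convert a dendropy tree to adjacency form.

    Degree-2 nodes (e.g. a rooted tree's root) are retained; the four-point
    condition is unaffected because the structure is still a tree.
    """
    adj: Adjacency = {}
    node_ids: dict[int, int] = {}
    nxt = len(label_index)
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label
            if label not in label_index:
                raise KeyError(f"tip {label!r} not in label index")
            node_ids[id(nd)] = label_index[label]
        else:
            node_ids[id(nd)] = nxt
            nxt += 1
        adj.setdefault(node_ids[id(nd)], [])
    for nd in tree.preorder_node_iter():
        u = node_ids[id(nd)]
        for ch in nd.child_nodes():
            v = node_ids[id(ch)]
            adj[u].append(v)
            adj[v].append(u)
    return adj


def to_newick(
    adj: Adjacency,
    labels: list[str],
    lengths: dict | None = None,
    supports: dict | None = None,
) -> str:
    """Serialize adjacency to newick.

    ``lengths``/``supports`` are keyed by frozenset edge; supports are
    attached as internal-node labels of the edge above the node.
    """
    n_tips = len(labels)
    # root the traversal at an internal node (or tip 0's neighbor)
    start = next((u for u in adj if u >= n_tips), 0)

    def fmt_len(u, v):
        if lengths is None:
            return ""
        return f":{lengths[frozenset((u, v))]:.8g}"

    def rec(u, parent):
        if u < n_tips:
            return labels[u] + fmt_len(u, parent)
        parts = [rec(v, u) for v in adj[u] if v != parent]
        lab = ""
        if supports is not None and parent is not None:
            key = frozenset((u, parent))
            if key in supports:
                lab = f"{supports[key]:g}"
        suffix = fmt_len(u, parent) if parent is not None else ""
        return "(" + ",".join(parts) + ")" + lab + suffix

    return rec(start, None) + ";"


# ---------------------------------------------------------------------------
# distances and quartets
# ---------------------------------------------------------------------------

def topo_distances(adj: Adjacency, n_tips: int) -> np.ndarray:
    """Tip-to-tip path lengths in edge counts (BFS from each tip)."""
    D = np.zeros((n_tips, n_tips), dtype=np.int32)
    for src in range(n_tips):
        dist = {src: 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for t in range(n_tips):
            D[src, t] = dist[t]
    return D


@lru_cache(maxsize=64)
def quartet_combos(n_tips: int) -> np.ndarray:
    """All sorted 4-subsets of ``range(n_tips)`` in lexicographic order."""
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n_tips), 4)),
        dtype=np.int32,
    ).reshape(-1, 4)
    combos.setflags(write=False)
    return combos


def quartet_codes(D: np.ndarray, combos: np.ndarray) -> np.ndarray:
    """Four-point-condition quartet codes for every row of *combos*.

    For tree metrics the pairing with the strictly smallest sum of
    within-pair distances is the induced topology; if the minimum is not
    unique the quartet is a star (UNRESOLVED).
    """
    a, b, c, d = combos[:, 0], combos[:, 1], combos[:, 2], combos[:, 3]
    sums = np.stack(
        [D[a, b] + D[c, d], D[a, c] + D[b, d], D[a, d] + D[b, c]], axis=1
    )
    code = np.argmin(sums, axis=1).astype(np.int8)
    m = sums.min(axis=1, keepdims=True)
    tie = (sums == m).sum(axis=1) > 1
    code[tie] = UNRESOLVED
    return code


def tree_quartet_codes(adj: Adjacency, n_tips: int) -> np.ndarray:
    return quartet_codes(topo_distances(adj, n_tips), quartet_combos(n_tips))


@lru_cache(maxsize=64)
def _rank_tables(n: int):
    """Cumulative tables for lexicographic ranking of sorted 4-subsets."""
    idx = np.arange(n)
    c3 = np.array([_comb(n - 1 - a, 3) for a in range(n)], dtype=np.int64)
    c2 = np.array([_comb(n - 1 - b, 2) for b in range(n)], dtype=np.int64)
    c1 = np.array([n - 1 - c for c in range(n)], dtype=np.int64)
    t1 = np.concatenate([[0], np.cumsum(c3)])     # combos with first < i
    s2 = np.concatenate([[0], np.cumsum(c2)])
    s3 = np.concatenate([[0], np.cumsum(c1)])
    del idx
    return t1, s2, s3


def _comb(n, k):
    if n < k:
        return 0
    from math import comb

    return comb(n, k)


def quartet_rank(q: np.ndarray, n: int) -> np.ndarray:
    """Lexicographic rank of sorted quartets ``q`` (shape (m, 4)) among
    ``itertools.combinations(range(n), 4)``."""
    t1, s2, s3 = _rank_tables(n)
    i, j, k, l = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    return (
        t1[i]
        + (s2[j] - s2[i + 1])
        + (s3[k] - s3[j + 1])
        + (l - k - 1)
    )


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: np.ndarray, clamp_negative: bool = True):
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Parameters
    ----------
    D:
        Symmetric distance matrix over tips ``0..n-1``.
    clamp_negative:
        Clamp negative branch-length estimates to zero.

    Returns
    -------
    (adj, lengths):
        Adjacency over node ids (tips ``0..n-1``) and branch lengths keyed
        by frozenset edge.  The tree is unrooted; the last join produces a
        trifurcation (or the trivial 2- and 3-tip shapes).

    Ties in the Q criterion are broken toward the lowest (row, column)
    index pair, which makes the output a pure function of the matrix.
    """
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 tips")
    adj: Adjacency = {i: [] for i in range(n)}
    lengths: dict = {}

    def connect(u, v, ln):
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
        lengths[frozenset((u, v))] = max(ln, 0.0) if clamp_negative else ln

    if n == 2:
        connect(0, 1, float(D[0, 1]))
        return adj, lengths

    active = list(range(n))
    dist = D.astype(float).copy()
    nxt = n
    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = np.argmin(Q)          # first minimum in row-major order ->
        i, j = divmod(flat, m)       # lowest (i, j) on ties
        if i > j:
            i, j = j, i
        a, b = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        u = nxt
        nxt += 1
        connect(a, u, li)
        connect(b, u, lj)
        # distances from u to remaining nodes
        newrow = 0.5 * (sub[i, :] + sub[j, :] - dij)
        grown = np.zeros((dist.shape[0] + 1, dist.shape[1] + 1))
        grown[:-1, :-1] = dist
        for k_pos, k in enumerate(active):
            grown[u, k] = grown[k, u] = newrow[k_pos]
        dist = grown
        active = [x for x in active if x not in (a, b)] + [u]

    if len(active) == 3:
        a, b, c = active
        dab, dac, dbc = dist[a, b], dist[a, c], dist[b, c]
        u = nxt
        connect(a, u, 0.5 * (dab + dac - dbc))
        connect(b, u, 0.5 * (dab + dbc - dac))
        connect(c, u, 0.5 * (dac + dbc - dab))
    return adj, lengths


# ---------------------------------------------------------------------------
# NNI and bipartitions
# ---------------------------------------------------------------------------

def nni_neighbors(adj: Adjacency, n_tips: int):
    """Yield the 2 NNI rearrangements of every internal edge."""
    for u, v in internal_edges(adj, n_tips):
        a_side = [x for x in adj[u] if x != v]
        b_side = [x for x in adj[v] if x != u]
        if len(a_side) != 2 or len(b_side) != 2:
            continue  # polytomy: NNI undefined, skip
        a2 = a_side[1]
        for b in b_side:
            new = copy_adjacency(adj)
            new[u][new[u].index(a2)] = b
            new[v][new[v].index(b)] = a2
            new[a2][new[a2].index(u)] = v
            new[b][new[b].index(v)] = u
            yield new


def bipartition_masks(adj: Adjacency, n_tips: int) -> dict:
    """Non-trivial bipartitions as canonical tip bitmasks, keyed by edge.

    The canonical mask is the side *not* containing tip 0.
    """
    out = {}
    full = (1 << n_tips) - 1
    for u, v in internal_edges(adj, n_tips):
        # tips on v's side of the edge
        mask = 0
        stack = [v]
        seen = {u, v}
        while stack:
            x = stack.pop()
            if x < n_tips:
                mask |= 1 << x
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if mask & 1:
            mask = full & ~mask
        if 0 < mask < full:
            out[(u, v)] = mask
    return out
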