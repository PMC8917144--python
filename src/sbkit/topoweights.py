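"""Topology weighting over non-overlapping 4-gene windows of the supergene.

For each window a tree is built from the concatenated alignments (JC + NJ,
as for single genes) and its support is decomposed over group-level
topologies by enumerating (or sampling) one-tip-per-group subtrees, in the
manner of phylogenetic weighting methods.  For the supergene question the
four groups are donor-SB, recipient-SB, the Sb pool and the outgroup, and
the three possible unrooted topologies read as:

* ``((donorSB, Sb), (recipSB, out))`` -- introgression-like;
* ``((donorSB, recipSB), (Sb, out))`` -- trans-species-like;
* the third -- alternative.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from . import trees as tr
from .genetrees import gene_tree, jc_distance_matrix
from .seqs import GeneAlignment

log = logging.getLogger(__name__)


@dataclass
class TopologyWeightRow:
    window_id: str
    gene_ids: list
    weights: dict  # topology id -> weight in [0, 1]
    winner: str | None
    n_combinations_used: int

    def __post_init__(self):
        s = sum(self.weights.values())
        if self.weights and abs(s - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {s}, not 1")


def make_windows(gene_layouts, w: int = 4):
    """Consecutive disjoint blocks of ``w`` genes in genomic order;
    a trailing remainder of < w genes is dropped (logged)."""
    if w < 1:
        raise ValueError("window size must be >= 1")
    uniq = {}
    for lay in gene_layouts:
        uniq[lay.gene_id] = lay
    ordered = sorted(uniq.values(), key=lambda l: (l.chrom, l.start))
    windows = []
    for i in range(0, len(ordered) - w + 1, w):
        windows.append([l.gene_id for l in ordered[i:i + w]])
    dropped = len(ordered) - w * len(windows)
    if dropped:
        log.info("make_windows: %d trailing gene(s) dropped", dropped)
    return windows


def window_tree(alignments, taxon_namespace=None):
    """Tree from the concatenation of a window's alignments (JC + NJ)."""
    concat = GeneAlignment.concatenate(list(alignments))
    return gene_tree(concat, taxon_namespace=taxon_namespace)


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def group_topologies(k: int):
    """Canonical list of unrooted topologies over k labelled groups,
    as tuples of quartet codes over all C(k, 4) group quartets."""
    out = []
    for adj in tr.enumerate_topologies(k):
        out.append(tuple(tr.tree_quartet_codes(adj, k).tolist()))
    # enumeration can repeat shapes only for k < 4; deduplicate, keep order
    seen, uniq = set(), []
    for t in out:
        if t not in seen:
            seen.add(t)
            uniq.append(t)
    return uniq


def topology_weights(
    tree,
    group_map: dict,
    mode: str = "exhaustive",
    m: int = 2000,
    rng: np.random.Generator | None = None,
):
    """Weights over group topologies from one-tip-per-group subsampling.

    ``group_map``: group name -> list of tip labels (>= 3 groups, each with
    >= 1 tip present in the tree).  Returns (weights dict keyed by
    topology-code tuple, group order, n_combinations_used).  In sampled
    mode ``m`` combinations are drawn with replacement; exhaustive mode
    enumerates all of them.
    """
    group_names = sorted(group_map)
    if len(group_names) < 3:
        raise ValueError("need at least 3 groups")
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    index = {l: i for i, l in enumerate(labels)}
    members = []
    for g in group_names:
        present = [index[t] for t in group_map[g] if t in index]
        if not present:
            raise ValueError(f"group {g!r} absent from the tree")
        members.append(np.array(present))
    k = len(group_names)
    adj = tr.adjacency_from_dendropy(tree, index)
    D = tr.topo_distances(adj, len(labels))

    topos = group_topologies(k) if k >= 4 else [()]
    qsubs = list(itertools.combinations(range(k), 4))

    if mode == "exhaustive":
        grids = np.meshgrid(*members, indexing="ij")
        combos = np.stack([g.ravel() for g in grids], axis=1)
    elif mode == "sample":
        if rng is None:
            raise ValueError("sampled mode requires an rng")
        total = int(np.prod([len(mm) for mm in members]))
        if m >= total:
            # sampling without replacement saturates to the full enumeration
            grids = np.meshgrid(*members, indexing="ij")
            combos = np.stack([g.ravel() for g in grids], axis=1)
        else:
            combos = np.stack(
                [mm[rng.integers(0, len(mm), size=m)] for mm in members], axis=1
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # induced code per combo for every group quartet; the four-point
    # condition is order-free, so the code can be read directly in group
    # order (0: ab|cd, 1: ac|bd, 2: ad|bc over the group quartet a<b<c<d)
    code_cols = []
    for (a, b, c, d) in qsubs:
        ta, tb, tc, td = (combos[:, x] for x in (a, b, c, d))
        sums = np.stack(
            [D[ta, tb] + D[tc, td], D[ta, tc] + D[tb, td], D[ta, td] + D[tb, tc]],
            axis=1,
        )
        gcode = np.argmin(sums, axis=1).astype(np.int8)
        mmin = sums.min(axis=1, keepdims=True)
        gcode[(sums == mmin).sum(axis=1) > 1] = tr.UNRESOLVED
        code_cols.append(gcode)
    codes = np.stack(code_cols, axis=1)  # (n_combos, n_group_quartets)

    counts = {t: 0 for t in topos}
    unresolved = 0
    keys = [tuple(row) for row in codes]
    for key in keys:
        if key in counts:
            counts[key] += 1
        else:
            unresolved += 1
    used = len(keys) - unresolved
    if unresolved:
        log.info("topology_weights: %d combinations induced no binary "
                 "group topology", unresolved)
    if used == 0:
        raise ValueError("no combination induced a resolved group topology")
    # exact rationals: weights sum to exactly 1
    weights = {t: Fraction(counts[t], used) for t in topos}
    return weights, group_names, used


# readable ids for the canonical 4-group topologies, in group sort order
def topology_id(codes: tuple, group_names) -> str:
    if len(group_names) == 4 and len(codes) == 1:
        g = group_names
        return {
            0: f"(({g[0]},{g[1]}),({g[2]},{g[3]}))",
            1: f"(({g[0]},{g[2]}),({g[1]},{g[3]}))",
            2: f"(({g[0]},{g[3]}),({g[1]},{g[2]}))",
        }[codes[0]]
    return "topo" + "".join(str(c) for c in codes)


def weigh_windows(
    alignments_by_gene: dict,
    windows,
    group_map: dict,
    mode: str = "exhaustive",
    m: int = 2000,
    seed: int = 0,
):
    """TopologyWeightRow per window, using concatenation window trees."""
    from .util import stage_rng

    rows = []
    for wi, genes in enumerate(windows):
        wtree = window_tree([alignments_by_gene[g] for g in genes])
        rng = stage_rng(seed, "topoweights", f"w{wi}")
        weights, names, used = topology_weights(wtree, group_map, mode, m, rng)
        named = {topology_id(t, names): float(v) for t, v in weights.items()}
        mx = max(named.values())
        winners = [t for t, v in named.items() if v == mx]
        rows.append(
            TopologyWeightRow(
                f"window{wi:03d}", list(genes), named,
                winners[0] if len(winners) == 1 else None, used,
            )
        )
        if len(winners) > 1:
            log.info("window %d: tie between %s", wi, winners)
    return rows


def summarize_windows(rows):
    """Winner counts per topology and ordered pairwise count ratios."""
    if not rows:
        raise ValueError("no windows")
    topos = sorted(rows[0].weights)
    counts = {t: 0 for t in topos}
    ties = 0
    for r in rows:
        if r.winner is None:
            ties += 1
        else:
            counts[r.winner] += 1
    ratios = {}
    for a in topos:
        for b in topos:
            if a != b:
                ratios[f"{a} / {b}"] = (
                    counts[a] / counts[b] if counts[b] else np.inf
                )
    return {"counts": counts, "ties": ties, "n_windows": len(rows), "ratios": ratios}
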