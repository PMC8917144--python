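"""Per-sample consensus sequences and distance-based gene trees.

Gene trees are Jukes-Cantor-corrected neighbor-joining trees with site-
resampling bootstrap support.  This is a deliberate desk-scale substitution
for per-gene maximum likelihood: deterministic, fast, and sufficient input
for coalescent-summary inference, which consumes induced quartet topologies
rather than fine branch lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from . import trees as tr
from .genotypes import MISSING, GenotypeTable
from .seqs import N_CODE, GeneAlignment, encode

log = logging.getLogger(__name__)

MAX_DISTANCE = 5.0  # assigned when p >= 0.75 (JC correction undefined)
MIN_PAIR_OVERLAP = 50  # genes with any pair below this are unusable


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    single_copy: bool = True
    in_supergene: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty gene interval for {self.gene_id}")


def consensus_sequences(
    reference_gene_seq, table: GenotypeTable, gene: GeneModel
) -> GeneAlignment:
    """Reference-projected consensus: per sample, substitute the sample's
    alleles at its called sites; MISSING calls become N."""
    ref = reference_gene_seq
    if isinstance(ref, str):
        ref = encode(ref)
    ref = np.asarray(ref, dtype=np.uint8)
    if len(ref) != gene.end - gene.start:
        raise ValueError("reference sequence length does not match gene interval")
    s = table.sites
    in_gene = (s["chrom"].values == gene.chrom) & (
        (s["pos"].values > gene.start) & (s["pos"].values <= gene.end)
    )
    idx = np.flatnonzero(in_gene)
    offsets = s["pos"].values[idx] - gene.start - 1  # 0-based within gene
    n = table.n_samples
    seqs = np.tile(ref, (n, 1))
    for j, off in zip(idx, offsets):
        ref_b = s["ref"].iloc[j]
        alt_codes = [encode(a)[0] for a in s["alt"].iloc[j].split(",")]
        site_alleles = [encode(ref_b)[0]] + alt_codes
        calls = table.alleles[j]
        for i in range(n):
            a = calls[i]
            seqs[i, off] = N_CODE if a == MISSING else site_alleles[a]
    return GeneAlignment(gene.gene_id, list(table.samples), seqs)


def diffs_vs_reference(aln: GeneAlignment, reference_gene_seq) -> np.ndarray:
    ref = reference_gene_seq
    if isinstance(ref, str):
        ref = encode(ref)
    valid = aln.seqs != N_CODE
    return ((aln.seqs != ref[None, :]) & valid).sum(axis=1)


def select_informative(
    alignments,
    references,
    ingroup_samples,
    min_avg_diffs: float = 10.0,
):
    """Retain genes whose ingroup-average count of non-N differences from
    the reference is >= ``min_avg_diffs``.

    ``references`` maps gene_id -> reference sequence (str or codes).
    """
    if not ingroup_samples:
        raise ValueError("ingroup is empty")
    kept = []
    for aln in alignments:
        sub = aln.subset([s for s in ingroup_samples if s in aln.labels])
        if not sub.labels:
            continue
        avg = diffs_vs_reference(sub, references[aln.gene_id]).mean()
        if avg >= min_avg_diffs:
            kept.append(aln.gene_id)
    return kept


def jc_distance_matrix(aln: GeneAlignment, max_distance: float = MAX_DISTANCE):
    """Jukes-Cantor distances with pairwise deletion of N positions.

    Returns (D, overlap) where overlap[i, j] is the number of pairwise-
    complete positions.  p >= 0.75 maps to ``max_distance`` (with a logged
    warning); zero overlap raises.
    """
    S = aln.seqs
    valid = (S != N_CODE)
    overlap = (valid.astype(np.int32) @ valid.astype(np.int32).T)
    poly = np.flatnonzero(
        ~np.all((S == S[0]) | ~valid, axis=0) | ~valid.all(axis=0)
    )
    Sp = S[:, poly]
    vp = valid[:, poly]
    n = S.shape[0]
    mism = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        mism[i] = ((Sp[i][None, :] != Sp) & vp[i][None, :] & vp).sum(axis=1)
    if (overlap == 0).any() and n > 1:
        off = ~np.eye(n, dtype=bool)
        if (overlap[off] == 0).any():
            raise ValueError("a sequence pair has zero overlap")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = mism / overlap
    D = np.zeros((n, n))
    ok = p < 0.75
    D[ok] = -0.75 * np.log1p(-(4.0 / 3.0) * p[ok])
    if (~ok).any():
        log.warning("jc_distance: %d pairs at p >= 0.75 set to max", (~ok).sum() // 2)
        D[~ok] = max_distance
    np.fill_diagonal(D, 0.0)
    return D, overlap


def jc_correct(p: float) -> float:
    """Closed-form JC69 distance for a mismatch fraction."""
    if p >= 0.75:
        return MAX_DISTANCE
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


def _nj_dendropy(D, labels, taxon_namespace=None) -> dendropy.Tree:
    adj, lengths = tr.neighbor_joining(D)
    return tr.read_newick(tr.to_newick(adj, labels, lengths), taxon_namespace)


def gene_tree(
    aln: GeneAlignment,
    bootstrap_B: int = 0,
    rng: np.random.Generator | None = None,
    taxon_namespace=None,
) -> dendropy.Tree:
    """JC + neighbor joining with optional site-resampling bootstrap.

    Bootstrap supports (fraction of replicates containing each internal
    bipartition) are stored as internal node labels on the point tree.
    """
    n = len(aln.labels)
    if n < 3:
        raise ValueError("need at least 3 sequences")
    D, overlap = jc_distance_matrix(aln)
    off = ~np.eye(n, dtype=bool)
    if overlap[off].min() < MIN_PAIR_OVERLAP:
        log.warning(
            "gene %s: minimum pairwise overlap %d < %d sites",
            aln.gene_id, int(overlap[off].min()), MIN_PAIR_OVERLAP,
        )
    adj, lengths = tr.neighbor_joining(D)
    supports = None
    if bootstrap_B:
        if rng is None:
            raise ValueError("bootstrap requires an rng")
        ref_masks = tr.bipartition_masks(adj, n)
        hits = {e: 0 for e in ref_masks}
        L = aln.length
        for _ in range(bootstrap_B):
            cols = rng.integers(0, L, size=L)
            rep = GeneAlignment(aln.gene_id, aln.labels, aln.seqs[:, cols])
            Db, _ = jc_distance_matrix(rep)
            radj, _ = tr.neighbor_joining(Db)
            rep_masks = set(tr.bipartition_masks(radj, n).values())
            for e, m in ref_masks.items():
                if m in rep_masks:
                    hits[e] += 1
        supports = {
            frozenset(e): hits[e] / bootstrap_B for e in ref_masks
        }
    newick = tr.to_newick(adj, aln.labels, lengths, supports)
    return tr.read_newick(newick, taxon_namespace)


def read_gene_trees(path, taxon_namespace=None) -> dict:
    """Read precomputed gene trees: one ``gene_id<TAB>newick`` per line
    (plain one-newick-per-line files get ids ``gene0000``, ``gene0001``...).
    """
    ns = taxon_namespace or tr.new_taxon_namespace()
    out = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            if "\t" in line:
                gid, nwk = line.split("\t", 1)
            else:
                gid, nwk = f"gene{i:04d}", line
            out[gid] = tr.read_newick(nwk, ns)
    return out


def gene_trees_for(
    alignments,
    bootstrap_B: int = 0,
    seed: int = 0,
    taxon_namespace=None,
):
    """Gene trees over a shared taxon namespace (one per alignment)."""
    from .util import stage_rng

    ns = taxon_namespace or tr.new_taxon_namespace()
    out = []
    for aln in alignments:
        rng = stage_rng(seed, "gene_tree", aln.gene_id) if bootstrap_B else None
        out.append(gene_tree(aln, bootstrap_B, rng, taxon_namespace=ns))
    return out
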