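"""ILS-vs-introgression discrimination from internal branch lengths.

For a species triplet plus outgroup, each gene tree is pruned to four tips
and contributes (i) which pair of the triplet is monophyletic and (ii) the
length of the internal branch subtending that pair.  Under pure incomplete
lineage sorting the discordant internal branches are exponentially
distributed near zero; introgression (or any non-ILS history) adds a
component shifted away from zero.  Each topology's branch lengths are fit
with

* M1: a single exponential, rate lambda (MLE = 1/mean), and
* M2: a two-component mixture
  ``(1-pi2) * lam * exp(-lam t)  +  pi2 * lam * exp(-lam (t - delta)) * 1[t >= delta]``
  with a shared rate (k = 3 free parameters), fit by EM with a
  grid-then-refine schedule for the shift delta (the likelihood is not
  smooth in delta, so delta is profiled over empirical quantiles and the
  EM handles (pi2, lambda) at fixed delta).

Model choice is by BIC with a conventional threshold: the topology is
called non-ILS when ``BIC1 - BIC2 > threshold`` (default 10).  Branch
lengths are used as-is in substitutions/site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

log = logging.getLogger(__name__)

LAMBDA_CAP = 1e9
MIN_FIT_N = 10


@dataclass
class TripletFit:
    triplet: tuple
    outgroup: str
    topology: tuple  # the monophyletic pair
    n: int
    lambda1: float
    logL1: float
    pi2: float
    lambda2: float
    delta: float
    logL2: float
    BIC1: float
    BIC2: float
    call: str  # "ILS-only" | "non-ILS"
    reliable: bool = True


# ---------------------------------------------------------------------------
# branch-length extraction
# ---------------------------------------------------------------------------

def triplet_branch_lengths(gene_trees, triplet, outgroup: str):
    """Per-topology internal branch lengths for one triplet.

    ``triplet`` is three tip labels, ``outgroup`` a fourth.  Each gene tree
    containing all four tips is pruned, rooted on the outgroup, and the
    length of the branch subtending the monophyletic pair recorded.
    Returns ({pair -> np.ndarray of lengths}, n_skipped).
    """
    triplet = tuple(triplet)
    if outgroup in triplet:
        raise ValueError("outgroup cannot be part of the triplet")
    wanted = set(triplet) | {outgroup}
    out: dict = {tuple(sorted(p)): [] for p in
                 [(triplet[0], triplet[1]), (triplet[0], triplet[2]),
                  (triplet[1], triplet[2])]}
    skipped = 0
    for tree in gene_trees:
        tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if not wanted <= tips:
            skipped += 1
            continue
        sub = tree.extract_tree_with_taxa_labels(
            wanted, suppress_unifurcations=True
        )
        og = sub.find_node_with_taxon_label(outgroup)
        sub.reroot_at_edge(og.edge, update_bipartitions=False)
        sub.suppress_unifurcations()
        pair_node = None
        for nd in sub.preorder_node_iter():
            if nd.is_leaf() or nd.parent_node is None:
                continue
            tipset = {lf.taxon.label for lf in nd.leaf_iter()}
            if len(tipset) == 2 and outgroup not in tipset:
                pair_node = nd
                break
        if pair_node is None:  # polytomy after pruning
            skipped += 1
            continue
        pair = tuple(sorted(lf.taxon.label for lf in pair_node.leaf_iter()))
        out[pair].append(pair_node.edge.length or 0.0)
    return {p: np.asarray(v, dtype=float) for p, v in out.items()}, skipped


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def fit_exponential(lengths) -> tuple:
    """ML single-exponential fit: (lambda_hat, logL)."""
    t = np.asarray(lengths, dtype=float)
    if t.size == 0:
        raise ValueError("no branch lengths to fit")
    if (t < 0).any():
        raise ValueError("negative branch length")
    mean = t.mean()
    if mean <= 0:
        log.warning("fit_exponential: all-zero lengths, rate capped")
        lam = LAMBDA_CAP
    else:
        lam = 1.0 / mean
    logL = t.size * np.log(lam) - lam * t.sum()
    return float(lam), float(logL)


def _mixture_loglik(t, pi2, lam, delta):
    f1 = (1.0 - pi2) * lam * np.exp(-lam * t)
    f2 = np.where(t >= delta, pi2 * lam * np.exp(-lam * (t - delta)), 0.0)
    return np.log(np.maximum(f1 + f2, 1e-300)).sum(), f1, f2

def _em_at_delta(t, delta, pi0, lam0, tol, max_iter):
    """EM over (pi2, lambda) at fixed delta; logL is non-decreasing."""
    pi2, lam = pi0, lam0
    last = -np.inf
    for it in range(max_iter):
        ll, f1, f2 = _mixture_loglik(t, pi2, lam, delta)
        if ll < last - 1e-8:
            raise AssertionError("EM log-likelihood decreased")
        if ll - last < tol:
            last = ll
            break
        last = ll
        tot = np.maximum(f1 + f2, 1e-300)
        r2 = f2 / tot
        pi2 = float(np.clip(r2.mean(), 0.0, 1.0))
        denom = (1.0 - r2) @ t + r2 @ np.maximum(t - delta, 0.0)
        lam = t.size / max(denom, 1e-12)
        lam = min(lam, LAMBDA_CAP)
    return pi2, lam, last


def fit_mixture_em(
    lengths,
    n_starts: int = 4,
    tol: float = 1e-8,
    max_iter: int = 500,
    rng: np.random.Generator | None = None,
    n_delta_grid: int = 24,
):
    """Shifted-exponential mixture fit: (pi2, lambda, delta, logL).

    delta is profiled over empirical quantiles then refined locally;
    (pi2, lambda) are fit by EM at each delta from ``n_starts`` seeded
    initializations (pi2 = 0 is an EM fixed point, hence the multi-start).
    """
    t = np.asarray(lengths, dtype=float)
    if t.size == 0:
        raise ValueError("no branch lengths to fit")
    rng = rng or np.random.default_rng(0)
    reliable = t.size >= MIN_FIT_N
    lam_mom = 1.0 / max(t.mean(), 1e-12)
    qs = np.unique(np.quantile(t, np.linspace(0.0, 0.98, n_delta_grid)))
    best = (-np.inf, 0.0, lam_mom, 0.0)

    def scan(deltas):
        nonlocal best
        for delta in deltas:
            for s in range(n_starts):
                pi0 = rng.uniform(0.05, 0.95)
                lam0 = lam_mom * rng.uniform(0.5, 2.0)
                pi2, lam, ll = _em_at_delta(t, delta, pi0, lam0, tol, max_iter)
                if ll > best[0]:
                    best = (ll, pi2, lam, float(delta))

    scan(qs)
    # local refinement around the best delta
    _, _, _, d0 = best
    span = (t.max() - t.min()) or 1.0
    fine = np.clip(d0 + span * np.linspace(-0.05, 0.05, 11), 0.0, t.max())
    scan(np.unique(fine))
    ll, pi2, lam, delta = best
    if not reliable:
        log.warning("fit_mixture_em: n = %d < %d, fit marked unreliable",
                    t.size, MIN_FIT_N)
    return float(pi2), float(lam), float(delta), float(ll), reliable


def compare_models(logL1: float, logL2: float, n: int, threshold: float = 10.0):
    """BIC comparison: k=1 (single exponential) vs k=3 (mixture).

    Returns (BIC1, BIC2, delta_bic, call); call = "non-ILS" iff
    BIC1 - BIC2 > threshold (strict).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    bic1 = 1 * np.log(n) - 2.0 * logL1
    bic2 = 3 * np.log(n) - 2.0 * logL2
    delta = bic1 - bic2
    return float(bic1), float(bic2), float(delta), (
        "non-ILS" if delta > threshold else "ILS-only"
    )


def fit_triplet(
    gene_trees,
    triplet,
    outgroup: str,
    threshold: float = 10.0,
    rng: np.random.Generator | None = None,
):
    """All-topology TripletFits for one triplet (skips empty topologies)."""
    lengths, skipped = triplet_branch_lengths(gene_trees, triplet, outgroup)
    fits = []
    for pair in sorted(lengths):
        t = lengths[pair]
        if t.size == 0:
            continue
        lam1, logL1 = fit_exponential(t)
        pi2, lam2, delta, logL2, reliable = fit_mixture_em(t, rng=rng)
        if logL2 < logL1 - 1e-6:
            # the mixture nests the exponential; numerical guard
            pi2, lam2, delta, logL2 = 0.0, lam1, 0.0, logL1
        bic1, bic2, _, call = compare_models(logL1, logL2, t.size, threshold)
        fits.append(
            TripletFit(
                tuple(triplet), outgroup, pair, int(t.size),
                lam1, logL1, pi2, lam2, delta, logL2, bic1, bic2, call,
                reliable,
            )
        )
    return fits, skipped
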