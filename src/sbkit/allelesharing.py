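"""Allele-sharing ("BBBAA-BBABA") test for the direction of Sb origin.

If Sb originated inside the donor species, Sb haplotypes should share more
alleles with the donor's SB background than with the recipient's SB
background.  Per site, each group is summarized by its strict-majority
consensus allele; a site is informative when the Sb pool's consensus
matches exactly one of the two SB consensuses.  Polarization (default on)
keeps only sites where the shared allele is derived relative to the
outgroup consensus.  The imbalance between the two informative counts is
assessed with a two-sided exact binomial test against 0.5.

The classic ABBA-BABA D statistic is deliberately not implemented (the
supergene tree's topology makes it inappropriate); a gene-level jackknife
is available as a robustness output instead of a block jackknife.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotypes import MISSING, GenotypeTable

log = logging.getLogger(__name__)


@dataclass
class AlleleSharingResult:
    n_donor_shared: int
    n_recipient_shared: int
    p_value: float
    groups: dict = field(default_factory=dict)
    n_per_group: int | None = None
    seed: int | None = None
    polarized: bool = True

    @property
    def n_informative(self) -> int:
        return self.n_donor_shared + self.n_recipient_shared


def equalize_groups(
    table: GenotypeTable,
    group_map: dict,
    n_per_group: int,
    rng: np.random.Generator,
) -> GenotypeTable:
    """Seeded subsampling to exactly ``n_per_group`` samples per group.

    ``group_map`` maps group name -> list of sample names; groups must be
    disjoint.  Samples outside any group are dropped.
    """
    seen = set()
    for g, members in group_map.items():
        overlap = seen & set(members)
        if overlap:
            raise ValueError(f"samples {sorted(overlap)} appear in several groups")
        seen |= set(members)
    chosen = []
    for g in sorted(group_map):
        members = [s for s in group_map[g] if s in table.samples]
        if len(members) < n_per_group:
            raise ValueError(
                f"group {g!r} has {len(members)} samples, needs {n_per_group}"
            )
        idx = rng.choice(len(members), size=n_per_group, replace=False)
        chosen.extend(members[i] for i in sorted(idx))
    return table.take_samples(chosen)


def _consensus(alleles: np.ndarray) -> np.ndarray:
    """Strict-majority consensus allele per site; -1 where tied/all-missing.

    ``alleles`` is (n_sites, n_group_samples) with MISSING = -1.
    """
    n_sites = alleles.shape[0]
    out = np.full(n_sites, -1, dtype=np.int16)
    max_allele = int(alleles.max(initial=0))
    counts = np.zeros((n_sites, max_allele + 1), dtype=np.int32)
    for a in range(max_allele + 1):
        counts[:, a] = (alleles == a).sum(axis=1)
    top = counts.max(axis=1)
    n_top = (counts == top[:, None]).sum(axis=1)
    ok = (top > 0) & (n_top == 1)
    out[ok] = counts[ok].argmax(axis=1)
    return out


def shared_allele_counts(
    table: GenotypeTable,
    sb_pool,
    donor_SB,
    recipient_SB,
    outgroup,
    polarize: bool = True,
):
    """Counts of sites where the Sb pool's consensus sides with the donor
    SB group vs the recipient SB group.

    Groups are lists of sample names and must be disjoint.  Sites where a
    needed consensus is undefined (tie or all-missing) are skipped; with
    ``polarize`` only derived sharing (consensus differing from the
    outgroup consensus) is counted.
    """
    groups = {
        "sb_pool": list(sb_pool),
        "donor_SB": list(donor_SB),
        "recipient_SB": list(recipient_SB),
        "outgroup": list(outgroup),
    }
    all_names = [n for g in groups.values() for n in g]
    if len(set(all_names)) != len(all_names):
        raise ValueError("groups overlap")
    idx = {
        g: np.array([table.samples.index(s) for s in names])
        for g, names in groups.items()
    }
    cons = {g: _consensus(table.alleles[:, idx[g]]) for g in groups}
    sbc, dc, rc, oc = (
        cons["sb_pool"], cons["donor_SB"], cons["recipient_SB"], cons["outgroup"]
    )
    defined = (sbc >= 0) & (dc >= 0) & (rc >= 0)
    donor_like = defined & (sbc == dc) & (dc != rc)
    recip_like = defined & (sbc == rc) & (dc != rc)
    if polarize:
        donor_like &= (oc >= 0) & (sbc != oc)
        recip_like &= (oc >= 0) & (sbc != oc)
    n_skipped = int((~defined).sum())
    if n_skipped:
        log.info("shared_allele_counts: %d sites without defined consensus", n_skipped)
    return int(donor_like.sum()), int(recip_like.sum())


def binomial_sharing_test(n_donor: int, n_recipient: int) -> float:
    """Two-sided exact binomial p-value for the sharing imbalance at p=0.5
    (sum of probabilities of outcomes no more likely than the observed)."""
    n = n_donor + n_recipient
    if n < 1:
        raise ValueError("no informative sites")
    return float(stats.binomtest(n_donor, n, 0.5, alternative="two-sided").pvalue)


def supergene_sites(table: GenotypeTable, gene_layouts) -> GenotypeTable:
    """Restrict a table to sites inside supergene genes: the sharing test
    interrogates the supergene's origin, and outside the non-recombining
    region a recipient-species Sb male is genomically recipient-like."""
    chrom = table.sites["chrom"].values
    pos = table.sites["pos"].values
    keep = np.zeros(table.n_sites, dtype=bool)
    for lay in gene_layouts:
        if getattr(lay, "in_supergene", False):
            keep |= (chrom == lay.chrom) & (pos > lay.start) & (pos <= lay.end)
    return table.take_sites(np.flatnonzero(keep))


def allele_sharing_test(
    table: GenotypeTable,
    labels: dict,
    donor_species,
    recipient_species: str,
    outgroup_species: str,
    n_per_group: int | None = None,
    polarize: bool = True,
    seed: int = 0,
) -> AlleleSharingResult:
    """Equalize per (lineage x variant) group, count, test.

    ``labels`` maps sample -> (species, variant); ``donor_species`` may be a
    list of nominal species forming one donor lineage.  The Sb pool is the
    union of the donor's and recipient's Sb samples; equalization draws
    ``n_per_group`` samples from each of donor-SB, donor-Sb, recipient-SB
    and recipient-Sb (the outgroup only polarizes and is exempt).
    """
    if isinstance(donor_species, str):
        donor_species = [donor_species]
    donor_species = list(donor_species)

    def members(species, variant):
        return [
            s for s in table.samples
            if labels[s][0] in species and labels[s][1] == variant
        ]

    groups = {
        "donor_SB": members(donor_species, "SB"),
        "donor_Sb": members(donor_species, "Sb"),
        "recipient_SB": members([recipient_species], "SB"),
        "recipient_Sb": members([recipient_species], "Sb"),
    }
    outgroup = members([outgroup_species], "SB") + members([outgroup_species], "Sb")
    rng = np.random.default_rng(seed)
    t = table
    if n_per_group is not None:
        t = equalize_groups(table, groups, n_per_group, rng)
        kept = set(t.samples)
        t = table.take_samples(
            [s for s in table.samples if s in kept or s in set(outgroup)]
        )
        groups = {g: [s for s in t.samples if s in set(groups[g])] for g in groups}
    sb_pool = groups["donor_Sb"] + groups["recipient_Sb"]
    nd, nr = shared_allele_counts(
        t, sb_pool, groups["donor_SB"], groups["recipient_SB"], outgroup,
        polarize=polarize,
    )
    p = binomial_sharing_test(nd, nr) if (nd + nr) else 1.0
    return AlleleSharingResult(
        nd, nr, p,
        groups={**{g: sorted(v) for g, v in groups.items()},
                "outgroup": sorted(outgroup)},
        n_per_group=n_per_group, seed=seed, polarized=polarize,
    )


def gene_jackknife_ratios(
    table: GenotypeTable, gene_layouts, group_map: dict, polarize: bool = True
):
    """Leave-one-gene-out donor-share fractions (robustness output)."""
    fracs = []
    chrom = table.sites["chrom"].values
    pos = table.sites["pos"].values
    for lay in gene_layouts:
        outside = ~((chrom == lay.chrom) & (pos > lay.start) & (pos <= lay.end))
        sub = table.take_sites(np.flatnonzero(outside))
        nd, nr = shared_allele_counts(
            sub, group_map["sb_pool"], group_map["donor_SB"],
            group_map["recipient_SB"], group_map["outgroup"], polarize=polarize,
        )
        if nd + nr:
            fracs.append(nd / (nd + nr))
    return np.array(fracs)
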