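"""Post-genotyping filter cascade for haploid male cohorts.

The cascade mirrors the order in which the genotypes were cleaned in the
study design it reproduces:

1. :func:`high_coverage_mask` -- exclude collapsed-repeat-like regions whose
   mean depth exceeds median + 3 SD of single-copy gene coverage.
2. :func:`site_filters` -- SNPs only, quality >= 30, both strands, outside
   masks.
3. :func:`mask_ambiguous_calls` -- per-call missingness for excess depth or
   intermediate allelic balance (impossible in a true haploid).
4. :func:`haploidize_pools` -- random-allele consensus for pooled samples.
5. :func:`flag_bad_samples` -- drop high-missingness samples, flag likely
   diploids by heterozygous-call excess.
6. :func:`site_call_rate_filter` -- retain sites genotyped in > 75% of the
   remaining samples.

All thresholds live in :class:`FilterParams`.  Filters only remove or mask;
no call value is altered except by the pool haploidization and by MISSING
assignment, and the full cascade is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable

log = logging.getLogger(__name__)


@dataclass
class FilterParams:
    qual_min: float = 30.0
    ab_low: float = 0.25
    ab_high: float = 0.75
    cov_sd_mult: float = 3.0
    site_call_rate_min: float = 0.75
    sample_missing_max: float = 0.25
    het_excess_mult: float = 5.0
    het_floor: float = 0.10  # absolute fallback when the cohort median is 0
    mask_merge_gap: int = 10  # bp; merge near-adjacent high-coverage runs

    def __post_init__(self):
        if not 0 <= self.ab_low < self.ab_high <= 1:
            raise ValueError("require 0 <= ab_low < ab_high <= 1")


@dataclass
class CoverageMask:
    intervals: pd.DataFrame  # chrom, start, end (0-based half-open)
    threshold_used: float

    def __post_init__(self):
        iv = self.intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        for _, grp in iv.groupby("chrom"):
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValueError("mask intervals overlap")
        self.intervals = iv

    def covers(self, chrom: np.ndarray, pos1: np.ndarray) -> np.ndarray:
        """Membership of 1-based positions in the 0-based half-open mask."""
        hit = np.zeros(len(pos1), dtype=bool)
        for _, row in self.intervals.iterrows():
            hit |= (chrom == row["chrom"]) & (pos1 > row["start"]) & (pos1 <= row["end"])
        return hit

    def total_bases(self) -> int:
        return int((self.intervals["end"] - self.intervals["start"]).sum())


def _runs_to_intervals(mask: np.ndarray, merge_gap: int):
    """Maximal True runs as (start, end) 0-based half-open, merging gaps
    shorter than ``merge_gap``."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > merge_gap)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]] + 1
    return list(zip(starts.tolist(), ends.tolist()))


def high_coverage_mask(
    depth_profile: dict,
    single_copy_regions,
    params: FilterParams | None = None,
) -> CoverageMask:
    """Mask genomic runs whose mean depth exceeds median + k*SD of
    single-copy coverage pooled across samples.

    Parameters
    ----------
    depth_profile:
        chrom -> per-position mean depth across samples (position 0-based).
    single_copy_regions:
        iterable of (chrom, start, end), 0-based half-open; the threshold is
        computed from depth restricted to these intervals.
    """
    params = params or FilterParams()
    if not depth_profile or all(len(v) == 0 for v in depth_profile.values()):
        raise ValueError("empty depth profile")
    sc = [
        np.asarray(depth_profile[c][s:e], dtype=float)
        for c, s, e in single_copy_regions
        if c in depth_profile
    ]
    if not sc or sum(len(x) for x in sc) == 0:
        raise ValueError("single-copy regions not covered by the depth profile")
    pooled = np.concatenate(sc)
    threshold = float(np.median(pooled) + params.cov_sd_mult * pooled.std())
    rows = []
    for chrom in sorted(depth_profile):
        prof = np.asarray(depth_profile[chrom], dtype=float)
        for s, e in _runs_to_intervals(prof > threshold, params.mask_merge_gap):
            rows.append({"chrom": chrom, "start": s, "end": e})
    iv = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return CoverageMask(iv, threshold)


def site_filters(
    table: GenotypeTable,
    params: FilterParams | None = None,
    masks: list | None = None,
) -> GenotypeTable:
    """SNP-only, quality and strand site filters plus mask exclusion.

    MNPs are assumed pre-decomposed; the VCF reader already drops residual
    non-SNP records, so here the check is on allele strings.  ``masks`` is a
    list of :class:`CoverageMask` (coverage mask, repeat intervals, ...).
    """
    params = params or FilterParams()
    s = table.sites
    is_snp = (s["ref"].str.len() == 1) & s["alt"].str.split(",").apply(
        lambda a: all(len(x) == 1 for x in a)
    )
    keep = (
        is_snp.values
        & (s["qual"].values >= params.qual_min)
        & s["has_fwd"].values
        & s["has_rev"].values
    )
    chrom = s["chrom"].values
    pos = s["pos"].values
    for m in masks or []:
        keep &= ~m.covers(chrom, pos)
    return table.take_sites(np.flatnonzero(keep))


def per_sample_coverage_caps(
    table: GenotypeTable,
    single_copy_regions,
    params: FilterParams | None = None,
) -> dict:
    """Per-sample depth cap: median + k*SD of that sample's call depth at
    sites inside single-copy regions."""
    params = params or FilterParams()
    chrom = table.sites["chrom"].values
    pos = table.sites["pos"].values
    inside = np.zeros(table.n_sites, dtype=bool)
    for c, s, e in single_copy_regions:
        inside |= (chrom == c) & (pos > s) & (pos <= e)
    caps = {}
    for i, name in enumerate(table.samples):
        d = table.depth[inside, i]
        d = d[d > 0]
        if d.size == 0:
            caps[name] = np.inf
            continue
        caps[name] = float(np.median(d) + params.cov_sd_mult * d.std())
    return caps


def mask_ambiguous_calls(
    table: GenotypeTable,
    params: FilterParams | None = None,
    per_sample_cov_caps: dict | None = None,
) -> GenotypeTable:
    """Set to MISSING any call with excess depth or allelic balance inside
    [ab_low, ab_high] (inclusive at both ends; such balance is not expected
    in a haploid).  Calls lacking AB are treated as 0/1 per their called
    allele and left alone (count logged)."""
    params = params or FilterParams()
    out = table.copy()
    ab = out.ab
    het_like = np.isfinite(ab) & (ab >= params.ab_low) & (ab <= params.ab_high)
    over_cap = np.zeros_like(het_like)
    if per_sample_cov_caps:
        caps = np.array(
            [per_sample_cov_caps.get(s, np.inf) for s in out.samples], dtype=float
        )
        over_cap = out.depth > caps[None, :]
    no_ab = ~np.isfinite(ab) & (out.alleles != MISSING)
    if no_ab.any():
        log.info("mask_ambiguous_calls: %d calls without AB left as-is", no_ab.sum())
    out.alleles[(het_like | over_cap)] = MISSING
    return out


def haploidize_pools(
    table: GenotypeTable,
    pool_sample_ids,
    rng: np.random.Generator,
    pool_flags: dict | None = None,
    params: FilterParams | None = None,
) -> GenotypeTable:
    """Random-allele haploid consensus for pooled (multi-individual) samples.

    A pool call is heterozygous-like when its allelic balance is strictly
    between 0 and 1; the call is replaced by REF or ALT with probability
    proportional to nothing -- a fair coin -- as in a random-allele
    consensus.  Seeded and reproducible.
    """
    if pool_flags is not None:
        bad = [s for s in pool_sample_ids if not pool_flags.get(s, False)]
        if bad:
            raise ValueError(f"samples {bad} are not flagged as pools")
    out = table.copy()
    for name in pool_sample_ids:
        if name not in out.samples:
            raise ValueError(f"pool sample {name!r} not in table")
        i = out.samples.index(name)
        ab = out.ab[:, i]
        het = np.isfinite(ab) & (ab > 0) & (ab < 1) & (out.alleles[:, i] != MISSING)
        n_het = int(het.sum())
        if n_het:
            # alt allele index taken from the recorded call when it is alt,
            # else 1 (biallelic assumption for pools)
            alt_idx = np.where(out.alleles[het, i] > 0, out.alleles[het, i], 1)
            pick_alt = rng.random(n_het) < 0.5
            out.alleles[np.flatnonzero(het), i] = np.where(pick_alt, alt_idx, 0)
    return out


def flag_bad_samples(
    table: GenotypeTable,
    params: FilterParams | None = None,
    het_fractions: dict | None = None,
):
    """Drop samples with > ``sample_missing_max`` missing calls; flag as
    likely diploid those whose heterozygous-like call fraction exceeds
    ``het_excess_mult`` x the cohort median (both removed from the table).

    ``het_fractions`` should be the PRE-masking heterozygous-like fractions;
    when omitted they are recomputed from the stored allelic balances, which
    survive call masking.

    Returns (table, dropped, flagged_diploid).
    """
    params = params or FilterParams()
    miss = table.missing_fraction()
    if het_fractions is None:
        het_fractions = heterozygous_fractions(table, params)
    het = np.array([het_fractions[s] for s in table.samples])
    dropped = [s for s, m in zip(table.samples, miss) if m > params.sample_missing_max]
    if table.n_samples < 3:
        log.warning("cohort of < 3 samples: diploid median rule disabled")
        flagged = []
    else:
        med = float(np.median(het))
        cut = max(params.het_excess_mult * med, params.het_floor if med == 0 else 0.0)
        flagged = [
            s
            for s, h in zip(table.samples, het)
            if h > cut and s not in dropped
        ]
    keep = [s for s in table.samples if s not in dropped and s not in flagged]
    return table.take_samples(keep), dropped, flagged


def heterozygous_fractions(table: GenotypeTable, params: FilterParams | None = None) -> dict:
    """Per-sample fraction of sites whose allelic balance falls in the
    ambiguous band (among sites with any reads)."""
    params = params or FilterParams()
    ab = table.ab
    het_like = np.isfinite(ab) & (ab >= params.ab_low) & (ab <= params.ab_high)
    covered = table.depth > 0
    with np.errstate(invalid="ignore"):
        frac = het_like.sum(axis=0) / np.maximum(covered.sum(axis=0), 1)
    return dict(zip(table.samples, frac))


def site_call_rate_filter(
    table: GenotypeTable, params: FilterParams | None = None
) -> GenotypeTable:
    """Retain sites genotyped in strictly more than ``site_call_rate_min``
    of the samples."""
    params = params or FilterParams()
    keep = table.call_rate() > params.site_call_rate_min
    return table.take_sites(np.flatnonzero(keep))


@dataclass
class CascadeResult:
    table: GenotypeTable
    coverage_mask: CoverageMask
    dropped_samples: list
    flagged_diploid: list
    counts: dict = field(default_factory=dict)


def apply_filter_cascade(
    table: GenotypeTable,
    depth_profile: dict,
    single_copy_regions,
    params: FilterParams | None = None,
    repeat_masks: list | None = None,
    pool_sample_ids=(),
    rng: np.random.Generator | None = None,
) -> CascadeResult:
    """Run the full cascade in its fixed order and keep stage bookkeeping."""
    params = params or FilterParams()
    counts = {"input_sites": table.n_sites, "input_samples": table.n_samples}
    cov_mask = high_coverage_mask(depth_profile, single_copy_regions, params)
    counts["masked_bases"] = cov_mask.total_bases()
    t = site_filters(table, params, [cov_mask] + list(repeat_masks or []))
    counts["sites_after_site_filters"] = t.n_sites
    het_before = heterozygous_fractions(t, params)
    caps = per_sample_coverage_caps(t, single_copy_regions, params)
    t = mask_ambiguous_calls(t, params, caps)
    counts["calls_masked"] = int((t.alleles == MISSING).sum())
    if pool_sample_ids:
        t = haploidize_pools(t, pool_sample_ids, rng or np.random.default_rng(0))
    t, dropped, flagged = flag_bad_samples(t, params, het_before)
    counts["dropped_samples"] = len(dropped)
    counts["flagged_diploid"] = len(flagged)
    t = site_call_rate_filter(t, params)
    counts["sites_final"] = t.n_sites
    counts["samples_final"] = t.n_samples
    return CascadeResult(t, cov_mask, dropped, flagged, counts)
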