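"""The haploid genotype matrix: parsed from VCF, substrate of the filters.

A :class:`GenotypeTable` holds one allele index per sample x site (-1 =
missing) plus the per-call read depth and allelic balance (alt reads /
total reads) and per-site quality and strand-support flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeTable:
    sites: pd.DataFrame  # chrom, pos (1-based), ref, alt, qual, has_fwd, has_rev
    samples: list
    alleles: np.ndarray  # (n_sites, n_samples) int16, MISSING = -1
    depth: np.ndarray  # (n_sites, n_samples) int32
    ab: np.ndarray  # (n_sites, n_samples) float32, NaN where no reads
    skipped: dict = field(default_factory=dict)

    def __post_init__(self):
        ns, nm = self.alleles.shape
        if len(self.sites) != ns or len(self.samples) != nm:
            raise ValueError("shape mismatch between sites/samples and matrices")
        pos = self.sites.groupby("chrom", sort=False)["pos"]
        if not pos.apply(lambda s: s.is_monotonic_increasing).all():
            raise ValueError("positions must increase within each chromosome")

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[1]

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            self.sites.copy(), list(self.samples), self.alleles.copy(),
            self.depth.copy(), self.ab.copy(), dict(self.skipped),
        )

    def take_sites(self, index: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            self.sites.iloc[index].reset_index(drop=True), list(self.samples),
            self.alleles[index], self.depth[index], self.ab[index], dict(self.skipped),
        )

    def take_samples(self, names) -> "GenotypeTable":
        idx = [self.samples.index(s) for s in names]
        return GenotypeTable(
            self.sites.reset_index(drop=True), list(names), self.alleles[:, idx],
            self.depth[:, idx], self.ab[:, idx], dict(self.skipped),
        )

    def missing_fraction(self) -> np.ndarray:
        """Per-sample fraction of sites with no call."""
        return (self.alleles == MISSING).mean(axis=0)

    def call_rate(self) -> np.ndarray:
        """Per-site fraction of samples with a call."""
        return (self.alleles != MISSING).mean(axis=1)


def read_vcf(path) -> GenotypeTable:
    """Parse a VCF 4.2 into a :class:`GenotypeTable`.

    Only SNP records are loaded.  Indels/MNPs are assumed pre-decomposed
    upstream; residual non-SNP records are skipped and counted, as are
    records with symbolic alleles.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows, alleles, depths, abs_ = [], [], [], []
    skipped = {"non_snp": 0, "symbolic": 0}
    for rec in vf:
        alts = rec.alts or ()
        if any(a is None or a.startswith("<") or a == "*" for a in alts):
            skipped["symbolic"] += 1
            continue
        if len(rec.ref) != 1 or any(len(a) != 1 for a in alts):
            skipped["non_snp"] += 1
            continue
        info = rec.info
        strand_keys = [info.get(k) for k in ("SRF", "SRR", "SAF", "SAR")]
        if all(v is None for v in strand_keys):
            # no strand annotation at all: do not fail the strand filter
            has_fwd = has_rev = True
        else:
            srf, srr, saf, sar = (v or 0 for v in strand_keys)
            has_fwd = (srf + saf) > 0
            has_rev = (srr + sar) > 0
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": ",".join(alts),
                "qual": rec.qual if rec.qual is not None else np.nan,
                "has_fwd": has_fwd,
                "has_rev": has_rev,
            }
        )
        arow = np.full(len(samples), MISSING, dtype=np.int16)
        drow = np.zeros(len(samples), dtype=np.int32)
        brow = np.full(len(samples), np.nan, dtype=np.float32)
        for i, name in enumerate(samples):
            call = rec.samples[name]
            gt = call.get("GT")
            dp = call.get("DP") or 0
            ad = call.get("AD")
            drow[i] = dp
            if ad is not None and dp > 0 and not any(a is None for a in ad):
                tot = sum(ad)
                if tot > 0:
                    brow[i] = sum(ad[1:]) / tot
            if gt is None or len(gt) == 0 or gt[0] is None:
                continue
            arow[i] = gt[0]
        alleles.append(arow)
        depths.append(drow)
        abs_.append(brow)
    if skipped["non_snp"] or skipped["symbolic"]:
        log.info("read_vcf skipped records: %s", skipped)
    n = len(rows)
    return GenotypeTable(
        pd.DataFrame(rows) if n else pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "qual", "has_fwd", "has_rev"]
        ),
        samples,
        np.array(alleles, dtype=np.int16).reshape(n, len(samples)),
        np.array(depths, dtype=np.int32).reshape(n, len(samples)),
        np.array(abs_, dtype=np.float32).reshape(n, len(samples)),
        skipped,
    )


def table_from_simulation(dataset, clean: bool = True) -> GenotypeTable:
    """Build a GenotypeTable directly from simulated site records.

    The artifact-free path: true alleles for the declared (haploid)
    samples, no depth/quality noise and no contaminants.  Used where an
    analysis consumes genotypes rather than the read-model artifacts
    (depths are set to a nominal constant, allelic balance to 0/1).
    """
    labels = dataset.alignments[0].labels
    n_vis = len(labels)
    ref_row = n_vis  # the hidden reference haplotype follows the samples
    rows, allele_rows = [], []
    for lay, recs in zip(dataset.gene_layouts, dataset.site_records):
        for rec in recs:
            ref_is_derived = bool(rec.carriers[ref_row])
            alleles = (rec.carriers[:n_vis] != ref_is_derived).astype(np.int16)
            if not alleles.any():  # private to the reference haplotype
                continue
            ref_code = rec.derived if ref_is_derived else rec.ancestral
            alt_code = rec.ancestral if ref_is_derived else rec.derived
            rows.append(
                {
                    "chrom": lay.chrom,
                    "pos": lay.start + rec.position,
                    "ref": "ACGTN"[ref_code],
                    "alt": "ACGTN"[alt_code],
                    "qual": 999.0,
                    "has_fwd": True,
                    "has_rev": True,
                }
            )
            allele_rows.append(alleles)
    n = len(rows)
    alleles = np.array(allele_rows, dtype=np.int16).reshape(n, len(labels))
    sites = pd.DataFrame(rows).sort_values(["chrom", "pos"], kind="stable")
    order = sites.index.to_numpy()
    sites = sites.reset_index(drop=True)
    alleles = alleles[order]
    return GenotypeTable(
        sites,
        list(labels),
        alleles,
        np.full((n, len(labels)), 10, dtype=np.int32),
        alleles.astype(np.float32),
    )
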