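"""End-to-end pipeline: simulate/load -> filter -> gene trees -> summary
trees -> scenario call -> allele sharing -> topology weighting -> branch-
length mixture.  One config, one seed, one consolidated JSON report.

Randomness: a single global seed with per-stage substreams derived from
stage names, so adding a stage never shifts another stage's draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np

from . import allelesharing as ash
from . import blmixture as blm
from . import filtering as flt
from . import genetrees as gt
from . import scenario as sc
from . import simdata as sd
from . import speciestree as st
from . import topoweights as tw
from . import trees as tr
from .genotypes import GenotypeTable, read_vcf
from .seqs import encode
from .util import stage_rng

log = logging.getLogger(__name__)


@dataclass
class RealInputs:
    vcf: str
    reference_fasta: str
    gff3: str
    metadata_tsv: str
    depth_tsv: str | None = None
    gene_trees_newick: str | None = None  # optional precomputed gene trees


@dataclass
class PipelineConfig:
    sim: sd.SimConfig | None = None
    real: RealInputs | None = None
    outdir: str | None = None
    seed: int = 0
    filter_params: flt.FilterParams = field(default_factory=flt.FilterParams)
    outgroup_species: str = "gem"
    min_avg_diffs: float = 10.0
    collapse_min_len: float = 0.05
    window_size: int = 4
    equalize_n: int | None = 4
    polarize: bool = True
    bic_threshold: float = 10.0
    tree_mode: str = "heuristic"
    bootstrap_B: int = 0

    def __post_init__(self):
        if (self.sim is None) == (self.real is None):
            raise ValueError("exactly one of sim / real inputs must be given")


def _load_real(real: RealInputs):
    import pandas as pd
    import pysam

    table = read_vcf(real.vcf)
    metadata = pd.read_csv(real.metadata_tsv, sep="\t")
    fa = pysam.FastaFile(real.reference_fasta)
    ref_seqs = {c: encode(fa.fetch(c)) for c in fa.references}
    layouts = []
    with open(real.gff3) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            layouts.append(
                sd.GeneLayout(
                    attrs.get("ID", f"{f[0]}:{f[3]}"), f[0], int(f[3]) - 1,
                    int(f[4]), attrs.get("in_supergene", "0") == "1",
                )
            )
    depth_profile = {}
    if real.depth_tsv:
        dp = pd.read_csv(real.depth_tsv, sep="\t")
        for chrom, grp in dp.groupby("chrom"):
            arr = np.zeros(int(grp["pos"].max()))
            arr[grp["pos"].values - 1] = grp["mean_depth"].values
            depth_profile[chrom] = arr
    else:
        log.warning("no depth profile given: high-coverage masking disabled")
    return table, metadata, ref_seqs, layouts, depth_profile


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in fixed order; returns the report dict (also
    written to ``outdir/report.json`` when an outdir is set)."""
    report: dict = {"stages": {}, "seed": config.seed}
    seed = config.seed

    # ---- stage: inputs -----------------------------------------------------
    if config.sim is not None:
        ds = sd.simulate_dataset(config.sim)
        if config.outdir:
            ds.write(pathlib.Path(config.outdir) / "simulated")
            table = read_vcf(pathlib.Path(config.outdir) / "simulated" / "genotypes.vcf")
        else:
            import io, tempfile

            with tempfile.TemporaryDirectory() as td:
                p = pathlib.Path(td) / "genotypes.vcf"
                p.write_text(ds.vcf_text)
                table = read_vcf(p)
        metadata = ds.metadata
        ref_seqs = ds.ref_seqs
        layouts = ds.gene_layouts
        depth_profile = ds.depth_profile
        report["stages"]["simulate"] = {
            "scenario": ds.truth.scenario,
            "n_samples": len(metadata),
            "n_sites": ds.vcf_text.count("\n") - ds.vcf_text.count("\n##") - 1,
        }
    else:
        table, metadata, ref_seqs, layouts, depth_profile = _load_real(config.real)
        report["stages"]["load"] = {
            "n_samples": len(metadata),
            "n_sites": table.n_sites,
        }

    labels = {
        r["sample"]: (r["species"], r["variant"]) for _, r in metadata.iterrows()
    }

    # ---- stage: filtering --------------------------------------------------
    single_copy = [(l.chrom, l.start, l.end) for l in layouts]
    if depth_profile:
        cascade = flt.apply_filter_cascade(
            table, depth_profile, single_copy, config.filter_params,
            rng=stage_rng(seed, "haploidize"),
        )
    else:
        t = flt.site_filters(table, config.filter_params, [])
        caps = flt.per_sample_coverage_caps(t, single_copy, config.filter_params)
        het = flt.heterozygous_fractions(t, config.filter_params)
        t = flt.mask_ambiguous_calls(t, config.filter_params, caps)
        t, dropped, flagged = flt.flag_bad_samples(t, config.filter_params, het)
        t = flt.site_call_rate_filter(t, config.filter_params)
        cascade = flt.CascadeResult(t, flt.CoverageMask(
            __import__("pandas").DataFrame(columns=["chrom", "start", "end"]), np.inf
        ), dropped, flagged, {"sites_final": t.n_sites})
    ftable = cascade.table
    report["stages"]["filtering"] = dict(cascade.counts)
    report["stages"]["filtering"]["dropped_samples"] = cascade.dropped_samples
    report["stages"]["filtering"]["flagged_diploid"] = cascade.flagged_diploid
    n_in = table.n_samples
    assert len(cascade.dropped_samples) + len(cascade.flagged_diploid) + \
        ftable.n_samples == n_in, "sample bookkeeping leak"

    outgroup_samples = [
        s for s in ftable.samples if labels[s][0] == config.outgroup_species
    ]
    if not outgroup_samples:
        raise ValueError("no outgroup samples survive filtering")

    # ---- stage: consensus + informative genes ------------------------------
    ingroup = [
        s for s in ftable.samples
        if labels[s][0] != config.outgroup_species
    ]
    alignments, references = [], {}
    for lay in layouts:
        gene = gt.GeneModel(lay.gene_id, lay.chrom, lay.start, lay.end,
                            in_supergene=lay.in_supergene)
        ref = ref_seqs[lay.chrom][lay.start:lay.end]
        aln = gt.consensus_sequences(ref, ftable, gene)
        alignments.append(aln)
        references[lay.gene_id] = ref
    informative = set(gt.select_informative(
        alignments, references, ingroup, config.min_avg_diffs
    ))
    report["stages"]["informative_genes"] = {
        "n_total": len(alignments),
        "n_informative": len(informative),
    }
    keep = [a for a in alignments if a.gene_id in informative]
    by_gene = {a.gene_id: a for a in keep}
    sg_ids = [l.gene_id for l in layouts
              if l.in_supergene and l.gene_id in informative]
    bg_ids = [l.gene_id for l in layouts
              if not l.in_supergene and l.gene_id in informative]

    # ---- stage: gene trees -------------------------------------------------
    ns = tr.new_taxon_namespace()
    precomputed = {}
    if config.real is not None and config.real.gene_trees_newick:
        precomputed = gt.read_gene_trees(config.real.gene_trees_newick, ns)
    gene_trees = {
        gid: precomputed.get(gid)
        or gt.gene_tree(by_gene[gid], config.bootstrap_B,
                        stage_rng(seed, "genetree", gid), taxon_namespace=ns)
        for gid in bg_ids + sg_ids
    }
    report["stages"]["gene_trees"] = {
        "n_trees": len(gene_trees), "n_precomputed": len(precomputed)
    }

    # ---- stage: summary trees ----------------------------------------------
    species_tree = st.infer_species_tree(
        [gene_trees[g] for g in bg_ids], mode=config.tree_mode
    )
    supergene_tree = st.infer_species_tree(
        [gene_trees[g] for g in sg_ids], mode=config.tree_mode
    )
    species_rooted = st.root_and_collapse(
        species_tree, outgroup_samples, config.collapse_min_len
    )
    supergene_rooted = st.root_and_collapse(
        supergene_tree, outgroup_samples, config.collapse_min_len
    )
    report["trees"] = {
        "species": species_rooted.as_string(schema="newick").strip(),
        "supergene": supergene_rooted.as_string(schema="newick").strip(),
        "species_quartet_score": species_tree.quartet_score_value,
        "supergene_quartet_score": supergene_tree.quartet_score_value,
    }

    # ---- stage: scenario ---------------------------------------------------
    call = sc.classify_scenario(species_rooted, supergene_rooted, labels)
    report["scenario"] = json.loads(call.to_json())

    # ---- downstream verification stages ------------------------------------
    donor_species = list(call.donor) if call.donor else ["inv", "mac"]
    sb_samples = {s for s in ftable.samples if labels[s][1] == "Sb"}
    sb_by_species: dict = {}
    for s in sb_samples:
        sb_by_species.setdefault(labels[s][0], []).append(s)
    recips = sorted(
        (sp for sp in sb_by_species if sp not in donor_species),
        key=lambda sp: (-len(sb_by_species[sp]), sp),
    )
    recipient = recips[0] if recips else None

    if recipient is not None:
        def role(species, variant):
            return [s for s in ftable.samples
                    if labels[s][0] in species and labels[s][1] == variant]

        group_map = {
            "donor_SB": role(donor_species, "SB"),
            "recipient_SB": role([recipient], "SB"),
            "sb_pool": role(donor_species + [recipient], "Sb"),
            "outgroup": [s for s in ftable.samples
                         if labels[s][0] == config.outgroup_species],
        }
        core_sizes = [
            len(role(donor_species, "SB")), len(role(donor_species, "Sb")),
            len(role([recipient], "SB")), len(role([recipient], "Sb")),
        ]
        n_eq = config.equalize_n
        if n_eq is not None and min(core_sizes) < n_eq:
            n_eq = min(core_sizes) or None
            log.warning("equalization reduced to n=%s by group sizes", n_eq)
        sg_table = ash.supergene_sites(ftable, layouts)
        sharing = ash.allele_sharing_test(
            sg_table, labels, donor_species, recipient,
            config.outgroup_species, n_per_group=n_eq,
            polarize=config.polarize, seed=seed,
        )
        report["allele_sharing"] = {
            "n_donor_shared": sharing.n_donor_shared,
            "n_recipient_shared": sharing.n_recipient_shared,
            "p_value": sharing.p_value,
            "polarized": sharing.polarized,
            "n_per_group": sharing.n_per_group,
        }

        if len(sg_ids) >= config.window_size:
            windows = tw.make_windows(
                [l for l in layouts if l.gene_id in set(sg_ids)],
                config.window_size,
            )
            rows = tw.weigh_windows(by_gene, windows, group_map, seed=seed)
            report["topology_weighting"] = tw.summarize_windows(rows)
            report["topology_weighting"]["rows"] = [
                dataclasses.asdict(r) for r in rows
            ]

        all_species = sorted({sp for sp, v in labels.values()})
        third = next((sp for sp in sorted(sb_by_species) + all_species
                      if sp not in donor_species and sp != recipient
                      and sp != config.outgroup_species
                      and any(labels[s][0] == sp for s in ftable.samples)), None)
        if third is not None:
            def rep(sp, variant):
                cands = sorted(s for s in ftable.samples
                               if labels[s][0] == sp and labels[s][1] == variant)
                cands = cands or sorted(s for s in ftable.samples
                                        if labels[s][0] == sp)
                return cands[0] if cands else None

            reps = [rep(donor_species[0], "Sb"), rep(recipient, "Sb"),
                    rep(third, "SB"), rep(config.outgroup_species, "SB")]
            if all(r is not None for r in reps):
                fits, skipped = blm.fit_triplet(
                    [gene_trees[g] for g in sg_ids], reps[:3], reps[3],
                    config.bic_threshold, rng=stage_rng(seed, "blmixture"),
                )
                report["branch_length_mixture"] = {
                    "skipped_trees": skipped,
                    "fits": [dataclasses.asdict(f) for f in fits],
                }

    if config.outdir:
        out = pathlib.Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=str)
        )
    return report
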