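"""Multispecies-coalescent simulator with a balanced supergene polymorphism.

The generator emulates the study system: several *Solenopsis* species
diverging on a dated tree, a non-recombining supergene where the SB and Sb
variants cannot coalesce more recently than the Sb origin, scheduled Sb
introgression events between species, free recombination between genes (and
none within), infinite-sites mutation, Poisson read depth with an
allelic-balance signal, planted diploid contaminant samples and planted
high-coverage "collapsed repeat" regions.

Lineage classes
---------------
For an ordinary gene the lineage classes are species; within a class,
``k`` lineages coalesce at rate ``k(k-1)/2 / (2N)`` per generation and
classes merge at species-split times.  For a supergene gene the classes are
(species x variant): SB classes follow the species tree, Sb classes cannot
coalesce with SB classes, recipient-Sb classes merge into the donor's Sb
class at each introgression event, and the ancestral Sb class merges into
the containing SB class at the Sb origin time.  The three competing
histories (trans-species polymorphism, independent origins, introgression)
are all expressible through this schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .seqs import BASES, GeneAlignment, SiteRecord, decode
from .util import stage_rng

SB = "SB"
Sb = "Sb"


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTreeSpec:
    """Rooted, dated species tree.

    ``node_times`` maps the frozenset of species descending from each
    internal node to its age in years before present; tips are at time 0.
    ``pop_size`` is the effective number of haploid genomes per lineage
    class (pairwise TMRCA = 2N generations).  ``pop_size_overrides`` may
    key on a species name (terminal branch), a frozenset of species (a
    specific ancestral branch) or the wildcard ``"__ancestral__"`` (any
    multi-species class).
    """

    newick_topology: str
    node_times: dict
    generations_per_year: float = 1.0
    pop_size: float = 50_000.0
    pop_size_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        self.node_times = {frozenset(k): float(v) for k, v in self.node_times.items()}
        tree = dendropy.Tree.get(data=self.newick_topology, schema="newick")
        self.species = sorted(t.label for t in tree.taxon_namespace)
        if self.pop_size <= 0:
            raise ConfigurationError("pop_size must be positive")
        self._splits = []  # (time_years, parent_set, [child_sets]) root-ward
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                nd._leafset = frozenset([nd.taxon.label])
                continue
            children = [c._leafset for c in nd.child_nodes()]
            nd._leafset = frozenset().union(*children)
            if len(children) < 2:  # unifurcation (e.g. single-species tree)
                continue
            if nd._leafset not in self.node_times:
                raise ConfigurationError(
                    f"no node time given for clade {sorted(nd._leafset)}"
                )
            t = self.node_times[nd._leafset]
            for c in nd.child_nodes():
                if not c.is_leaf() and self.node_times[c._leafset] >= t:
                    raise ConfigurationError("node times must increase root-ward")
            self._splits.append((t, nd._leafset, children))
        self._splits.sort(key=lambda s: s[0])

    @property
    def root_time_years(self) -> float:
        return self._splits[-1][0] if self._splits else 0.0

    def splits(self):
        return list(self._splits)

    def lineage_set_at(self, species: str, time_years: float) -> frozenset:
        """The species-tree lineage class containing *species* at a time."""
        cur = frozenset([species])
        for t, parent, children in self._splits:
            if t <= time_years and any(cur <= c for c in children):
                cur = parent
        return cur

    def split_time(self, a: str, b: str) -> float:
        """Age of the MRCA of two species."""
        for t, parent, _ in self._splits:
            if a in parent and b in parent:
                return t
        raise ConfigurationError(f"species {a!r} and {b!r} never join")

    def parent_split_time(self, species: str) -> float:
        for t, parent, children in self._splits:
            if any(child == frozenset([species]) for child in children) or any(
                species in child for child in children
            ):
                if species in parent:
                    return t
        raise ConfigurationError(f"{species!r} not in tree")

    def class_pop_size(self, species_set: frozenset) -> float:
        if species_set in self.pop_size_overrides:
            return float(self.pop_size_overrides[species_set])
        if len(species_set) == 1:
            (sp,) = species_set
            if sp in self.pop_size_overrides:
                return float(self.pop_size_overrides[sp])
        elif "__ancestral__" in self.pop_size_overrides:
            return float(self.pop_size_overrides["__ancestral__"])
        return float(self.pop_size)


@dataclass
class SupergeneSpec:
    """Sb origin and the gene indices belonging to the supergene region."""

    origin_time_years: float
    donor_species: str | None
    supergene_gene_indices: tuple
    sb_pop_fraction: float = 0.25  # Sb is the minor variant

    def __post_init__(self):
        self.supergene_gene_indices = tuple(sorted(set(self.supergene_gene_indices)))
        if not 0 < self.sb_pop_fraction <= 1:
            raise ConfigurationError("sb_pop_fraction must be in (0, 1]")


@dataclass
class IntrogressionEvent:
    donor: str
    recipient: str
    time_years: float


@dataclass
class SimConfig:
    species_tree: SpeciesTreeSpec
    supergene: SupergeneSpec
    events: list
    samples: dict  # species -> {variant -> count}
    n_genes: int = 100
    gene_length_bp: int = 5000
    mu: float = 3.5e-9  # mutations / bp / generation
    coverage_mean: float = 10.0
    n_diploid_contaminants: int = 0
    n_collapsed_repeat_regions: int = 0
    seed: int = 0
    sequencing_error: float = 0.02  # P(one opposite-allele read per call)
    call_dropout: float = 0.002  # P(a call has zero reads)
    low_qual_fraction: float = 0.02
    strand_bias_fraction: float = 0.01
    mnp_fraction: float = 0.003  # sites emitted as 2-bp MNPs (parser fodder)
    gene_spacing_bp: int = 200

    def __post_init__(self):
        known = set(self.species_tree.species)
        for sp, variants in self.samples.items():
            if sp not in known:
                raise ConfigurationError(f"unknown species {sp!r} in sample table")
            for v, n in variants.items():
                if v not in (SB, Sb) or n < 0:
                    raise ConfigurationError(f"bad sample spec {sp}:{v}={n}")
        if max(self.supergene.supergene_gene_indices, default=-1) >= self.n_genes:
            raise ConfigurationError("supergene gene index out of range")
        self._validate_sb_reachability()
        self.scenario  # force scenario resolution (raises if ambiguous)

    # -- scenario bookkeeping -------------------------------------------------

    @property
    def sb_species(self) -> list:
        return sorted(sp for sp, v in self.samples.items() if v.get(Sb, 0) > 0)

    def _validate_sb_reachability(self):
        if not self.events:
            return
        reachable = {self.supergene.donor_species}
        grew = True
        while grew:
            grew = False
            for ev in self.events:
                if ev.donor in reachable and ev.recipient not in reachable:
                    reachable.add(ev.recipient)
                    grew = True
        orphans = [sp for sp in self.sb_species if sp not in reachable]
        if orphans:
            raise ConfigurationError(
                f"species {orphans} carry Sb samples but are not reachable from "
                f"donor {self.supergene.donor_species!r} via introgression events"
            )
        for ev in self.events:
            if not 0 <= ev.time_years < self.supergene.origin_time_years:
                raise ConfigurationError(
                    f"event {ev.donor}->{ev.recipient} at {ev.time_years} must be "
                    f"younger than the Sb origin ({self.supergene.origin_time_years})"
                )

    @property
    def scenario(self) -> str:
        st, sg = self.species_tree, self.supergene
        if self.events:
            return "introgression"
        sb = self.sb_species
        if not sb:
            return "trans_species"  # degenerate: no Sb samples at all
        t_origin = sg.origin_time_years
        if len(sb) >= 2:
            t_mrca = max(st.split_time(a, b) for a in sb for b in sb if a < b)
            if t_origin >= t_mrca:
                return "trans_species"
        if all(t_origin < st.parent_split_time(sp) for sp in sb):
            return "independent_origins"
        raise ConfigurationError(
            "ambiguous supergene origin: without events, origin_time_years must be "
            "older than the MRCA of all Sb-bearing species (trans-species) or "
            "younger than each of their parent splits (independent origins)"
        )


@dataclass
class TruthRecord:
    scenario: str
    events: list  # dicts: donor, recipient, time_years
    sb_origin_years: float
    collapsed_repeats: list  # (chrom, start, end) 0-based half-open
    contaminants: dict  # sample -> {"species":, "parents": [h1, h2]}
    gene_mrca: list  # per gene: {"groupA|groupB": mean TMRCA generations}

    def to_json(self) -> str:
        return json.dumps(
            {
                "scenario": self.scenario,
                "events": self.events,
                "sb_origin_years": self.sb_origin_years,
                "collapsed_repeats": [list(r) for r in self.collapsed_repeats],
                "contaminants": self.contaminants,
                "gene_mrca": self.gene_mrca,
            },
            indent=1,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# genealogy
# ---------------------------------------------------------------------------

class Genealogy:
    """Ultrametric binary genealogy in generations, tips labelled
    (sample, species, variant)."""

    def __init__(self, labels, species, variants):
        n = len(labels)
        self.labels = list(labels)
        self.species = list(species)
        self.variants = list(variants)
        self.n_tips = n
        self.time = np.zeros(2 * n - 1)
        self.parent = np.full(2 * n - 1, -1, dtype=np.int64)
        self.children: list = [[] for _ in range(2 * n - 1)]
        self._next = n

    def add_node(self, t, left, right) -> int:
        u = self._next
        self._next += 1
        self.time[u] = t
        self.children[u] = [left, right]
        self.parent[left] = u
        self.parent[right] = u
        return u

    @property
    def root(self) -> int:
        return 2 * self.n_tips - 2

    def branch_lengths(self) -> np.ndarray:
        bl = self.time[self.parent] - self.time
        bl[self.root] = 0.0
        return bl

    def tip_masks(self) -> np.ndarray:
        """(n_nodes, n_tips) bool: tips below each node."""
        n = self.n_tips
        masks = np.zeros((2 * n - 1, n), dtype=bool)
        masks[np.arange(n), np.arange(n)] = True
        for u in range(n, 2 * n - 1):
            for c in self.children[u]:
                masks[u] |= masks[c]
        return masks

    def tmrca_matrix(self) -> np.ndarray:
        n = self.n_tips
        T = np.zeros((n, n))
        masks = self.tip_masks()
        for u in range(n, 2 * n - 1):
            left, right = self.children[u]
            li = np.where(masks[left])[0]
            ri = np.where(masks[right])[0]
            T[np.ix_(li, ri)] = self.time[u]
            T[np.ix_(ri, li)] = self.time[u]
        return T

    def newick(self) -> str:
        def rec(u):
            if u < self.n_tips:
                name = self.labels[u]
            else:
                name = "(" + ",".join(rec(c) for c in self.children[u]) + ")"
            if u == self.root:
                return name
            return f"{name}:{self.time[self.parent[u]] - self.time[u]:.8g}"

        return rec(self.root) + ";"


def _merge_schedule(config: SimConfig, supergene_gene: bool):
    """Time-sorted class-relabelling rules: list of (time_gen, {old: new})."""
    st = config.species_tree
    g = st.generations_per_year
    sched: dict = {}

    def add(t_years, old, new):
        sched.setdefault(t_years * g, {})[old] = new

    variants = (None,) if not supergene_gene else (SB, Sb)
    for t, parent, children in st.splits():
        for v in variants:
            for child in children:
                add(t, (child, v), (parent, v))
    if supergene_gene:
        sg = config.supergene
        t0 = sg.origin_time_years
        scenario = config.scenario
        if scenario == "introgression":
            for ev in config.events:
                add(
                    ev.time_years,
                    (st.lineage_set_at(ev.recipient, ev.time_years), Sb),
                    (st.lineage_set_at(ev.donor, ev.time_years), Sb),
                )
            donor_set = st.lineage_set_at(sg.donor_species, t0)
            add(t0, (donor_set, Sb), (donor_set, SB))
        elif scenario == "independent_origins":
            for sp in config.sb_species:
                add(t0, (frozenset([sp]), Sb), (frozenset([sp]), SB))
        else:  # trans_species: Sb rides the species tree, joins SB at t0
            anchor = config.sb_species[0] if config.sb_species else st.species[0]
            tgt = st.lineage_set_at(anchor, t0)
            add(t0, (tgt, Sb), (tgt, SB))
    return sorted(sched.items())


def _class_pop_size(config: SimConfig, key) -> float:
    species_set, variant = key
    n = config.species_tree.class_pop_size(species_set)
    if variant == Sb:
        n *= config.supergene.sb_pop_fraction
    return n


def simulate_genealogy(
    config: SimConfig,
    gene_index: int,
    rng: np.random.Generator,
    extra_tips: list | None = None,
) -> Genealogy:
    """Structured-coalescent genealogy for one gene.

    ``extra_tips`` is a list of (label, species, variant) appended after
    the declared samples (used internally for hidden contaminant
    haplotypes).
    """
    if not 0 <= gene_index < config.n_genes:
        raise ValueError(f"gene_index {gene_index} out of range")
    supergene_gene = gene_index in config.supergene.supergene_gene_indices

    tips = []
    for sp in sorted(config.samples):
        for v in (SB, Sb):
            for i in range(config.samples[sp].get(v, 0)):
                tips.append((f"{sp}_{v}_{i:02d}", sp, v))
    tips.extend(extra_tips or [])
    labels = [t[0] for t in tips]
    gen = Genealogy(labels, [t[1] for t in tips], [t[2] for t in tips])

    def tip_class(sp, v):
        if not supergene_gene:
            return (frozenset([sp]), None)
        return (frozenset([sp]), v)

    lineages = [(i, tip_class(sp, v)) for i, (_, sp, v) in enumerate(tips)]
    schedule = _merge_schedule(config, supergene_gene)
    ev_idx = 0
    t = 0.0
    while len(lineages) > 1:
        # per-class coalescence rates
        classes: dict = {}
        for node, key in lineages:
            classes.setdefault(key, []).append(node)
        keys = sorted(classes, key=repr)
        rates = np.array(
            [
                len(classes[k]) * (len(classes[k]) - 1) / 2.0 / (2.0 * _class_pop_size(config, k))
                for k in keys
            ]
        )
        total = rates.sum()
        t_next = schedule[ev_idx][0] if ev_idx < len(schedule) else np.inf
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if t + wait < t_next:
            t += wait
            k = keys[rng.choice(len(keys), p=rates / total)]
            members = classes[k]
            i, j = rng.choice(len(members), size=2, replace=False)
            a, b = members[i], members[j]
            u = gen.add_node(t, a, b)
            lineages = [(n, c) for n, c in lineages if n not in (a, b)]
            lineages.append((u, k))
        else:
            if not np.isfinite(t_next):
                raise ConfigurationError(
                    "lineages can never fully coalesce; check class schedule"
                )
            t = t_next
            mapping = schedule[ev_idx][1]
            ev_idx += 1

            def relabel(c):
                seen = set()
                while c in mapping and c not in seen:  # chase chained merges
                    seen.add(c)
                    c = mapping[c]
                return c

            lineages = [(n, relabel(c)) for n, c in lineages]
    return gen


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

def drop_mutations(
    genealogy: Genealogy,
    mu: float,
    gene_length_bp: int,
    rng: np.random.Generator,
    gene_id: str = "gene",
):
    """Infinite-sites mutations: Poisson(mu * L * branch) per branch, distinct
    uniform positions (collisions redrawn), random ancestral sequence.

    Returns (GeneAlignment over the genealogy's tips, list of SiteRecord,
    ancestral sequence codes).
    """
    if gene_length_bp <= 0:
        raise ValueError("gene length must be positive")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    L = gene_length_bp
    n = genealogy.n_tips
    bl = genealogy.branch_lengths()
    counts = rng.poisson(mu * L * bl)
    counts[genealogy.root] = 0
    total = int(counts.sum())
    if total > L:
        raise ValueError(
            f"{total} mutations on a {L} bp gene: infinite-sites assumption broken"
        )
    anc = rng.integers(0, 4, size=L, dtype=np.uint8)
    positions = rng.choice(L, size=total, replace=False)  # distinct == redraw
    shifts = rng.integers(1, 4, size=total, dtype=np.uint8)
    masks = genealogy.tip_masks()
    seqs = np.tile(anc, (n, 1))
    records = []
    pos_cursor = 0
    for node in range(2 * n - 1):
        for _ in range(counts[node]):
            p = int(positions[pos_cursor])
            der = int((anc[p] + shifts[pos_cursor]) % 4)
            pos_cursor += 1
            carriers = masks[node].copy()
            seqs[carriers, p] = der
            records.append(SiteRecord(p + 1, int(anc[p]), der, carriers))
    records.sort(key=lambda r: r.position)
    aln = GeneAlignment(gene_id, list(genealogy.labels), seqs)
    return aln, records, anc


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class GeneLayout:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    in_supergene: bool


class SimulatedDataset:
    """In-memory result of :func:`simulate_dataset`; ``write`` serializes."""

    def __init__(self, config, truth, metadata, alignments, site_records,
                 gene_layouts, ref_seqs, vcf_text, bed_text, depth_profile):
        self.config = config
        self.truth = truth
        self.metadata = metadata
        self.alignments = alignments
        self.site_records = site_records
        self.gene_layouts = gene_layouts
        self.ref_seqs = ref_seqs
        self.vcf_text = vcf_text
        self.bed_text = bed_text
        self.depth_profile = depth_profile

    def gene_models_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "chrom": g.chrom,
                    "start": g.start,
                    "end": g.end,
                    "in_supergene": g.in_supergene,
                }
                for g in self.gene_layouts
            ]
        )

    def write(self, outdir, write_depth: bool = False):
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "genotypes.vcf").write_text(self.vcf_text)
        (out / "collapsed_repeats.bed").write_text(self.bed_text)
        (out / "truth.json").write_text(self.truth.to_json())
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        with open(out / "reference.fasta", "w") as fh:
            for chrom in sorted(self.ref_seqs):
                fh.write(f">{chrom}\n{decode(self.ref_seqs[chrom])}\n")
        with open(out / "genes.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.gene_layouts:
                fh.write(
                    f"{g.chrom}\tsbkit\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                    f"ID={g.gene_id};in_supergene={int(g.in_supergene)}\n"
                )
        aln_dir = out / "alignments"
        aln_dir.mkdir(exist_ok=True)
        for aln in self.alignments:
            (aln_dir / f"{aln.gene_id}.fasta").write_text(aln.to_fasta())
        if write_depth:
            with open(out / "depth.tsv", "w") as fh:
                fh.write("chrom\tpos\tmean_depth\n")
                for chrom in sorted(self.depth_profile):
                    for i, d in enumerate(self.depth_profile[chrom]):
                        fh.write(f"{chrom}\t{i + 1}\t{d:.4g}\n")
        return out


def _layout_genes(config: SimConfig):
    layouts, offsets = [], {}
    sg = set(config.supergene.supergene_gene_indices)
    cursors = {"chr1": config.gene_spacing_bp, "chr16": config.gene_spacing_bp}
    for g in range(config.n_genes):
        chrom = "chr16" if g in sg else "chr1"
        start = cursors[chrom]
        end = start + config.gene_length_bp
        cursors[chrom] = end + config.gene_spacing_bp
        layouts.append(GeneLayout(f"gene{g:04d}", chrom, start, end, g in sg))
    lengths = {c: cursors[c] for c in cursors}
    return layouts, lengths


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Simulate genealogies, mutations and a VCF with coverage artifacts.

    Byte-identical outputs for identical seeds.
    """
    seed = config.seed
    n_vis = sum(n for v in config.samples.values() for n in v.values())
    if n_vis == 0:
        raise ConfigurationError("no samples declared")

    # hidden haplotypes: the reference genome (an extant haplotype, as the
    # real reference is an S. invicta SB assembly) and the diploid
    # contaminants' parent genomes
    contaminant_species = []
    ref_sp = "inv" if config.samples.get("inv") else sorted(
        sp for sp, v in config.samples.items() if sum(v.values()) > 0
    )[0]
    ref_var = SB if config.samples[ref_sp].get(SB, 0) else Sb
    # plant contaminants starting in the reference species: a diploid male
    # conspecific with the reference shows the canonical excess of
    # intermediate allelic balance among its (few) variant sites
    sp_cycle = sorted(
        (sp for sp in config.samples if config.samples[sp].get(SB, 0) > 0),
        key=lambda sp: (sp != ref_sp, sp),
    )
    if config.n_diploid_contaminants and not sp_cycle:
        raise ConfigurationError("diploid contaminants need >=1 SB-bearing species")
    extra = [("__ref", ref_sp, ref_var)]
    contaminants = {}
    for c in range(config.n_diploid_contaminants):
        sp = sp_cycle[c % len(sp_cycle)]
        contaminant_species.append(sp)
        name = f"dip_{sp}_{c:02d}"
        h1, h2 = f"__hap_{name}_a", f"__hap_{name}_b"
        extra.extend([(h1, sp, SB), (h2, sp, SB)])
        contaminants[name] = {"species": sp, "parents": [h1, h2]}

    layouts, chrom_lengths = _layout_genes(config)
    genealogies, alignments, all_records, ref_gene_seqs = [], [], [], []
    gene_mrca = []
    for g in range(config.n_genes):
        rng = stage_rng(seed, "genealogy", f"gene{g:05d}")
        gen = simulate_genealogy(config, g, rng, extra_tips=extra)
        aln, recs, anc = drop_mutations(
            gen, config.mu, config.gene_length_bp,
            stage_rng(seed, "mutations", f"gene{g:05d}"), gene_id=layouts[g].gene_id,
        )
        genealogies.append(gen)
        all_records.append((recs, anc))
        ref_gene_seqs.append(aln.seqs[aln.labels.index("__ref")].copy())
        # visible-sample alignment (hidden haplotypes stripped)
        vis = [i for i, lab in enumerate(aln.labels)
               if not lab.startswith("__hap_") and lab != "__ref"]
        alignments.append(
            GeneAlignment(aln.gene_id, [aln.labels[i] for i in vis], aln.seqs[vis])
        )
        # truth MRCA summary by (species, variant) group pair
        T = gen.tmrca_matrix()
        groups: dict = {}
        for i, lab in enumerate(gen.labels):
            if lab.startswith("__hap_") or lab == "__ref":
                continue
            groups.setdefault(f"{gen.species[i]}/{gen.variants[i]}", []).append(i)
        summary = {}
        for ga in sorted(groups):
            for gb in sorted(groups):
                if ga < gb:
                    summary[f"{ga}|{gb}"] = float(
                        T[np.ix_(groups[ga], groups[gb])].mean()
                    )
        gene_mrca.append(summary)

    # reference chromosomes: gene regions carry the reference haplotype
    ref_rng = stage_rng(seed, "reference")
    ref_seqs = {
        c: ref_rng.integers(0, 4, size=ln, dtype=np.uint8)
        for c, ln in sorted(chrom_lengths.items())
    }
    for g, lay in enumerate(layouts):
        ref_seqs[lay.chrom][lay.start:lay.end] = ref_gene_seqs[g]

    # planted collapsed-repeat regions inside non-supergene genes
    rep_rng = stage_rng(seed, "repeats")
    non_sg = [lay for lay in layouts if not lay.in_supergene]
    repeats = []
    if config.n_collapsed_repeat_regions:
        picks = rep_rng.choice(
            len(non_sg), size=min(config.n_collapsed_repeat_regions, len(non_sg)),
            replace=False,
        )
        for p in sorted(picks):
            lay = non_sg[p]
            span = int(0.5 * (lay.end - lay.start))
            start = lay.start + int(0.2 * (lay.end - lay.start))
            repeats.append((lay.chrom, start, start + span))
    repeat_factor = 3.0

    def depth_factor(chrom, pos0):
        for c, s, e in repeats:
            if c == chrom and s <= pos0 < e:
                return repeat_factor
        return 1.0

    # metadata
    meta_rows = []
    vis_labels = alignments[0].labels
    for lab in vis_labels:
        sp, v, _ = lab.split("_")
        meta_rows.append({"sample": lab, "species": sp, "variant": v, "ploidy_truth": 1})
    for name, info in contaminants.items():
        meta_rows.append(
            {"sample": name, "species": info["species"], "variant": SB, "ploidy_truth": 2}
        )
    metadata = pd.DataFrame(meta_rows)
    all_samples = list(metadata["sample"])

    # VCF
    cov_rng = stage_rng(seed, "coverage")
    lines = [
        "##fileformat=VCFv4.2",
        "##source=sbkit-simdata",
    ]
    for c in sorted(chrom_lengths):
        lines.append(f"##contig=<ID={c},length={chrom_lengths[c]}>")
    lines += [
        '##INFO=<ID=SRF,Number=1,Type=Integer,Description="Ref reads on forward strand">',
        '##INFO=<ID=SRR,Number=1,Type=Integer,Description="Ref reads on reverse strand">',
        '##INFO=<ID=SAF,Number=1,Type=Integer,Description="Alt reads on forward strand">',
        '##INFO=<ID=SAR,Number=1,Type=Integer,Description="Alt reads on reverse strand">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(all_samples),
    ]
    records_out = []  # (chrom, pos, line)
    full_label_index = {lab: i for i, lab in enumerate(genealogies[0].labels)}
    ref_row = full_label_index["__ref"]
    for g, lay in enumerate(layouts):
        recs, anc = all_records[g]
        for rec in recs:
            pos0 = lay.start + rec.position - 1
            fac = depth_factor(lay.chrom, pos0)
            # VCF alleles are relative to the reference haplotype
            ref_is_derived = bool(rec.carriers[ref_row])
            ref_code = rec.derived if ref_is_derived else rec.ancestral
            alt_code = rec.ancestral if ref_is_derived else rec.derived
            segregates = any(
                bool(rec.carriers[full_label_index[lab]]) != ref_is_derived
                for lab in vis_labels
            ) or any(
                rec.carriers[full_label_index[pa]] != rec.carriers[full_label_index[pb]]
                for pa, pb in (info["parents"] for info in contaminants.values())
            )
            if not segregates:  # private to the reference haplotype
                continue
            ref_b = decode(np.array([ref_code], dtype=np.uint8))
            alt_b = decode(np.array([alt_code], dtype=np.uint8))
            is_mnp = cov_rng.random() < config.mnp_fraction
            if is_mnp:  # emit as undecomposed 2-bp MNP (dropped by the parser)
                pad = decode(ref_seqs[lay.chrom][pos0 + 1:pos0 + 2])
                ref_b, alt_b = ref_b + pad, alt_b + pad
            qual = (
                cov_rng.uniform(0.0, 40.0)
                if cov_rng.random() < config.low_qual_fraction
                else max(50.0, cov_rng.normal(300.0, 60.0))
            )
            gts, dps, ads = [], [], []
            tot_ref = tot_alt = 0
            for lab in all_samples:
                if lab in contaminants:
                    pa, pb = contaminants[lab]["parents"]
                    a1 = bool(rec.carriers[full_label_index[pa]]) != ref_is_derived
                    a2 = bool(rec.carriers[full_label_index[pb]]) != ref_is_derived
                    depth = cov_rng.poisson(config.coverage_mean * fac)
                    if depth == 0 or cov_rng.random() < config.call_dropout:
                        gts.append(".")
                        dps.append(0)
                        ads.append((0, 0))
                        continue
                    if a1 != a2:  # true heterozygote
                        p_alt = cov_rng.beta(20.0, 20.0)
                        alt_reads = cov_rng.binomial(depth, p_alt)
                    else:
                        alt_reads = depth if a1 else 0
                        if cov_rng.random() < config.sequencing_error and depth > 0:
                            alt_reads = alt_reads - 1 if a1 else 1
                    call = 1 if 2 * alt_reads >= depth else 0
                else:
                    carrier = bool(rec.carriers[full_label_index[lab]]) != ref_is_derived
                    depth = cov_rng.poisson(config.coverage_mean * fac)
                    if depth == 0 or cov_rng.random() < config.call_dropout:
                        gts.append(".")
                        dps.append(0)
                        ads.append((0, 0))
                        continue
                    alt_reads = depth if carrier else 0
                    if cov_rng.random() < config.sequencing_error:
                        alt_reads = alt_reads - 1 if carrier else 1
                    call = 1 if carrier else 0
                gts.append(str(call))
                dps.append(depth)
                ads.append((depth - alt_reads, alt_reads))
                tot_ref += depth - alt_reads
                tot_alt += alt_reads
            if config.strand_bias_fraction and cov_rng.random() < config.strand_bias_fraction:
                srf, saf = tot_ref, tot_alt
                srr = sar = 0
            else:
                srf = int(cov_rng.binomial(tot_ref, 0.5)) if tot_ref else 0
                saf = int(cov_rng.binomial(tot_alt, 0.5)) if tot_alt else 0
                srr, sar = tot_ref - srf, tot_alt - saf
            info = f"SRF={srf};SRR={srr};SAF={saf};SAR={sar}"
            fields = [
                lay.chrom, str(pos0 + 1), ".", ref_b, alt_b, f"{qual:.2f}", ".",
                info, "GT:DP:AD",
            ] + [
                f"{gt}:{dp}:{ad[0]},{ad[1]}" for gt, dp, ad in zip(gts, dps, ads)
            ]
            records_out.append((lay.chrom, pos0 + 1, "\t".join(fields)))
    records_out.sort(key=lambda r: (r[0], r[1]))
    lines += [r[2] for r in records_out]
    vcf_text = "\n".join(lines) + "\n"

    bed_text = "".join(f"{c}\t{s}\t{e}\n" for c, s, e in repeats)

    # per-position mean depth across samples (for region masking)
    depth_rng = stage_rng(seed, "depth_profile")
    n_total = len(all_samples)
    depth_profile = {}
    for chrom in sorted(chrom_lengths):
        lam = np.full(chrom_lengths[chrom], config.coverage_mean * n_total)
        for c, s, e in repeats:
            if c == chrom:
                lam[s:e] *= repeat_factor
        depth_profile[chrom] = depth_rng.poisson(lam).astype(np.float64) / n_total

    truth = TruthRecord(
        scenario=config.scenario,
        events=[
            {"donor": e.donor, "recipient": e.recipient, "time_years": e.time_years}
            for e in config.events
        ],
        sb_origin_years=config.supergene.origin_time_years,
        collapsed_repeats=repeats,
        contaminants=contaminants,
        gene_mrca=gene_mrca,
    )
    return SimulatedDataset(
        config, truth, metadata, alignments, [r for r, _ in all_records],
        layouts, ref_seqs, vcf_text, bed_text, depth_profile,
    )


def simulate_alignments(config: SimConfig):
    """Genealogies and alignments only (no read-model artifacts, no VCF).

    The light-weight path for tree-recovery experiments: returns
    (alignments, genealogies, scenario).  Seed handling matches
    :func:`simulate_dataset`, so gene g has the same genealogy in both.
    """
    gens, alns = [], []
    for g in range(config.n_genes):
        gen = simulate_genealogy(
            config, g, stage_rng(config.seed, "genealogy", f"gene{g:05d}")
        )
        aln, _, _ = drop_mutations(
            gen, config.mu, config.gene_length_bp,
            stage_rng(config.seed, "mutations", f"gene{g:05d}"),
            gene_id=f"gene{g:04d}",
        )
        gens.append(gen)
        alns.append(aln)
    return alns, gens, config.scenario


# ---------------------------------------------------------------------------
# paper-like presets
# ---------------------------------------------------------------------------

SPECIES_NEWICK = "(((((inv,mac),rich),meg),intr),gem);"
NODE_TIMES_MYA = {
    ("inv", "mac"): 0.81,
    ("inv", "mac", "rich"): 1.01,
    ("inv", "mac", "rich", "meg"): 1.30,
    ("inv", "mac", "rich", "meg", "intr"): 1.60,
    ("inv", "mac", "rich", "meg", "intr", "gem"): 3.90,
}
SB_ORIGIN_MYA = 0.97


def paper_like_species_tree(
    pop_size: float = 50_000.0, ancestral_pop_size: float = 10_000.0
) -> SpeciesTreeSpec:
    """Six *Solenopsis*-like species on the study's dated backbone.

    Splits at 0.81 (S. invicta/macdonaghi diversification), 1.01
    (S. richteri), 3.90 Mya (S. geminata outgroup) follow the study's
    inference; the 1.30/1.60 Mya attachments of the basal species are free
    choices.  Ancestral branches default to a smaller population size
    (speciation bottlenecks), consistent with the low gene-tree discordance
    the study observed.
    """
    return SpeciesTreeSpec(
        newick_topology=SPECIES_NEWICK,
        node_times={k: v * 1e6 for k, v in NODE_TIMES_MYA.items()},
        generations_per_year=1.0,
        pop_size=pop_size,
        pop_size_overrides={"__ancestral__": ancestral_pop_size},
    )


def _default_samples(include_meg_sb: bool) -> dict:
    samples = {
        "inv": {SB: 5, Sb: 5},
        "mac": {SB: 5},
        "rich": {SB: 5, Sb: 5},
        "meg": {SB: 4, Sb: 2} if include_meg_sb else {SB: 4},
        "intr": {SB: 3},
        "gem": {SB: 2},
    }
    return samples


def _preset(
    scenario: str,
    seed: int,
    n_genes: int,
    n_supergene: int,
    n_diploid_contaminants: int,
    n_collapsed_repeat_regions: int,
) -> SimConfig:
    st = paper_like_species_tree()
    sg_idx = tuple(range(n_genes - n_supergene, n_genes))
    if scenario == "introgression":
        supergene = SupergeneSpec(SB_ORIGIN_MYA * 1e6, "inv", sg_idx)
        events = [
            IntrogressionEvent("inv", "rich", 0.75e6),
            IntrogressionEvent("inv", "meg", 0.10e6),
        ]
        samples = _default_samples(include_meg_sb=True)
    elif scenario == "trans_species":
        supergene = SupergeneSpec(1.15e6, None, sg_idx)
        events = []
        samples = _default_samples(include_meg_sb=False)
    elif scenario == "independent_origins":
        supergene = SupergeneSpec(0.50e6, None, sg_idx)
        events = []
        samples = _default_samples(include_meg_sb=False)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return SimConfig(
        species_tree=st,
        supergene=supergene,
        events=events,
        samples=samples,
        n_genes=n_genes,
        seed=seed,
        n_diploid_contaminants=n_diploid_contaminants,
        n_collapsed_repeat_regions=n_collapsed_repeat_regions,
    )


def preset_introgression(seed=0, n_genes=100, n_supergene=30,
                         n_diploid_contaminants=2, n_collapsed_repeat_regions=2):
    """Sb arises in S. invicta/macdonaghi at 0.97 Mya and introgresses into
    S. richteri (0.75 Mya, old) and S. megergates (0.10 Mya, recent)."""
    return _preset("introgression", seed, n_genes, n_supergene,
                   n_diploid_contaminants, n_collapsed_repeat_regions)


def preset_trans_species(seed=0, n_genes=100, n_supergene=30,
                         n_diploid_contaminants=2, n_collapsed_repeat_regions=2):
    """SB/Sb divergence at 1.15 Mya, in the common ancestor of the
    socially dimorphic species (older than their 1.01 Mya split)."""
    return _preset("trans_species", seed, n_genes, n_supergene,
                   n_diploid_contaminants, n_collapsed_repeat_regions)


def preset_independent_origins(seed=0, n_genes=100, n_supergene=30,
                               n_diploid_contaminants=2, n_collapsed_repeat_regions=2):
    """Sb arises separately within each dimorphic species at 0.50 Mya."""
    return _preset("independent_origins", seed, n_genes, n_supergene,
                   n_diploid_contaminants, n_collapsed_repeat_regions)


def preset_pure_ils(seed=0, n_genes=500, gene_length_bp=5000) -> SimConfig:
    """Four species with a very short internal branch: abundant incomplete
    lineage sorting and no supergene signal (control for the branch-length
    mixture test)."""
    st = SpeciesTreeSpec(
        newick_topology="(((A,B),C),O);",
        node_times={
            ("A", "B"): 200_000.0,
            ("A", "B", "C"): 220_000.0,
            ("A", "B", "C", "O"): 2_000_000.0,
        },
        pop_size=50_000.0,
    )
    supergene = SupergeneSpec(2_500_000.0, None, ())
    return SimConfig(
        species_tree=st,
        supergene=supergene,
        events=[],
        samples={"A": {SB: 1}, "B": {SB: 1}, "C": {SB: 1}, "O": {SB: 1}},
        n_genes=n_genes,
        gene_length_bp=gene_length_bp,
        seed=seed,
    )
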