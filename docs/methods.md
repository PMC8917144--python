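# Methods

`sbkit` reconstructs, at desk scale, the chain of inference by which one
decides whether a supergene polymorphism shared by several species is (a) a
trans-species polymorphism older than the speciations, (b) the product of
independent origins within each species, or (c) a single origin followed by
introgression of the derived variant.  The model system is the fire-ant
social chromosome: the Sb variant of the chromosome-16 supergene determines
multiple-queen colonies, recombines with neither SB nor between species,
and is carried by haploid males whose genomes can be genotyped directly.

## The generative model

### Structured coalescent with a balanced supergene

Each gene has its own genealogy drawn from a structured coalescent over
*lineage classes*.  For an ordinary (collinear-genome) gene the classes are
species; `k` lineages in a class of `N` haploid genomes coalesce at rate
`k(k-1)/2 * 1/(2N)` per generation (pairwise TMRCA `2N` generations), and
classes merge at the dated species splits.  For a supergene gene the
classes are (species x variant).  SB classes follow the species tree.  Sb
classes cannot coalesce with SB classes; they merge into the donor's Sb
class at each introgression event time, and the last Sb class merges into
the enclosing SB class at the Sb origin time `T_sb`.  The three competing
histories differ only in this merge schedule:

* **trans-species** — Sb classes ride the species tree and join SB in the
  common ancestor (`T_sb` older than the splits of the Sb-bearing species);
* **independent origins** — each species' Sb class joins its own SB class
  at `T_sb` (younger than every Sb-bearing species' parent split);
* **introgression** — recipient Sb classes join the donor's Sb pool at the
  event times; only the donor's Sb descends from `T_sb`.

Genes are unlinked (free recombination between genes, none within).  The
supergene's linkage is represented by the shared class structure, not by a
shared genealogy across supergene genes; this is conservative for
tree-concordance statistics, because even fully linked loci could not be
more concordant than loci constrained by the same class schedule.

### Dates and population sizes

The species-tree backbone follows the study system's published dates:
*S. invicta/macdonaghi* diversification 0.81 Mya, split from *S. richteri*
1.01 Mya, Sb origin 0.97 Mya, outgroup (*S. geminata*) 3.9 Mya.  The
attachments of the two basal species (1.30, 1.60 Mya) are free choices in
the same range.  One generation per year.

No effective population sizes are published for these species; they are
free parameters and were fixed once, before any downstream testing, by two
requirements a field scientist would recognize: within-species nucleotide
diversity of a few SNPs per 5-kb gene (ants are low-diversity), and the
low gene-tree discordance implied by the near-uniform support the empirical
coalescent trees show at the nodes dated 0.81-1.01 Mya.  Defaults:

| parameter | default | rationale |
|---|---|---|
| tip-branch pop. size | 50 000 haploid genomes | pairwise diversity ~3.5 diffs / 5 kb gene pair |
| ancestral-branch pop. size | 10 000 | speciation bottlenecks; matches observed low ILS at the 0.97/1.01 Mya nodes |
| Sb class size fraction | 0.25 | Sb is the minor variant in dimorphic populations |
| mutation rate `mu` | 3.5e-9 /bp/gen | direct estimates in social insects |
| gene span | 5 000 bp | gene incl. introns |
| genes | 100 (30 supergene) | desk-scale analogue of the >1,600-gene empirical datasets |
| samples | ~35 across 6 species | ~5 per species x variant |
| coverage | Poisson(10) per call | matches ~10x study coverage |

### Read-model artifacts

The VCF layer adds what the filter cascade exists to remove.  Depth is
Poisson(10) per call; a haploid call has allelic balance 0 or 1 except
that with probability 0.02 one read carries the opposite allele.  Planted
*diploid contaminants* are built from two hidden conspecific haplotypes;
at their truly heterozygous sites the alt-read fraction is
Beta(20,20)-distributed, so the allelic balance concentrates in the
forbidden (0.25, 0.75) band.  Planted *collapsed repeats* multiply depth by
3 across a half-gene interval in every sample.  A small fraction of records
is emitted as undecomposed 2-bp MNPs (parser fodder), with low quality
(2%), or with single-strand support (1%).

The VCF's REF is **not** the ancestral sequence: a hidden extant haplotype
(donor-species SB) is simulated alongside the samples and serves as the
reference genome, as in the real pipeline where the reference is an
*S. invicta* SB assembly.  This matters: against a conspecific reference a
diploid contaminant is heterozygous-like at roughly half of its variant
sites, whereas against a deep ancestor the het-like fraction would be
diluted by fixed differences.

## The analysis chain

1. **Filter cascade** (fixed order, idempotent): exclusion of regions with
   mean depth > median + 3 SD of single-copy-gene coverage (runs merged
   across <10 bp gaps); SNP-only/quality >= 30/both-strand site filters;
   per-call masking when depth exceeds the sample's own median + 3 SD cap
   or allelic balance lies in [0.25, 0.75] (inclusive — "between" read
   conservatively for haploids); random-allele haploidization of pooled
   samples; dropping samples with > 25% missing calls and flagging as
   diploid samples whose pre-masking heterozygous-like fraction exceeds 5x
   the cohort median (absolute fallback 0.10 if the median is zero);
   retention of sites called in strictly > 75% of remaining samples.
2. **Consensus and informative genes**: reference-projected per-sample
   consensus (missing -> N); genes kept when the ingroup-average count of
   non-N differences from the reference is >= 10.  N positions are excluded
   from the count (the alternative — counting them — would conflate
   missingness with divergence).
3. **Gene trees**: Jukes-Cantor distances with pairwise deletion
   (p >= 0.75 capped at 5.0 substitutions/site), neighbor joining with
   deterministic lowest-index tie-breaking and negative branch lengths
   clamped to zero, optional site-resampling bootstrap.  Distance NJ
   deliberately replaces per-gene maximum likelihood: it is deterministic,
   fast, and sufficient for a quartet-based summary, which consumes induced
   topologies rather than branch lengths.  (Consequently there is no
   analogue of ML convergence filtering.)
4. **Summary trees**: the candidate maximizing the quartet score (number of
   gene-tree-induced resolved 4-taxon topologies agreeing with the
   candidate).  Exhaustive enumeration up to 8 tips; otherwise NNI
   hill-climbing (first improvement) from an NJ start on mean
   internode-count distances.  Induced quartets are read off tip-to-tip
   path lengths via the four-point condition, vectorized over all C(n,4)
   subsets; per-gene quartet codes are histogrammed once so a candidate's
   score costs one gather regardless of gene count.  Internal branch
   lengths are coalescent units `-ln(1.5(1-q))` from the fraction `q` of
   resolved quartets around the edge agreeing with it (capped at 10 when
   q = 1, floored at 0); terminal branches carry a nominal length 1.
   Support is a multilocus (gene-resampling) bootstrap; replicate searches
   restart from the point topology, and genes are put in canonical order
   first so supports depend only on the gene-tree multiset.  Trees are
   rooted on the outgroup and internal branches shorter than 0.05
   (coalescent units, the natural reading for these trees) are collapsed.
5. **Scenario call**: ordered monophyly/sister rules (independent origins,
   then trans-species, then introgression, else unresolved) as documented
   in `sbkit.scenario`.  The donor may span several nominal species when
   the sister clade does (the *S. invicta/macdonaghi* situation).  The
   count of maximal non-donor Sb subclades is reported as a lower bound on
   the number of introgression events.
6. **Allele sharing**: on supergene-region sites only (outside the
   non-recombining region a recipient-species Sb male is genomically
   recipient-like, which would invert the counts), per-group strict-
   majority consensus, counts of sites where the Sb pool sides with the
   donor vs the recipient SB consensus, optional outgroup polarization
   (default on), groups equalized per species x variant, two-sided exact
   binomial test against 0.5.  Sites within a gene are linked, so the
   nominal calibration is approximate; in practice the polarized statistic
   is conservative under the symmetric (trans-species) history because
   informative sites are then rare.
7. **Topology weighting**: non-overlapping windows of 4 supergene genes in
   genomic order (trailing remainder dropped), one JC+NJ tree per window
   from the concatenated alignment, weights over the three group topologies
   of {donor-SB, recipient-SB, Sb pool, outgroup} by exhaustive (or
   sampled) one-tip-per-group enumeration.  Weights are exact rationals so
   they sum to exactly 1.
8. **Branch-length mixture**: per species-triplet-plus-outgroup, each gene
   tree is pruned to four tips, rooted, and contributes the internal branch
   length of its monophyletic pair.  M1 is a single exponential (ILS); M2
   adds a shifted component
   `(1-pi2) lam e^{-lam t} + pi2 lam e^{-lam(t-delta)} 1[t>=delta]`
   with shared rate (3 free parameters), fit by EM over (pi2, lambda) with
   the shift `delta` profiled over empirical quantiles and refined locally
   (the likelihood is not smooth in `delta`).  pi2 = 0 is an EM fixed
   point, hence multi-start.  The per-iteration log-likelihood is asserted
   non-decreasing.  Call: non-ILS iff BIC1 - BIC2 > 10 (strict).  Branch
   lengths are used as-is in substitutions/site.  Note the method separates
   ILS from *any* non-ILS history; an ancient trans-species polymorphism
   also produces a shifted component, so this statistic complements, and
   does not replace, the scenario rules.

## What the simulator does and does not emulate

It emulates the coalescent/mutational signal that the inference chain
consumes, the coverage/allelic-balance artifacts the filters target, and
scheduled introgression with known truth.  It does **not** emulate read
mapping and alignment error, copy-number variation beyond the depth-factor
caricature, selection or meiotic drive on Sb, within-gene recombination,
base-quality structure, or the concatenation-vs-coalescent subtleties of
real data.  Passing the recovery suites therefore shows the chain is
correct and well-calibrated *under its own model*, not that real data of
this size would behave as cleanly.

## Numerical choices and degenerate inputs

* NJ tie-breaking: first minimum of the Q-criterion in row-major order.
* Quartets with non-unique four-point minima are unresolved and contribute
  nothing to scores or weights.
* Exhaustive-search ties are broken by stepwise-addition enumeration order
  and logged.
* Saturated JC distances (p >= 0.75) map to 5.0 with a warning; zero
  pairwise overlap is an error; gene pairs overlapping < 50 sites warn.
* All-zero branch-length sets cap the exponential rate at 1e9.
* Windows with tied topology weights have no winner and are excluded from
  winner counts (logged).
* Single randomness root: every stage derives its stream from
  (seed, stage-name) via `SeedSequence` spawn keys, so adding a stage never
  shifts another stage's draws, and identical configs reproduce outputs
  byte-for-byte.

## Problem sizes

Default experiments use 100 genes (30 supergene) x ~35 samples x 5 kb,
20 seeds per scenario for recovery rates, 100 seeds for the sharing-test
calibration, and n = 2000 draws for mixture recovery — sizes chosen so the
whole analysis chain, not a cache of its outputs, can be re-run routinely.

## Known limitations

* The sharing-test counts depend on the consensus rule; strict majority
  with tie-skip discards sites a frequency-threshold rule would keep.
* Coalescent-unit branch lengths are undefined for terminal edges; the
  nominal value 1 is a display convention, and the 0.05 collapse threshold
  is only applied to internal edges.
* The subclade count undercounts introgression events when two events are
  adjacent in the tree (secondary-transfer ambiguity), and overcounts when
  a recipient's samples fail to be monophyletic; it is reported as a lower
  bound with memberships listed.
* `pi2`/`delta` in the mixture are weakly identified when `delta` is small
  relative to 1/lambda (the components then nearly coincide); fits with
  n < 10 are flagged unreliable.
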