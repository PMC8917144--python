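"""Filter-cascade unit and property tests, including an independent
brute-force recount oracle on a simulated VCF."""

import numpy as np
import pandas as pd
import pytest

from sbkit import filtering as flt
from sbkit.genotypes import MISSING, GenotypeTable, read_vcf


def make_table(
    quals=(100.0, 100.0),
    fwd=(True, True),
    rev=(True, True),
    alleles=None,
    depth=None,
    ab=None,
    n_samples=2,
    ref="A",
    alt="T",
):
    n_sites = len(quals)
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_sites,
            "pos": np.arange(1, n_sites + 1) * 10,
            "ref": [ref] * n_sites,
            "alt": [alt] * n_sites,
            "qual": list(quals),
            "has_fwd": list(fwd),
            "has_rev": list(rev),
        }
    )
    if alleles is None:
        alleles = np.zeros((n_sites, n_samples), dtype=np.int16)
    if depth is None:
        depth = np.full((n_sites, n_samples), 10, dtype=np.int32)
    if ab is None:
        ab = np.zeros((n_sites, n_samples), dtype=np.float32)
    return GenotypeTable(
        sites, [f"s{i}" for i in range(n_samples)],
        np.asarray(alleles, dtype=np.int16), np.asarray(depth, dtype=np.int32),
        np.asarray(ab, dtype=np.float32),
    )


class TestHighCoverageMask:
    def test_uniform_depth_yields_empty_mask(self):
        prof = {"chr1": np.full(1000, 10.0)}
        mask = flt.high_coverage_mask(prof, [("chr1", 0, 1000)])
        assert len(mask.intervals) == 0

    def test_threshold_is_median_plus_three_sd(self):
        # single-copy depths with median 10 and SD 2 -> threshold 16
        depths = np.array([8.0, 10.0, 12.0] * 100)
        assert np.median(depths) == 10 and abs(depths.std() - np.sqrt(8 / 3)) < 1e-9
        d = np.array([6.0, 8.0, 10.0, 12.0, 14.0])  # median 10, sd sqrt(8)
        scaled = 10 + (d - 10) * (2 / d.std())
        prof = {"chr1": scaled}
        mask = flt.high_coverage_mask(prof, [("chr1", 0, 5)])
        assert mask.threshold_used == pytest.approx(16.0)

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError):
            flt.high_coverage_mask({}, [("chr1", 0, 10)])

    def test_planted_repeats_masked_over_seeds(self):
        from sbkit import simdata as sd

        frac = []
        for seed in range(8):
            cfg = sd.preset_introgression(
                seed=seed, n_genes=12, n_supergene=3,
                n_diploid_contaminants=0, n_collapsed_repeat_regions=2,
            )
            ds = sd.simulate_dataset(cfg)
            layouts = [(l.chrom, l.start, l.end) for l in ds.gene_layouts]
            mask = flt.high_coverage_mask(ds.depth_profile, layouts)
            covered = 0
            total = 0
            for chrom, s, e in ds.truth.collapsed_repeats:
                total += e - s
                hit = np.zeros(e - s, dtype=bool)
                for _, row in mask.intervals.iterrows():
                    if row["chrom"] != chrom:
                        continue
                    lo, hi = max(row["start"], s), min(row["end"], e)
                    if hi > lo:
                        hit[lo - s:hi - s] = True
                covered += hit.sum()
            frac.append(covered / total)
        assert np.mean(frac) >= 0.9


class TestSiteFilters:
    def test_quality_boundary_is_strict(self):
        t = make_table(quals=(29.0, 30.0))
        out = flt.site_filters(t)
        assert list(out.sites["qual"]) == [30.0]

    def test_single_strand_support_dropped(self):
        t = make_table(fwd=(True, True), rev=(False, True))
        out = flt.site_filters(t)
        assert out.n_sites == 1 and bool(out.sites["has_rev"].iloc[0])

    def test_clean_table_passes_unchanged(self):
        t = make_table()
        out = flt.site_filters(t, masks=[])
        assert out.n_sites == t.n_sites
        assert (out.alleles == t.alleles).all()

    def test_non_snp_alleles_dropped(self):
        t = make_table(quals=(100.0, 100.0))
        t.sites.loc[0, "ref"] = "AT"
        out = flt.site_filters(t)
        assert out.n_sites == 1


class TestMaskAmbiguousCalls:
    @pytest.mark.parametrize(
        "ab, expect_missing",
        [(0.5, True), (0.25, True), (0.75, True), (0.0, False), (0.9, False)],
    )
    def test_allelic_balance_band_inclusive(self, ab, expect_missing):
        t = make_table(quals=(100.0,), fwd=(True,), rev=(True,),
                       ab=[[ab, 0.0]])
        out = flt.mask_ambiguous_calls(t)
        assert (out.alleles[0, 0] == MISSING) == expect_missing
        assert out.alleles[0, 1] == 0  # untouched neighbour call

    def test_depth_above_per_sample_cap_masked(self):
        t = make_table(quals=(100.0,), fwd=(True,), rev=(True,),
                       depth=[[50, 10]])
        out = flt.mask_ambiguous_calls(t, per_sample_cov_caps={"s0": 20.0, "s1": 20.0})
        assert out.alleles[0, 0] == MISSING and out.alleles[0, 1] == 0


class TestHaploidizePools:
    def test_seeded_choice_reproducible_and_homozygous_unchanged(self):
        ab = [[0.5, 0.0], [0.0, 0.0]]
        alleles = [[1, 0], [1, 1]]
        t1 = make_table(alleles=alleles, ab=ab)
        out1 = flt.haploidize_pools(t1, ["s0"], np.random.default_rng(5))
        out2 = flt.haploidize_pools(t1, ["s0"], np.random.default_rng(5))
        assert (out1.alleles == out2.alleles).all()
        assert out1.alleles[1, 0] == 1  # homozygous-like call untouched
        assert out1.alleles[0, 1] == 0  # non-pool sample untouched

    def test_non_pool_sample_rejected_when_flags_given(self):
        t = make_table()
        with pytest.raises(ValueError):
            flt.haploidize_pools(
                t, ["s0"], np.random.default_rng(0), pool_flags={"s0": False}
            )

    def test_reference_chosen_about_half_the_time(self):
        n = 10_000
        ab = np.full((n, 1), 0.5, dtype=np.float32)
        alleles = np.ones((n, 1), dtype=np.int16)
        t = make_table(
            quals=tuple([100.0] * n), fwd=tuple([True] * n), rev=tuple([True] * n),
            alleles=alleles, depth=np.full((n, 1), 10), ab=ab, n_samples=1,
        )
        out = flt.haploidize_pools(t, ["s0"], np.random.default_rng(8))
        frac_ref = (out.alleles[:, 0] == 0).mean()
        assert abs(frac_ref - 0.5) < 0.02


class TestFlagBadSamples:
    def test_missingness_boundary(self):
        alleles = np.zeros((100, 2), dtype=np.int16)
        alleles[:26, 0] = MISSING  # 26% missing -> dropped
        t = make_table(
            quals=tuple([100.0] * 100), fwd=tuple([True] * 100),
            rev=tuple([True] * 100), alleles=alleles,
        )
        kept, dropped, flagged = flt.flag_bad_samples(t)
        assert dropped == ["s0"] and kept.samples == ["s1"]

    def test_planted_diploids_flagged_across_seeds(self):
        from sbkit import simdata as sd
        from sbkit import filtering

        hits, total = 0, 0
        for seed in range(8):
            cfg = sd.preset_introgression(
                seed=seed, n_genes=10, n_supergene=3,
                n_diploid_contaminants=2, n_collapsed_repeat_regions=0,
            )
            ds = sd.simulate_dataset(cfg)
            import pathlib, tempfile

            with tempfile.TemporaryDirectory() as td:
                p = pathlib.Path(td) / "g.vcf"
                p.write_text(ds.vcf_text)
                tab = read_vcf(p)
            het = filtering.heterozygous_fractions(tab)
            _, dropped, flagged = filtering.flag_bad_samples(tab, het_fractions=het)
            for name in ds.truth.contaminants:
                total += 1
                hits += name in flagged
        assert hits / total >= 0.95


class TestSiteCallRate:
    def test_exactly_75_percent_dropped(self):
        alleles = np.zeros((2, 4), dtype=np.int16)
        alleles[0, 0] = MISSING  # site 0 genotyped in exactly 75%
        t = make_table(quals=(100.0, 100.0), n_samples=4, alleles=alleles)
        out = flt.site_call_rate_filter(t)
        assert list(out.sites["pos"]) == [20]

    def test_retained_counts_match_brute_force(self, rng):
        n_sites, n_samples = 100, 8
        alleles = np.zeros((n_sites, n_samples), dtype=np.int16)
        miss = rng.random((n_sites, n_samples)) < 0.3
        alleles[miss] = MISSING
        t = make_table(
            quals=tuple([100.0] * n_sites), fwd=tuple([True] * n_sites),
            rev=tuple([True] * n_sites), alleles=alleles, n_samples=n_samples,
        )
        out = flt.site_call_rate_filter(t)
        brute = sum(
            1 for i in range(n_sites)
            if sum(alleles[i, j] != MISSING for j in range(n_samples)) / n_samples > 0.75
        )
        assert out.n_sites == brute


class TestCascadeProperties:
    def test_cascade_idempotent_and_conservative(self, small_dataset, small_dataset_dir):
        ds = small_dataset
        tab = read_vcf(small_dataset_dir / "genotypes.vcf")
        sc = [(l.chrom, l.start, l.end) for l in ds.gene_layouts]
        res1 = flt.apply_filter_cascade(tab, ds.depth_profile, sc)
        res2 = flt.apply_filter_cascade(res1.table, ds.depth_profile, sc)
        assert res2.table.n_sites == res1.table.n_sites
        assert res2.table.samples == res1.table.samples
        assert (res2.table.alleles == res1.table.alleles).all()
        # conservation: kept + dropped + flagged = input samples
        assert (
            res1.table.n_samples
            + len(res1.dropped_samples)
            + len(res1.flagged_diploid)
            == tab.n_samples
        )

    def test_clean_dataset_masks_under_one_percent_of_calls(self):
        from sbkit import simdata as sd

        cfg = sd.preset_introgression(
            seed=5, n_genes=10, n_supergene=3,
            n_diploid_contaminants=0, n_collapsed_repeat_regions=0,
        )
        ds = sd.simulate_dataset(cfg)
        import pathlib, tempfile

        with tempfile.TemporaryDirectory() as td:
            p = pathlib.Path(td) / "g.vcf"
            p.write_text(ds.vcf_text)
            tab = read_vcf(p)
        sc = [(l.chrom, l.start, l.end) for l in ds.gene_layouts]
        caps = flt.per_sample_coverage_caps(tab, sc)
        called_before = tab.alleles != MISSING
        out = flt.mask_ambiguous_calls(tab, per_sample_cov_caps=caps)
        newly_masked = called_before & (out.alleles == MISSING)
        assert newly_masked.sum() / called_before.sum() < 0.01
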