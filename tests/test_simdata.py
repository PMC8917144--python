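"""Generative model checks: coalescent rates, class constraints, mutations,
artifact planting and determinism."""

import itertools

import numpy as np
import pytest
from scipy import stats

from sbkit import simdata as sd
from sbkit.seqs import N_CODE


def one_class_config(n_samples=2, pop_size=100.0, n_genes=1, L=100, mu=0.0, seed=0):
    st = sd.SpeciesTreeSpec("(A);", {}, pop_size=pop_size)
    return sd.SimConfig(
        st, sd.SupergeneSpec(1e12, None, ()), [], {"A": {"SB": n_samples}},
        n_genes=n_genes, gene_length_bp=L, mu=mu, seed=seed,
    )


class TestGenealogy:
    def test_pairwise_tmrca_matches_exponential_mean(self):
        # two lineages, one class, N=100 haploids -> E[TMRCA] = 2N = 200
        cfg = one_class_config()
        rng = np.random.default_rng(7)
        t = np.array([
            sd.simulate_genealogy(cfg, 0, rng).time[-1] for _ in range(5000)
        ])
        se = t.std() / np.sqrt(t.size)
        assert abs(t.mean() - 200.0) < 3 * se

    def test_trans_species_never_coalesces_sb_with_SB_below_origin(self):
        cfg = sd.preset_trans_species(n_genes=10, n_supergene=10)
        t_sb = cfg.supergene.origin_time_years
        rng = np.random.default_rng(3)
        for g in range(10):
            gen = sd.simulate_genealogy(cfg, g, rng)
            T = gen.tmrca_matrix()
            for i, j in itertools.combinations(range(gen.n_tips), 2):
                if {gen.variants[i], gen.variants[j]} == {"SB", "Sb"}:
                    assert T[i, j] >= t_sb

    def test_recent_introgression_coalesces_recipient_into_donor_pool(self):
        cfg = sd.preset_introgression(n_genes=10, n_supergene=10)
        cfg.events[0] = sd.IntrogressionEvent("inv", "rich", 0.0)
        t_sb = cfg.supergene.origin_time_years
        rng = np.random.default_rng(4)
        for g in range(10):
            gen = sd.simulate_genealogy(cfg, g, rng)
            T = gen.tmrca_matrix()
            rich_sb = [i for i in range(gen.n_tips)
                       if gen.species[i] == "rich" and gen.variants[i] == "Sb"]
            inv_sb = [i for i in range(gen.n_tips)
                      if gen.species[i] == "inv" and gen.variants[i] == "Sb"]
            assert T[np.ix_(rich_sb, inv_sb)].min() < t_sb

    def test_genealogies_ultrametric_with_positive_branches(self):
        cfg = sd.preset_introgression(n_genes=4, n_supergene=2)
        rng = np.random.default_rng(5)
        for g in range(4):
            gen = sd.simulate_genealogy(cfg, g, rng)
            bl = gen.branch_lengths()
            assert (bl[: gen.root] > 0).all()
            # tips at time zero, node times increase toward the root
            assert (gen.time[: gen.n_tips] == 0).all()
            assert (np.diff(gen.time[gen.n_tips:]) > 0).all()

    def test_orphan_sb_species_raises_naming_the_species(self):
        cfg = sd.preset_introgression()
        with pytest.raises(sd.ConfigurationError, match="meg"):
            sd.SimConfig(
                cfg.species_tree, cfg.supergene,
                [sd.IntrogressionEvent("inv", "rich", 0.75e6)],
                cfg.samples,  # meg carries Sb but has no event
            )

    def test_older_introgression_increases_recipient_donor_distance(self):
        means = []
        for age in (0.1e6, 0.4e6, 0.75e6):
            cfg = sd.preset_introgression(n_genes=10, n_supergene=10)
            cfg.events = [sd.IntrogressionEvent("inv", "rich", age),
                          sd.IntrogressionEvent("inv", "meg", 0.1e6)]
            rng = np.random.default_rng(11)
            vals = []
            for g in range(10):
                gen = sd.simulate_genealogy(cfg, g, rng)
                T = gen.tmrca_matrix()
                rich_sb = [i for i in range(gen.n_tips)
                           if gen.species[i] == "rich" and gen.variants[i] == "Sb"]
                inv_sb = [i for i in range(gen.n_tips)
                          if gen.species[i] == "inv" and gen.variants[i] == "Sb"]
                vals.append(T[np.ix_(rich_sb, inv_sb)].mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestMutations:
    def test_mu_zero_gives_identical_sequences(self):
        cfg = one_class_config(n_samples=4, mu=0.0)
        gen = sd.simulate_genealogy(cfg, 0, np.random.default_rng(0))
        aln, recs, anc = sd.drop_mutations(gen, 0.0, 100, np.random.default_rng(1))
        assert not recs
        assert (aln.seqs == anc[None, :]).all()

    def test_pairwise_differences_match_two_t_mu_L(self):
        # E[diffs] between two tips with TMRCA T is 2 T mu L
        mu, L = 1e-6, 500
        cfg = one_class_config(n_samples=2, pop_size=200.0, L=L, mu=mu)
        diffs, expect = [], []
        for rep in range(2000):
            rng = np.random.default_rng(rep)
            gen = sd.simulate_genealogy(cfg, 0, rng)
            aln, _, _ = sd.drop_mutations(gen, mu, L, rng)
            diffs.append((aln.seqs[0] != aln.seqs[1]).sum())
            expect.append(2 * gen.time[-1] * mu * L)
        d = np.asarray(diffs, dtype=float)
        se = d.std() / np.sqrt(d.size)
        assert abs(d.mean() - np.mean(expect)) < 3 * se

    def test_zero_length_gene_rejected(self):
        cfg = one_class_config()
        gen = sd.simulate_genealogy(cfg, 0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            sd.drop_mutations(gen, 1e-8, 0, np.random.default_rng(0))

    def test_site_records_biallelic_and_positions_distinct(self):
        cfg = one_class_config(n_samples=6, pop_size=5000.0, L=300, mu=1e-6)
        gen = sd.simulate_genealogy(cfg, 0, np.random.default_rng(2))
        _, recs, _ = sd.drop_mutations(gen, 1e-6, 300, np.random.default_rng(3))
        pos = [r.position for r in recs]
        assert len(pos) == len(set(pos))
        assert all(r.ancestral != r.derived for r in recs)
        assert pos == sorted(pos)


class TestSiteFrequencySpectrum:
    def test_neutral_sfs_not_rejected(self):
        # one species, one class: folded-free SFS ~ theta / i
        n = 6
        cfg = one_class_config(n_samples=n, pop_size=1000.0, L=200, mu=5e-7)
        counts = np.zeros(n - 1)
        for rep in range(2000):
            rng = np.random.default_rng(10_000 + rep)
            gen = sd.simulate_genealogy(cfg, 0, rng)
            _, recs, _ = sd.drop_mutations(gen, 5e-7, 200, rng)
            for r in recs:
                k = int(r.carriers.sum())
                if 0 < k < n:
                    counts[k - 1] += 1
        expected = (1.0 / np.arange(1, n)) / (1.0 / np.arange(1, n)).sum()
        chi2 = ((counts - counts.sum() * expected) ** 2 / (counts.sum() * expected)).sum()
        p = 1 - stats.chi2.cdf(chi2, df=n - 2)
        assert p > 0.01


class TestSimulatedDataset:
    def test_same_seed_byte_identical(self):
        cfg1 = sd.preset_introgression(seed=9, n_genes=6, n_supergene=2)
        cfg2 = sd.preset_introgression(seed=9, n_genes=6, n_supergene=2)
        d1, d2 = sd.simulate_dataset(cfg1), sd.simulate_dataset(cfg2)
        assert d1.vcf_text == d2.vcf_text
        assert d1.bed_text == d2.bed_text
        assert all(
            (a.seqs == b.seqs).all() for a, b in zip(d1.alignments, d2.alignments)
        )

    @pytest.mark.parametrize(
        "preset, expected",
        [
            (sd.preset_trans_species, "trans_species"),
            (sd.preset_independent_origins, "independent_origins"),
            (sd.preset_introgression, "introgression"),
        ],
    )
    def test_truth_scenario_matches_preset(self, preset, expected):
        cfg = preset(n_genes=4, n_supergene=2)
        assert cfg.scenario == expected
        ds = sd.simulate_dataset(cfg)
        assert ds.truth.scenario == expected

    def test_reference_conspecific_diploid_has_intermediate_balance(
        self, small_dataset, small_dataset_dir
    ):
        from sbkit.genotypes import read_vcf

        tab = read_vcf(small_dataset_dir / "genotypes.vcf")
        name = next(
            n for n, info in small_dataset.truth.contaminants.items()
            if info["species"] == "inv"
        )
        i = tab.samples.index(name)
        ab, al = tab.ab[:, i], tab.alleles[:, i]
        het = np.isfinite(ab) & (ab > 0.25) & (ab < 0.75)
        variant = (al > 0) | het
        assert het.sum() / variant.sum() >= 0.20

    def test_collapsed_repeats_triple_depth(self, small_dataset):
        ds = small_dataset
        chrom, s, e = ds.truth.collapsed_repeats[0]
        inside = ds.depth_profile[chrom][s:e].mean()
        outside = np.r_[ds.depth_profile[chrom][:s], ds.depth_profile[chrom][e:]].mean()
        assert inside > 2 * outside

    def test_inconsistent_sample_table_fails_before_output(self):
        cfg = sd.preset_introgression(n_genes=4, n_supergene=2)
        with pytest.raises(sd.ConfigurationError):
            sd.SimConfig(
                cfg.species_tree, cfg.supergene, cfg.events,
                {"nosuch": {"SB": 2}},
            )
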