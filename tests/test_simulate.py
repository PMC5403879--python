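"""Generator behavior: Balding-Nichols draws, ancestry mosaics, phenotypes."""

import numpy as np
import pytest

from stratsim import (
    MISSING,
    AdmixtureModel,
    AncestralModel,
    FstMixture,
    PhenotypeModel,
    child_rng,
    draw_population_freqs,
    fst_for_dataset,
    multilocus_fst,
    simulate_genotypes,
    simulate_local_ancestry,
    simulate_phenotype,
    simulate_tagged_snps,
)


def _pair_at_fixed_f(f_value, num_snps=5000, seed=3, **kw):
    model = AncestralModel(num_snps=num_snps, seed=seed,
                           fst_sampler=lambda rng, size: np.full(size, f_value), **kw)
    return draw_population_freqs(model)


class TestDrawPopulationFreqs:
    def test_zero_divergence_copies_ancestral_freq(self):
        model = AncestralModel(
            num_snps=50, seed=1,
            ancestral_freq_sampler=lambda rng, size: np.full(size, 0.3),
            fst_sampler=lambda rng, size: np.zeros(size))
        pair = draw_population_freqs(model)
        assert np.all(pair.freq_pop1 == 0.3)
        assert np.all(pair.freq_pop2 == 0.3)

    def test_balding_nichols_moments(self):
        # var of drawn frequencies = F * p * (1-p) = 0.5 * 0.25 = 0.125
        model = AncestralModel(
            num_snps=40_000, seed=2,
            ancestral_freq_sampler=lambda rng, size: np.full(size, 0.5),
            fst_sampler=lambda rng, size: np.full(size, 0.5))
        pair = draw_population_freqs(model)
        draws = np.concatenate([pair.freq_pop1, pair.freq_pop2])
        assert abs(draws.mean() - 0.5) < 0.01
        assert abs(draws.var() - 0.125) < 0.005

    def test_default_mixture_matches_divergence_profile(self):
        # calibration target: ~17% of estimates > 0.25 and ~3% > 0.5
        # at the 112/147 two-population design
        model = AncestralModel(num_snps=30_000, seed=4)
        pair = draw_population_freqs(model)
        labels = np.array(["pop1"] * 112 + ["pop2"] * 147)
        ds = simulate_genotypes(pair, labels, 0.0, seed=4)
        est = fst_for_dataset(ds).fst
        est = est[np.isfinite(est)]
        assert abs(np.mean(est > 0.25) - 0.17) < 0.02
        assert abs(np.mean(est > 0.50) - 0.03) < 0.01

    def test_degenerate_freq_sampler_rejected(self):
        model = AncestralModel(
            num_snps=10, seed=1,
            ancestral_freq_sampler=lambda rng, size: np.zeros(size))
        with pytest.raises(ValueError, match="outside"):
            draw_population_freqs(model)

    def test_seed_determinism(self):
        a = draw_population_freqs(AncestralModel(num_snps=100, seed=9))
        b = draw_population_freqs(AncestralModel(num_snps=100, seed=9))
        assert np.array_equal(a.freq_pop1, b.freq_pop1)
        assert np.array_equal(a.snp_pos_morgan, b.snp_pos_morgan)


class TestBaldingNicholsRecovery:
    @pytest.mark.parametrize("f_true", [0.1, 0.5])
    def test_multilocus_estimate_recovers_f(self, f_true):
        pair = _pair_at_fixed_f(f_true, num_snps=20_000)
        labels = np.array(["pop1"] * 112 + ["pop2"] * 147)
        ds = simulate_genotypes(pair, labels, 0.0, seed=3)
        est = multilocus_fst(fst_for_dataset(ds))
        assert abs(est - f_true) < 0.02


class TestLocalAncestry:
    def test_theta_one_gives_all_population_two(self, small_pair):
        adm = AdmixtureModel()
        tracks = simulate_local_ancestry(adm, small_pair, 3, seed=5,
                                         thetas=np.array([1.0, 1.0, 1.0]))
        for i in range(3):
            for c in range(len(small_pair.chrom_lengths)):
                for copy in range(2):
                    _, sources = tracks.segments[i][c][copy]
                    assert np.all(sources == 2)

    def test_switch_count_matches_poisson_rate(self, small_pair):
        adm = AdmixtureModel(generations=6)
        tracks = simulate_local_ancestry(adm, small_pair, 200, seed=6)
        counts = [len(tracks.segments[i][c][copy][0])
                  for i in range(200)
                  for c in range(len(small_pair.chrom_lengths))
                  for copy in range(2)]
        expected = 6 * small_pair.chrom_lengths[0]
        assert abs(np.mean(counts) - expected) < 0.3

    def test_segments_tile_chromosome(self, small_pair):
        adm = AdmixtureModel()
        tracks = simulate_local_ancestry(adm, small_pair, 5, seed=7)
        length = small_pair.chrom_lengths[0]
        for i in range(5):
            breaks, sources = tracks.segments[i][0][0]
            assert sources.size == breaks.size + 1
            assert np.all(np.diff(breaks) >= 0)
            assert np.all((breaks >= 0) & (breaks <= length))
            assert np.all(np.isin(sources, [1, 2]))

    def test_stationary_source_probability_is_theta(self, small_pair):
        adm = AdmixtureModel()
        theta = 0.7
        tracks = simulate_local_ancestry(adm, small_pair, 400, seed=8,
                                         thetas=np.full(400, theta))
        pos = np.linspace(0.1, small_pair.chrom_lengths[0] - 0.1, 5)
        fracs = [np.mean(tracks.sources_at(i, 0, 0, pos) == 2) for i in range(400)]
        assert abs(np.mean(fracs) - theta) < 0.03


class TestSimulateGenotypes:
    def test_fixed_allele_gives_all_homozygotes(self):
        model = AncestralModel(
            num_snps=20, seed=1,
            ancestral_freq_sampler=lambda rng, size: np.full(size, 0.5),
            fst_sampler=lambda rng, size: np.zeros(size))
        pair = draw_population_freqs(model)
        pair.freq_pop1[:] = 1.0
        pair.freq_pop2[:] = 1.0
        ds = simulate_genotypes(pair, ["pop1", "pop2"], 0.0, seed=1)
        assert np.all(ds.genotypes == 2)

    def test_sample_frequency_matches_population_frequency(self, small_pair):
        labels = np.repeat("pop2", 147)
        ds = simulate_genotypes(small_pair, labels, 0.0, seed=2)
        freq = ds.genotypes.mean(axis=0) / 2.0
        # binomial sd per SNP ~ sqrt(p(1-p)/(2*147)) <= 0.03
        assert np.mean(np.abs(freq - small_pair.freq_pop2)) < 0.03

    def test_missing_rate_zero_and_bounds(self, small_pair, small_labels):
        ds = simulate_genotypes(small_pair, small_labels, 0.0, seed=3)
        assert not np.any(ds.genotypes == MISSING)
        with pytest.raises(ValueError, match="missing_rate"):
            simulate_genotypes(small_pair, small_labels, 1.5, seed=3)

    def test_missing_rate_applied(self, small_pair, small_labels):
        ds = simulate_genotypes(small_pair, small_labels, 0.1, seed=3)
        frac = np.mean(ds.genotypes == MISSING)
        assert 0.07 < frac < 0.13

    def test_bit_identical_under_same_seed(self, small_pair, small_labels):
        a = simulate_genotypes(small_pair, small_labels, 0.05, seed=11)
        b = simulate_genotypes(small_pair, small_labels, 0.05, seed=11)
        assert np.array_equal(a.genotypes, b.genotypes)

    def test_admixture_ld_exceeds_distinct_design(self, small_pair):
        """Shared ancestry fractions correlate even unlinked high-F SNPs."""
        adm = AdmixtureModel()
        tracks = simulate_local_ancestry(adm, small_pair, 150, seed=12)
        ds_adm = simulate_genotypes(small_pair, tracks, 0.0, seed=12)
        # pair the most-diverged polymorphic SNPs across chromosomes
        poly = (ds_adm.genotypes.astype(float).var(axis=0) > 0.05)
        fst_rank = np.where(poly, small_pair.true_fst, -1.0)
        order = np.argsort(fst_rank)[::-1][:20]
        chrom = small_pair.snp_chrom[order]
        pairs = [(int(a), int(b))
                 for i, a in enumerate(order) for j, b in enumerate(order)
                 if i < j and chrom[i] != chrom[j]]

        def mean_abs_corr(ds):
            g = ds.genotypes.astype(float)
            vals = [abs(np.corrcoef(g[:, a], g[:, b])[0, 1])
                    for a, b in pairs[:30]
                    if g[:, a].var() > 0 and g[:, b].var() > 0]
            return np.mean(vals)

        labels = np.repeat("pop1", 150)
        ds_one = simulate_genotypes(small_pair, labels, 0.0, seed=12)
        assert mean_abs_corr(ds_adm) > mean_abs_corr(ds_one)


class TestSimulatePhenotype:
    def test_group_means_and_sds(self, small_pair):
        labels = np.array(["pop1"] * 300 + ["pop2"] * 300)
        ds = simulate_genotypes(small_pair, labels, 0.0, seed=4)
        y = simulate_phenotype(ds, PhenotypeModel(divergence_delta=3.0), seed=4)
        g1, g2 = y[:300], y[300:]
        assert abs((g2.mean() - g1.mean()) - 3.0) < 0.25
        assert abs(g1.std() - 1.0) < 0.15
        assert abs(g2.std() - 1.0) < 0.15

    def test_causal_effect_slope(self, small_pair):
        labels = np.repeat("pop1", 800)
        ds = simulate_genotypes(small_pair, labels, 0.0, seed=5)
        model = PhenotypeModel(divergence_delta=0.0, causal_snp=0, snp_effect=0.2)
        y = simulate_phenotype(ds, model, seed=5)
        g = ds.genotypes[:, 0].astype(float)
        slope = np.polyfit(g, y, 1)[0]
        assert abs(slope - 0.2) < 0.15

    def test_pure_noise_has_no_slope(self, small_dataset):
        y = simulate_phenotype(small_dataset, PhenotypeModel(), seed=6)
        g = small_dataset.genotypes[:, 3].astype(float)
        slope = np.polyfit(g, y, 1)[0]
        assert abs(slope) < 0.5

    def test_causal_index_out_of_range(self, small_dataset):
        with pytest.raises(IndexError):
            simulate_phenotype(small_dataset,
                               PhenotypeModel(causal_snp=10**6), seed=1)


class TestTaggedSnps:
    def test_allelic_correlation_tracks_tag_probability(self):
        probs = np.array([0.0, 0.5, 1.0])
        ds = simulate_tagged_snps(4000, 3, probs, 0.5, seed=1)
        g = ds.genotypes.astype(float)
        r = [np.corrcoef(g[:, 0], g[:, k + 1])[0, 1] for k in range(3)]
        assert abs(r[0]) < 0.05
        assert abs(r[1] - 0.5) < 0.05
        assert r[2] == pytest.approx(1.0)
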