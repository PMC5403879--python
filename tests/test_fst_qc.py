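"""Weir-Cockerham estimator against an independent oracle; staged QC."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as stst

from stratsim import (
    MISSING,
    EmptyDatasetError,
    GenotypeDataset,
    QcThresholds,
    apply_qc,
    fst_for_dataset,
    stratify_by_fst,
    weir_cockerham_fst,
)


def wc_oracle(n1, n2, p1, p2):
    """Literal transcription of the two-population unbiased estimator,
    in exact rational arithmetic, independent of the implementation."""
    n1, n2, p1, p2 = (Fraction(x) for x in (n1, n2, p1, p2))
    tot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / tot
    n_c = tot - (n1 * n1 + n2 * n2) / tot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 - 1 + n2 - 1)
    denom = msp + (n_c - 1) * msg
    if denom == 0:
        return None
    return float((msp - msg) / denom)


def _dataset(genotypes, populations):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    snp_meta = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "chrom": 1, "pos_morgan": np.linspace(0, 1, m),
        "pos_bp": np.arange(m), "true_fst": 0.0,
    })
    sample_meta = pd.DataFrame({
        "sample_id": [f"i{i}" for i in range(n)],
        "population": populations,
        "theta": (np.asarray(populations) == "pop2").astype(float),
    })
    return GenotypeDataset(genotypes, snp_meta, sample_meta)


class TestWeirCockerham:
    def test_complete_fixation_is_exactly_one(self):
        fst, msp, msg, n_c, defined = weir_cockerham_fst(200, 200, 0.0, 1.0)
        assert msg == 0.0
        assert fst == 1.0
        assert defined

    def test_null_divergence_equals_minus_one_over_nc_minus_one(self):
        fst, _, _, n_c, _ = weir_cockerham_fst(200, 200, 0.5, 0.5)
        assert n_c == 200.0
        assert fst == pytest.approx(-1.0 / 199.0, abs=1e-15)

    def test_hand_derived_unequal_sample_case(self):
        # 112/147 alleles at frequencies 0.2/0.8: frozen from the exact
        # rational evaluation of the estimator
        fst, *_ = weir_cockerham_fst(112, 147, 0.2, 0.8)
        assert fst == pytest.approx(0.5257172910120963, abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            weir_cockerham_fst(1, 100, 0.5, 0.5)

    @settings(max_examples=300, derandomize=True)
    @given(
        n1=stst.integers(2, 500), n2=stst.integers(2, 500),
        k1=stst.integers(0, 1000), k2=stst.integers(0, 1000),
    )
    def test_matches_independent_oracle(self, n1, n2, k1, k2):
        p1, p2 = Fraction(k1, 1000), Fraction(k2, 1000)
        expected = wc_oracle(n1, n2, p1, p2)
        fst, *_, defined = weir_cockerham_fst(n1, n2, float(p1), float(p2))
        if expected is None:
            assert not defined
        elif defined:
            assert fst == pytest.approx(expected, abs=1e-9)

    def test_defined_estimates_never_exceed_one(self):
        rng = np.random.default_rng(0)
        f, *_, d = weir_cockerham_fst(
            rng.integers(2, 300, 500), rng.integers(2, 300, 500),
            rng.random(500), rng.random(500))
        assert np.all(f[d] <= 1.0 + 1e-12)


class TestFstForDataset:
    def test_monomorphic_snp_is_undefined(self):
        geno = np.zeros((8, 2), dtype=np.int8)
        geno[:, 1] = [0, 1, 2, 1, 0, 2, 1, 1]
        ds = _dataset(geno, ["pop1"] * 4 + ["pop2"] * 4)
        tab = fst_for_dataset(ds)
        assert not tab.defined[0]
        assert tab.defined[1]

    def test_duplicated_population_scatters_around_null_value(self, small_dataset):
        g = small_dataset.genotypes[small_dataset.sample_meta.population == "pop1"]
        dup = np.vstack([g, g])
        ds = _dataset(dup, ["pop1"] * g.shape[0] + ["pop2"] * g.shape[0])
        tab = fst_for_dataset(ds)
        n_c = tab.table["n_c"].to_numpy()[tab.defined]
        null_value = -1.0 / (n_c - 1.0)
        est = tab.fst[tab.defined]
        # copies are identical, so MSP = 0 exactly and each defined SNP
        # sits exactly at the null value
        assert np.allclose(est, null_value, atol=1e-12)

    def test_requires_two_groups(self, small_pair):
        from stratsim import simulate_genotypes
        ds = simulate_genotypes(small_pair, np.repeat("pop1", 10), 0.0, seed=1)
        with pytest.raises(ValueError, match="two groups"):
            fst_for_dataset(ds)

    def test_missing_genotypes_change_allele_counts(self, small_dataset):
        ds = small_dataset.subset(snps=np.arange(5))
        g = ds.genotypes.copy()
        g[0:3, 0] = MISSING
        ds2 = GenotypeDataset(g, ds.snp_meta, ds.sample_meta)
        full = fst_for_dataset(ds).table
        part = fst_for_dataset(ds2).table
        assert part["n_c"][0] < full["n_c"][0]


class TestStratify:
    def test_cumulative_exceedance_counts(self):
        table = pd.DataFrame({
            "snp_id": list("abc"), "chrom": 1, "pos_bp": [1, 2, 3],
            "fst": [0.1, 0.3, 0.6], "msp": 1.0, "msg": 1.0, "n_c": 10.0,
            "defined": True,
        })
        from stratsim.fst import FstTable
        masks = stratify_by_fst(FstTable(table))
        assert masks["all"].sum() == 3
        assert masks[">0.25"].sum() == 2
        assert masks[">0.5"].sum() == 1

    def test_undefined_snps_in_no_stratum(self):
        table = pd.DataFrame({
            "snp_id": list("ab"), "chrom": 1, "pos_bp": [1, 2],
            "fst": [np.nan, 0.9], "msp": 0.0, "msg": 0.0, "n_c": 10.0,
            "defined": [False, True],
        })
        from stratsim.fst import FstTable
        masks = stratify_by_fst(FstTable(table))
        for mask in masks.values():
            assert not mask[0]

    def test_empty_threshold_list_gives_single_stratum(self):
        table = pd.DataFrame({
            "snp_id": ["a"], "chrom": 1, "pos_bp": [1],
            "fst": [0.2], "msp": 1.0, "msg": 1.0, "n_c": 5.0, "defined": True,
        })
        from stratsim.fst import FstTable
        assert list(stratify_by_fst(FstTable(table), [])) == ["all"]


class TestApplyQc:
    def test_clean_data_untouched(self, small_dataset):
        ds, report = apply_qc(small_dataset)
        assert ds.n_snps <= small_dataset.n_snps
        assert report.snps_removed_stage1 == 0
        assert report.individuals_removed == 0

    def test_high_missingness_snp_removed_at_stage1(self, small_dataset):
        g = small_dataset.genotypes.copy()
        g[: int(0.25 * g.shape[0]) + 1, 0] = MISSING
        ds = GenotypeDataset(g, small_dataset.snp_meta, small_dataset.sample_meta)
        _, report = apply_qc(ds)
        assert report.snps_removed_stage1 == 1

    def test_rare_variant_removed_at_maf_stage(self):
        rng = np.random.default_rng(1)
        geno = rng.integers(0, 3, size=(120, 3)).astype(np.int8)
        geno[:, 0] = 0
        geno[0, 0] = 1  # MAF = 1/240 < 0.01
        ds = _dataset(geno, ["pop1"] * 60 + ["pop2"] * 60)
        _, report = apply_qc(ds)
        assert report.snps_removed_maf == 1

    def test_idempotent(self, small_dataset):
        once, _ = apply_qc(small_dataset)
        twice, report = apply_qc(once)
        assert twice.n_snps == once.n_snps
        assert twice.n_samples == once.n_samples
        assert np.array_equal(twice.genotypes, once.genotypes)

    @pytest.mark.parametrize("maf_lo,maf_hi", [(0.01, 0.05), (0.05, 0.2)])
    def test_raising_maf_threshold_never_keeps_more_snps(
            self, small_dataset, maf_lo, maf_hi):
        lo, _ = apply_qc(small_dataset, QcThresholds(maf_min=maf_lo))
        hi, _ = apply_qc(small_dataset, QcThresholds(maf_min=maf_hi))
        assert hi.n_snps <= lo.n_snps

    def test_all_snps_removed_raises(self):
        geno = np.full((10, 3), MISSING, dtype=np.int8)
        ds = _dataset(geno, ["pop1"] * 5 + ["pop2"] * 5)
        with pytest.raises(EmptyDatasetError):
            apply_qc(ds)
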