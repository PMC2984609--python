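"""Synthetic cohort generator: HWE structure, families, additive lifespans."""

import numpy as np
import pandas as pd
import pytest

import gendose as g
from gendose.errors import ConfigError


def _hwe_config(n=10000, n_snps=200, maf=0.3, seed=1):
    return g.unrelated_config(
        n_individuals=n, n_snps=n_snps, n_causal=0, maf_range=(maf, maf),
        call_rate_range=(1.0, 1.0), target_heritability=0.0, random_seed=seed)


class TestGenotypes:
    def test_hwe_genotype_proportions(self):
        """Founder genotypes follow HWE proportions (p=0.3 -> 0.49/0.42/0.09)."""
        cfg = _hwe_config()
        m = g.simulate_genotypes(cfg)
        d = m.dosages
        n = cfg.n_individuals
        expected = np.array([0.49, 0.42, 0.09])
        counts = np.stack([(d == k).sum(axis=0) for k in (0, 1, 2)])  # 3 x n_snps
        se = np.sqrt(expected * (1 - expected) * n)[:, None]
        z = np.abs(counts - expected[:, None] * n) / se
        # mean frequencies match tightly; individual SNPs within 4 SE nearly always
        assert np.allclose(counts.mean(axis=1) / n, expected, atol=0.01)
        assert (z < 4).mean() >= 0.99

    def test_full_call_rate_means_no_missing(self):
        m = g.simulate_genotypes(_hwe_config(n=200, n_snps=50))
        assert not np.isnan(m.dosages).any()

    def test_missingness_rate_matches_call_rate(self):
        cfg = g.unrelated_config(n_individuals=2000, n_snps=100, n_causal=0,
                                 call_rate_range=(0.8, 0.8),
                                 target_heritability=0.0, random_seed=3)
        m = g.simulate_genotypes(cfg)
        observed_cr = 1 - np.isnan(m.dosages).mean()
        assert observed_cr == pytest.approx(0.8, abs=0.01)

    def test_same_seed_bit_identical_different_seed_differs(self):
        cfg = _hwe_config(n=100, n_snps=40, seed=5)
        a = g.simulate_genotypes(cfg)
        b = g.simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        c = g.simulate_genotypes(_hwe_config(n=100, n_snps=40, seed=6))
        assert not np.array_equal(a.dosages, c.dosages)

    def test_sibling_dosage_correlation_is_half(self):
        cfg = g.SimulationConfig(
            n_individuals=1000, n_snps=400, n_causal=0, n_families=500,
            n_singletons=0, family_size_distribution={2: 1.0},
            call_rate_range=(1.0, 1.0), maf_range=(0.2, 0.5),
            target_heritability=0.0, random_seed=7)
        fam = g.assign_families(cfg)
        m = g.simulate_genotypes(cfg, families=fam)
        order = fam.sort_values(["family_id", "individual_id"])
        rows = m.individual_indexer(order["individual_id"])
        sib1 = m.dosages[rows[0::2]].astype(float)
        sib2 = m.dosages[rows[1::2]].astype(float)
        corrs = [np.corrcoef(sib1[:, j], sib2[:, j])[0, 1] for j in range(m.n_snps)]
        assert np.nanmean(corrs) == pytest.approx(0.5, abs=0.05)


class TestFamilies:
    def test_study_design_counts(self):
        """618 families plus 162 singletons covering 1,173 individuals."""
        cfg = g.SimulationConfig(n_individuals=1173, n_snps=10, n_causal=0,
                                 n_families=618, n_singletons=162,
                                 target_heritability=0.0, random_seed=1)
        fam = g.assign_families(cfg)
        assert len(fam) == 1173
        assert fam["family_id"].isna().sum() == 162
        assert fam["family_id"].nunique() == 618
        sizes = fam["family_id"].value_counts()
        assert sizes.sum() == 1173 - 162
        assert (sizes >= 1).all()

    def test_no_families_all_singletons(self):
        cfg = g.unrelated_config(n_individuals=20, n_snps=5, n_causal=0,
                                 target_heritability=0.0, random_seed=2)
        fam = g.assign_families(cfg)
        assert fam["family_id"].isna().all()

    def test_assignment_reproducible_under_seed(self):
        cfg = g.SimulationConfig(n_individuals=100, n_snps=5, n_causal=0,
                                 n_families=30, n_singletons=10,
                                 target_heritability=0.0, random_seed=9)
        pd.testing.assert_frame_equal(g.assign_families(cfg), g.assign_families(cfg))

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(n_individuals=10, n_families=0, n_singletons=5), "n_singletons"),
        (dict(n_individuals=10, n_families=20, n_singletons=0), "n_families"),
        (dict(maf_range=(0.0, 0.5)), "maf_range"),
        (dict(target_heritability=1.0), "target_heritability"),
        (dict(n_causal=5, n_snps=3), "n_causal"),
        (dict(target_heritability=0.2, n_causal=0), "unattainable"),
    ])
    def test_invalid_config_names_field(self, kwargs, msg):
        base = dict(n_individuals=10, n_snps=10, n_causal=2,
                    n_families=3, n_singletons=4,
                    family_size_distribution={2: 1.0}, random_seed=0)
        base.update(kwargs)
        with pytest.raises(ConfigError, match=msg):
            g.SimulationConfig(**base).validate()


class TestLifespans:
    def test_null_model_variance(self):
        """No effects: lifespan variance equals the residual variance."""
        cfg = g.unrelated_config(n_individuals=4000, n_snps=20, n_causal=0,
                                 target_heritability=0.0, lifespan_sd=10.0,
                                 random_seed=21)
        m = g.simulate_genotypes(cfg)
        pheno, truth = g.simulate_lifespans(m, cfg)
        assert truth.realized_heritability == 0.0
        assert pheno["lifespan_years"].std() == pytest.approx(10.0, rel=0.05)

    def test_deterministic_additive_case(self):
        """One causal SNP, beta=5, no noise: lifespans are baseline + 5*g."""
        m = g.GenotypeMatrix(dosages=np.array([[0.0], [1.0], [2.0]]),
                             individual_ids=["a", "b", "c"], snp_ids=["s1"])
        cfg = g.unrelated_config(n_individuals=3, n_snps=1, n_causal=1,
                                 baseline_lifespan=70.0, random_seed=0)
        pheno, truth = g.simulate_lifespans(
            m, cfg, causal_snp_ids=["s1"], effects=[5.0], noise_sd=0.0)
        np.testing.assert_allclose(pheno["lifespan_years"], [70.0, 75.0, 80.0])
        np.testing.assert_allclose(truth.effects, [5.0])

    def test_heritability_calibration(self):
        """Realized genetic variance share lands on the 0.25 target at n=5000."""
        cfg = g.unrelated_config(n_individuals=5000, n_snps=300, n_causal=100,
                                 target_heritability=0.25, random_seed=23)
        cohort = g.simulate_cohort(cfg)
        assert cohort.realized_heritability == pytest.approx(0.25, abs=0.05)

    def test_causal_truth_consistency(self, small_cohort):
        c = small_cohort
        assert len(c.causal_snp_ids) == len(set(c.causal_snp_ids)) == 30
        assert set(c.causal_snp_ids) <= set(c.genotypes.snp_ids)
        assert (c.truth.effects > 0).all()
        assert 0 <= c.realized_heritability <= 1

    def test_missing_causal_genotypes_still_give_phenotypes(self):
        cfg = g.unrelated_config(n_individuals=300, n_snps=50, n_causal=20,
                                 call_rate_range=(0.5, 0.7),
                                 target_heritability=0.4, random_seed=29)
        cohort = g.simulate_cohort(cfg)
        assert cohort.phenotypes["lifespan_years"].notna().all()
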