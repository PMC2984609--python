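"""Genetic dose scoring and the dose-response regression."""

import numpy as np
import pandas as pd
import pytest

import gendose as g
from gendose.errors import ValidationError

nan = np.nan


def _matrix(rows, snp_ids):
    return g.GenotypeMatrix(
        dosages=np.array(rows, dtype=float), snp_ids=snp_ids,
        individual_ids=[f"i{k}" for k in range(len(rows))])


class TestGeneticDose:
    def test_dosage_and_carrier_counting(self):
        m = _matrix([[0, 1, 2, 2]], ["a", "b", "c", "d"])
        assert g.genetic_dose(m, ["a", "b", "c", "d"], "dosage")["dose"][0] == 5
        assert g.genetic_dose(m, ["a", "b", "c", "d"], "carrier")["dose"][0] == 3

    def test_empty_panel_gives_zero(self):
        m = _matrix([[1, 2], [0, 1]], ["a", "b"])
        assert (g.genetic_dose(m, [])["dose"] == 0).all()

    def test_missing_contributes_zero_and_is_tallied(self):
        m = _matrix([[0, nan, 2]], ["a", "b", "c"])
        d = g.genetic_dose(m, ["a", "b", "c"])
        assert d.loc[0, "dose"] == 2
        assert d.loc[0, "n_missing"] == 1
        assert d.loc[0, "n_snps_used"] == 2

    def test_mean_imputation_option(self):
        m = _matrix([[2.0], [0.0], [nan], [0.0]], ["a"])
        d = g.genetic_dose(m, ["a"], impute_mean=True)
        assert d.loc[2, "dose"] == pytest.approx(2 / 3)

    def test_absent_panel_snp_named_in_error(self):
        m = _matrix([[0, 1]], ["a", "b"])
        with pytest.raises(ValidationError, match="zzz"):
            g.genetic_dose(m, ["a", "zzz"])

    def test_additive_over_panel_partition(self, small_cohort, rng):
        snps = list(small_cohort.genotypes.snp_ids[:40])
        cut = 17
        full = g.genetic_dose(small_cohort.genotypes, snps)["dose"]
        left = g.genetic_dose(small_cohort.genotypes, snps[:cut])["dose"]
        right = g.genetic_dose(small_cohort.genotypes, snps[cut:])["dose"]
        np.testing.assert_allclose(full, left + right)


def _pheno(ids, y):
    return g.make_phenotype_table(ids, y)


class TestFitDoseResponse:
    def test_group_means_on_a_line(self):
        """Group means exactly at 60 + 0.5*dose, arbitrary sizes -> exact fit."""
        doses, ys = [], []
        for dose, size in ((0, 7), (1, 3), (2, 11), (5, 2)):
            target = 60 + 0.5 * dose
            vals = target + np.linspace(-1, 1, size)
            vals = vals - vals.mean() + target  # group mean exactly on the line
            doses.extend([dose] * size)
            ys.extend(vals)
        ids = [f"i{k}" for k in range(len(doses))]
        dose_df = pd.DataFrame({"individual_id": ids, "dose": doses})
        fit = g.fit_dose_response(dose_df, _pheno(ids, ys), method="grouped_wls")
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(60.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert list(fit.group_table["n"]) == [7, 3, 11, 2]

    def test_grouped_wls_reproduces_individual_ols(self, rng):
        """Size-weighted WLS on dose-group means is algebraically OLS."""
        x = rng.integers(0, 12, 500).astype(float)
        y = 65 + 0.4 * x + rng.normal(0, 8, 500)
        ids = [f"i{k}" for k in range(500)]
        dose_df = pd.DataFrame({"individual_id": ids, "dose": x})
        ols = g.fit_dose_response(dose_df, _pheno(ids, y), "individual_ols")
        wls = g.fit_dose_response(dose_df, _pheno(ids, y), "grouped_wls")
        assert wls.slope == pytest.approx(ols.slope, rel=1e-8)
        assert wls.intercept == pytest.approx(ols.intercept, rel=1e-8)

    def test_fewer_than_three_distinct_doses_rejected(self):
        ids = ["a", "b", "c", "d"]
        dose_df = pd.DataFrame({"individual_id": ids, "dose": [0, 0, 1, 1]})
        with pytest.raises(ValidationError):
            g.fit_dose_response(dose_df, _pheno(ids, [70, 71, 72, 73]))

    def test_null_panel_ci_covers_zero(self, rng):
        """A pre-fixed random panel on null phenotypes: 95% CI covers 0 in
        >= 90% of replicates."""
        x = rng.integers(0, 10, 300).astype(float)
        ids = [f"i{k}" for k in range(300)]
        dose_df = pd.DataFrame({"individual_id": ids, "dose": x})
        covered = 0
        for _ in range(100):
            y = rng.normal(70, 10, 300)
            fit = g.fit_dose_response(dose_df, _pheno(ids, y))
            lo, hi = fit.slope_ci()
            covered += lo <= 0 <= hi
        assert covered >= 90


class TestVarianceExplained:
    def test_perfect_linearity(self):
        ids = list("abcd")
        dose_df = pd.DataFrame({"individual_id": ids, "dose": [0.0, 1, 2, 3]})
        fit = g.fit_dose_response(dose_df, _pheno(ids, [60, 60.5, 61, 61.5]))
        assert g.variance_explained(fit) == pytest.approx(1.0)

    def test_rejects_grouped_fit(self, rng):
        ids = [f"i{k}" for k in range(50)]
        dose_df = pd.DataFrame({"individual_id": ids,
                                "dose": rng.integers(0, 5, 50).astype(float)})
        fit = g.fit_dose_response(dose_df, _pheno(ids, rng.normal(70, 5, 50)),
                                  "grouped_wls")
        with pytest.raises(ValidationError):
            g.variance_explained(fit)

    def test_affine_invariance_of_r_squared(self, small_cohort):
        c = small_cohort
        dose_df = g.genetic_dose(c.genotypes, list(c.causal_snp_ids))
        fit = g.fit_dose_response(dose_df, c.phenotypes)
        scaled = c.phenotypes.assign(
            lifespan_years=2.5 * c.phenotypes["lifespan_years"] + 7.0)
        fit2 = g.fit_dose_response(dose_df, scaled)
        assert fit2.r_squared == pytest.approx(fit.r_squared, rel=1e-9)

    def test_true_panel_recovers_heritability(self):
        """Causal-SNP allele count explains ~h2 of lifespan variance."""
        cfg = g.unrelated_config(
            n_individuals=2000, n_snps=400, n_causal=100,
            target_heritability=0.25, call_rate_range=(1.0, 1.0),
            random_seed=31)
        c = g.simulate_cohort(cfg)
        dose_df = g.genetic_dose(c.genotypes, list(c.causal_snp_ids))
        fit = g.fit_dose_response(dose_df, c.phenotypes)
        assert g.variance_explained(fit) == pytest.approx(0.25, abs=0.05)


class TestWinnersCurse:
    def test_in_sample_selection_inflates_then_vanishes_out_of_sample(self):
        """Panel selected in-sample on a null cohort shows a strongly positive
        in-sample slope; the same panel on a fresh null cohort does not."""
        kwargs = dict(n_individuals=800, n_snps=8000, n_causal=0,
                      target_heritability=0.0, call_rate_range=(1.0, 1.0))
        a = g.simulate_cohort(g.unrelated_config(random_seed=42, **kwargs))
        b = g.simulate_cohort(g.unrelated_config(random_seed=43, **kwargs))
        rule = g.SelectionRule(1e-3, "positive")
        panel = g.select_longevity_snps(g.scan_all(a.genotypes, a.phenotypes), rule)
        assert len(panel) > 0
        fit_in = g.fit_dose_response(
            g.genetic_dose(a.genotypes, panel), a.phenotypes)
        assert fit_in.slope > 0 and fit_in.slope_p < 0.01
        fit_out = g.fit_dose_response(
            g.genetic_dose(b.genotypes, panel), b.phenotypes)
        lo, hi = fit_out.slope_ci()
        assert lo <= 0 <= hi
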