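"""REML variance components: closed-form oracles, boundary behaviour,
likelihood-ratio calibration and Satterthwaite degrees of freedom."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from scipy import stats

from phenosel import VarianceComponentsREML, fit_lmm, lrt_random_effect
from phenosel.varcomp import DesignError


def one_way(n_geno, reps, s2g, s2e, rng, mu=10.0):
    g = rng.normal(0, np.sqrt(s2g), n_geno)
    rows = []
    for i in range(n_geno):
        for j in range(reps):
            rows.append({"genotype": f"L{i}",
                         "y": mu + g[i] + rng.normal(0, np.sqrt(s2e))})
    return pd.DataFrame(rows)


def crossed(n_geno, reps, s2g, s2gxe, s2e, rng, delta=0.0):
    g = rng.normal(0, np.sqrt(s2g), n_geno)
    gt = rng.normal(0, np.sqrt(s2gxe), (n_geno, 2))
    rows = []
    for i in range(n_geno):
        for k, tr in enumerate(("complex", "simple")):
            for j in range(reps):
                rows.append({"genotype": f"L{i}", "treatment": tr,
                             "y": 10.0 + g[i] + gt[i, k]
                             + (delta if tr == "complex" else 0.0)
                             + rng.normal(0, np.sqrt(s2e))})
    return pd.DataFrame(rows)


class TestREMLEstimates:
    def test_balanced_one_way_matches_anova_closed_form(self):
        rng = np.random.default_rng(1)
        df = one_way(15, 8, s2g=4.0, s2e=2.0, rng=rng)
        est = VarianceComponentsREML(treatment_col=None,
                                     include_gxe=False).fit(df, "y")
        # method-of-moments oracle on the balanced design
        r = 8
        gm = df.groupby("genotype")["y"].mean()
        msb = r * gm.var(ddof=1)
        msw = df.groupby("genotype")["y"].apply(
            lambda v: ((v - v.mean()) ** 2).sum()).sum() / (len(df) - 15)
        np.testing.assert_allclose(est.sigma2_g_, (msb - msw) / r, atol=1e-6)
        np.testing.assert_allclose(est.sigma2_e_, msw, atol=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        rng = np.random.default_rng(4)
        df = crossed(12, 5, s2g=3.0, s2gxe=0.0, s2e=1.5, rng=rng, delta=0.8)
        est = VarianceComponentsREML(include_gxe=False).fit(df, "y")
        md = smf.mixedlm("y ~ treatment", df, groups=df["genotype"]).fit(reml=True)
        np.testing.assert_allclose(est.sigma2_g_, float(md.cov_re.iloc[0, 0]),
                                   rtol=1e-3)
        np.testing.assert_allclose(est.sigma2_e_, float(md.scale), rtol=1e-3)
        ours = est.fixed_effects_["treatment[complex]"]
        theirs = float(md.params["treatment[T.simple]"])
        np.testing.assert_allclose(ours, -theirs, rtol=1e-4)

    def test_zero_variance_data_hits_boundary(self):
        rng = np.random.default_rng(2)
        df = crossed(10, 6, s2g=0.0, s2gxe=0.0, s2e=1.0, rng=rng)
        est = VarianceComponentsREML().fit(df, "y")
        assert est.sigma2_g_ <= 1e-6
        assert est.sigma2_gxe_ <= 1e-6

    def test_invariant_to_row_order_and_genotype_relabeling(self):
        rng = np.random.default_rng(3)
        df = crossed(8, 4, s2g=2.0, s2gxe=0.5, s2e=1.0, rng=rng)
        a = VarianceComponentsREML().fit(df, "y")
        shuffled = df.sample(frac=1, random_state=9)
        perm = {f"L{i}": f"M{(i * 3) % 8}" for i in range(8)}
        shuffled = shuffled.assign(genotype=shuffled["genotype"].map(perm))
        b = VarianceComponentsREML().fit(shuffled, "y")
        # agreement is limited by the optimizer's numeric-gradient tolerance
        np.testing.assert_allclose(a.sigma2_g_, b.sigma2_g_, rtol=1e-3, atol=1e-6)
        np.testing.assert_allclose(a.loglik_, b.loglik_, rtol=1e-7)

    def test_full_model_loglik_dominates_reduction(self):
        rng = np.random.default_rng(5)
        df = crossed(10, 4, s2g=2.0, s2gxe=1.0, s2e=1.0, rng=rng)
        full = VarianceComponentsREML().fit(df, "y")
        red = VarianceComponentsREML(include_gxe=False).fit(df, "y")
        assert full.loglik_ >= red.loglik_ - 1e-8

    def test_too_few_genotypes_rejected(self):
        df = pd.DataFrame({"genotype": ["A"] * 6,
                           "treatment": ["complex", "simple"] * 3,
                           "y": np.arange(6.0)})
        with pytest.raises(DesignError):
            VarianceComponentsREML().fit(df, "y")


class TestLRT:
    def test_zero_variance_term_gives_zero_chi2_p_one(self):
        rng = np.random.default_rng(6)
        df = crossed(10, 6, s2g=2.0, s2gxe=0.0, s2e=1.0, rng=rng)
        est = VarianceComponentsREML().fit(df, "y")
        chi2, p = lrt_random_effect(est, "gxe")
        assert chi2 == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_chi2_invariant_to_treatment_relabeling(self):
        rng = np.random.default_rng(7)
        df = crossed(8, 4, s2g=2.0, s2gxe=0.8, s2e=1.0, rng=rng, delta=1.0)
        a = VarianceComponentsREML().fit(df, "y").lrt("genotype")[0]
        flipped = df.assign(treatment=df["treatment"].map(
            {"complex": "simple", "simple": "complex"}))
        b = VarianceComponentsREML().fit(flipped, "y").lrt("genotype")[0]
        assert a == pytest.approx(b, abs=1e-6)

    def test_power_at_moderate_heritability(self):
        """sigma2_g = sigma2_e (h2 ~ 0.5): the genotype LRT at N = 240
        should exceed the 3.84 cutoff in >= 95% of replicates."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            df = crossed(20, 6, s2g=1.0, s2gxe=0.0, s2e=1.0, rng=rng)
            est = VarianceComponentsREML(include_gxe=False).fit(df, "y")
            chi2, _ = est.lrt("genotype")
            hits += chi2 > 3.84
        assert hits / n_seeds >= 0.95

    def test_null_type_one_error_conservative(self):
        """Under sigma2_g = 0 the chi2(1) reference is conservative at the
        boundary; rejection at 0.05 stays below nominal (<= 7%)."""
        rejections = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(5000 + seed)
            df = one_way(20, 12, s2g=0.0, s2e=1.0, rng=rng)
            est = VarianceComponentsREML(treatment_col=None,
                                         include_gxe=False).fit(df, "y")
            chi2, p = est.lrt("genotype")
            rejections += p < 0.05
        assert rejections / n_sims <= 0.07

    def test_boundary_mixture_halves_p(self):
        rng = np.random.default_rng(8)
        df = one_way(12, 6, s2g=2.0, s2e=1.0, rng=rng)
        est = VarianceComponentsREML(treatment_col=None,
                                     include_gxe=False).fit(df, "y")
        chi2, p_plain = est.lrt("genotype")
        _, p_mix = est.lrt("genotype", boundary_mixture=True)
        assert p_mix == pytest.approx(p_plain / 2)


class TestSatterthwaite:
    def test_symmetric_groups_give_zero_f(self):
        # mirror-image responses across treatments: treatment estimate is 0
        rng = np.random.default_rng(9)
        half = crossed(8, 4, s2g=1.0, s2gxe=0.0, s2e=1.0, rng=rng)
        half = half[half.treatment == "complex"]
        mirror = half.assign(treatment="simple")
        df = pd.concat([half, mirror], ignore_index=True)
        est = VarianceComponentsREML(include_gxe=False).fit(df, "y")
        f = est.satterthwaite_f()
        assert f["F"] == pytest.approx(0.0, abs=1e-12)

    def test_ols_limit_recovers_residual_df(self):
        """With both random-effect variances estimated at the zero boundary
        the Satterthwaite df2 collapses to the OLS residual df (n - p).
        Sampling noise can push a variance estimate off the boundary, so the
        check conditions on replicates whose fit actually lands there."""
        checked = 0
        for seed in range(10, 20):
            rng = np.random.default_rng(seed)
            df = crossed(12, 5, s2g=0.0, s2gxe=0.0, s2e=1.0, rng=rng, delta=0.3)
            est = VarianceComponentsREML().fit(df, "y")
            if est.sigma2_g_ > 1e-10 or est.sigma2_gxe_ > 1e-10:
                continue
            f = est.satterthwaite_f()
            assert f["df2"] == pytest.approx(len(df) - 2, abs=0.5)
            checked += 1
        assert checked >= 1

    def test_strong_genotype_variance_shrinks_df2(self):
        """When genotype x treatment variance dominates, the treatment
        contrast is tested at close to the genotype-level df, far below
        the residual df."""
        rng = np.random.default_rng(11)
        df = crossed(20, 6, s2g=4.0, s2gxe=4.0, s2e=0.5, rng=rng, delta=1.0)
        est = VarianceComponentsREML().fit(df, "y")
        f = est.satterthwaite_f()
        assert f["df2"] < 40
        assert f["df2"] > 5

    def test_p_value_consistent_with_f_distribution(self):
        rng = np.random.default_rng(12)
        df = crossed(10, 6, s2g=1.0, s2gxe=0.0, s2e=1.0, rng=rng, delta=0.5)
        f = VarianceComponentsREML().fit(df, "y").satterthwaite_f()
        assert f["p"] == pytest.approx(stats.f.sf(f["F"], 1, f["df2"]))


class TestFitLmm:
    def test_full_row_on_simulated_experiment(self, sim_default):
        table, truth = sim_default
        vc = fit_lmm(table, "size")
        assert vc.sigma2_g > 0
        assert vc.chi2_g > 3.84  # sigma2_g = 35 vs sigma2_e = 130 is detectable
        assert 0 <= vc.p_g < 0.05
        assert vc.f_treatment > 0 and vc.df2 > 0
        assert vc.n_used == table.df["size"].notna().sum()

    def test_sqrt_transform_applied(self, sim_default):
        table, _ = sim_default
        raw = fit_lmm(table, "flowering_day", transform="none",
                      lrt_terms=False, f_test=False)
        sq = fit_lmm(table, "flowering_day", transform="sqrt",
                     lrt_terms=False, f_test=False)
        assert sq.transform == "sqrt"
        # variance scale shrinks by roughly (2 sqrt(mean))^-2
        assert sq.sigma2_e < raw.sigma2_e / 50
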