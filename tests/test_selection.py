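"""Selection differentials, gradients, the S = P beta decomposition, and the
stabilizing-selection (interior optimum) diagnosis."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from phenosel import (
    LandeArnoldRegression,
    default_config,
    linear_gradients,
    quadratic_gradients,
    selection_decomposition,
    selection_differential,
    simulate_experiment,
    stabilizing_check,
    standardize_traits,
)
from phenosel.data import TRAITS, AnalysisTable
from phenosel.selection import (
    CollinearityError,
    UnderdeterminedModelError,
    significance_stars,
)


def analysis_from_zw(z: dict, w, treatment=None) -> AnalysisTable:
    n = len(w)
    df = pd.DataFrame({f"z_{k}": v for k, v in z.items()})
    df["w"] = np.asarray(w, float)
    df["plant_id"] = [f"p{i}" for i in range(n)]
    df["treatment"] = treatment if treatment is not None else ["complex"] * n
    return AnalysisTable(df, ("complex", "simple"), "pooled")


class TestDifferentials:
    def test_collinear_three_points(self):
        an = analysis_from_zw({"flowering_day": [-1.0, 0.0, 1.0]},
                              [1.5, 1.0, 0.5])
        r = selection_differential(an, "flowering_day", "complex")
        assert r.S == pytest.approx(-0.5, abs=1e-12)
        assert abs(r.t) == pytest.approx(abs(r.S) / r.se)

    def test_constant_fitness_gives_zero(self):
        an = analysis_from_zw({"flowering_day": [-1.0, 0.0, 1.0, 2.0]},
                              [1.0] * 4)
        assert selection_differential(an, "flowering_day",
                                      "complex").S == pytest.approx(0.0)

    def test_degenerate_trait_errors(self):
        from phenosel.data import DegenerateTraitError
        an = analysis_from_zw({"flowering_day": [1.0, 1.0, 1.0]}, [1, 2, 3])
        with pytest.raises(DegenerateTraitError):
            selection_differential(an, "flowering_day", "complex")

    def test_too_few_cases(self):
        an = analysis_from_zw({"flowering_day": [0.0, 1.0]}, [1.0, 2.0])
        with pytest.raises(UnderdeterminedModelError):
            selection_differential(an, "flowering_day", "complex")


class TestGradients:
    def test_orthogonal_design_beta_equals_s(self):
        # Z columns from an orthogonal matrix: no indirect selection channel
        rng = np.random.default_rng(0)
        M = np.linalg.qr(rng.normal(size=(40, 3)))[0]
        M -= M.mean(axis=0)
        M /= M.std(axis=0, ddof=1)
        M[:, 1] -= M[:, 0] * (M[:, 0] @ M[:, 1]) / (M[:, 0] @ M[:, 0])
        M[:, 2] -= M[:, 0] * (M[:, 0] @ M[:, 2]) / (M[:, 0] @ M[:, 0])
        M[:, 2] -= M[:, 1] * (M[:, 1] @ M[:, 2]) / (M[:, 1] @ M[:, 1])
        M /= M.std(axis=0, ddof=1)
        w = 1 + 0.3 * M[:, 0] - 0.2 * M[:, 1] + rng.normal(0, 0.1, 40)
        an = analysis_from_zw(dict(zip(TRAITS, M.T)), w)
        g = linear_gradients(an, group="complex")
        for j, t in enumerate(TRAITS):
            s = selection_differential(an, t, "complex").S
            assert g.beta[j] == pytest.approx(s, abs=1e-10)

    def test_perfectly_collinear_traits_rejected(self):
        rng = np.random.default_rng(1)
        z1 = rng.normal(size=30)
        an = analysis_from_zw({"flowering_day": z1, "size": 2 * z1,
                               "growth": rng.normal(size=30)},
                              rng.normal(1, 0.1, 30))
        with pytest.raises(CollinearityError):
            linear_gradients(an, group="complex")

    def test_exact_parabola_single_trait(self):
        an = analysis_from_zw({"flowering_day": [-1.0, 0.0, 1.0, 2.0, -2.0]},
                              [0.0, 1.0, 0.0, -3.0, -3.0])
        g = quadratic_gradients(an, traits=["flowering_day"], group="complex")
        assert g.quadratic_raw[0] == pytest.approx(-1.0, abs=1e-10)
        assert g.gamma[0, 0] == pytest.approx(-2.0, abs=1e-10)

    def test_noiseless_correlational_recovery(self):
        rng = np.random.default_rng(2)
        z1, z2 = rng.normal(size=(2, 50))
        w = 1 + 0.2 * z1 - 0.15 * z1 * z2
        an = analysis_from_zw({"flowering_day": z1, "size": z2}, w)
        g = quadratic_gradients(an, traits=["flowering_day", "size"],
                                group="complex")
        assert g.gamma[0, 1] == pytest.approx(-0.15, abs=1e-8)
        assert g.gamma[1, 0] == pytest.approx(-0.15, abs=1e-8)

    def test_diagonal_se_doubled_offdiagonal_not(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(60, 3))
        w = 1 + Z @ [0.2, -0.1, 0.05] + rng.normal(0, 0.3, 60)
        an = analysis_from_zw(dict(zip(TRAITS, Z.T)), w)
        est = LandeArnoldRegression(order="quadratic").fit(
            an.df[[f"z_{t}" for t in TRAITS]], an.df["w"])
        res = est.result_
        assert est.gamma_se_[0, 0] == pytest.approx(
            2 * res.bse["z_flowering_day^2"])
        assert est.gamma_se_[0, 1] == pytest.approx(
            res.bse["z_flowering_day:z_size"])
        # p-values are those of the underlying coefficients (doubling a
        # coefficient and its SE leaves the t test unchanged)
        assert est.gamma_pvalues_[0, 0] == pytest.approx(
            res.pvalues["z_flowering_day^2"])

    def test_gamma_equals_hessian_of_fitted_surface(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(80, 3))
        w = 1 - 0.3 * Z[:, 0] ** 2 + 0.2 * Z[:, 0] * Z[:, 1] \
            + rng.normal(0, 0.1, 80)
        est = LandeArnoldRegression(order="quadratic").fit(Z, w)
        h = 1e-4
        H = np.zeros((3, 3))
        z0 = np.zeros(3)
        for i in range(3):
            for j in range(3):
                pts = []
                for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    p = z0.copy()
                    p[i] += si * h
                    p[j] += sj * h
                    pts.append(p)
                f = est.predict(np.array(pts))
                H[i, j] = (f[0] - f[1] - f[2] + f[3]) / (4 * h * h)
        np.testing.assert_allclose(est.gamma_, H, atol=1e-5)

    def test_sign_flip_equivariance(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(70, 3))
        w = 1 + Z @ [0.25, -0.1, 0.0] - 0.1 * Z[:, 0] * Z[:, 2] \
            + rng.normal(0, 0.2, 70)
        an = analysis_from_zw(dict(zip(TRAITS, Z.T)), w)
        g = quadratic_gradients(an, group="complex")
        Zf = Z.copy()
        Zf[:, 0] *= -1
        anf = analysis_from_zw(dict(zip(TRAITS, Zf.T)), w)
        gf = quadratic_gradients(anf, group="complex")
        assert gf.beta[0] == pytest.approx(-g.beta[0], abs=1e-10)
        assert gf.beta[1] == pytest.approx(g.beta[1], abs=1e-10)
        assert gf.gamma[0, 0] == pytest.approx(g.gamma[0, 0], abs=1e-10)
        assert gf.gamma[0, 2] == pytest.approx(-g.gamma[0, 2], abs=1e-10)


class TestDecomposition:
    @pytest.mark.parametrize("group", ["complex", "simple", "pooled"])
    def test_s_equals_p_beta(self, analysis_default, group):
        d = selection_decomposition(analysis_default, group=group)
        np.testing.assert_allclose(d["S"], d["P"] @ d["beta"], atol=1e-10)
        np.testing.assert_allclose(np.diag(d["P"]), 1.0, atol=1e-10)

    def test_scope_choice_preserves_selection_direction(self, sim_default):
        """Pooled vs within-treatment standardization leaves the sign of
        every within-treatment differential unchanged on the reference
        simulated design."""
        table, _ = sim_default
        pooled = standardize_traits(table, scope="pooled")
        within = standardize_traits(table, scope="within_treatment")
        for trait in TRAITS:
            for group in ("complex", "simple"):
                sp = selection_differential(pooled, trait, group).S
                sw = selection_differential(within, trait, group).S
                assert np.sign(sp) == np.sign(sw)


class TestStabilizing:
    def test_known_parabola_vertex(self):
        z = np.linspace(-2, 2, 20)
        w = 1 - (z - 0.2) ** 2
        an = analysis_from_zw({"flowering_day": z}, w)
        d = stabilizing_check(an, "flowering_day", "complex")
        assert d.vertex == pytest.approx(0.2, abs=1e-8)
        assert d.interior
        assert d.curvature == "concave"
        assert len(d.grid) == 101
        assert (d.grid["ci_low"] <= d.grid["w_fit"]).all()

    def test_monotone_fitness_no_interior_optimum(self):
        z = np.linspace(-2, 2, 25)
        w = 1 + 0.4 * z
        an = analysis_from_zw({"flowering_day": z}, w)
        d = stabilizing_check(an, "flowering_day", "complex")
        assert not d.interior

    def test_directional_selection_rarely_called_stabilizing(self):
        """Pure directional selection should trigger a significant
        interior-optimum diagnosis in at most ~10% of replicates."""
        cfg = default_config(seed=0)
        base = dataclasses.replace(
            cfg,
            fitness={lbl: dataclasses.replace(
                cfg.fitness[lbl], beta=(-0.3, 0.0, 0.0),
                gamma=((0.0,) * 3,) * 3)
                for lbl in cfg.treatment_labels})
        declared = 0
        n_seeds = 100
        for seed in range(n_seeds):
            table, _ = simulate_experiment(
                dataclasses.replace(base, seed=30_000 + seed))
            an = standardize_traits(table)
            d = stabilizing_check(an, "flowering_day", "pooled")
            declared += (d.curvature == "concave" and d.c_p < 0.05
                         and d.interior)
        assert declared / n_seeds <= 0.10


def test_significance_stars():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.0004) == "***"
    assert significance_stars(float("nan")) == ""
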