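import numpy as np
import pandas as pd
import pytest

from beebrains.allometry import (
    SingularDesignError,
    fit_pgls,
    relative_brain_size,
    species_means,
)
from beebrains.phylo import CovMatrix, phylo_covariance
from beebrains.simulate import simulate_allometric_traits, simulate_tree

from conftest import random_tree


def traits_from_specimens(specimens: pd.DataFrame) -> pd.DataFrame:
    return species_means(specimens)


class TestSpeciesMeans:
    def test_log_then_average(self, toy_specimens):
        out = species_means(toy_specimens)
        # species A: two specimens of mass e -> mean log brain = 1
        assert out.loc["A", "log_brain"] == pytest.approx(1.0)
        # species C: masses 1 and e^2 -> logs 0 and 2 -> mean 1
        assert out.loc["C", "log_brain"] == pytest.approx(1.0)
        # single specimen: log of the single measurement
        assert out.loc["B", "log_brain"] == pytest.approx(0.0)
        assert out.loc["B", "n_specimens"] == 1
        assert out.loc["A", "n_specimens"] == 2

    def test_nonpositive_measurement_names_record(self, toy_specimens):
        bad = toy_specimens.copy()
        bad.loc[3, "brain_mg"] = 0.0
        with pytest.raises(ValueError, match=r"brain_mg.*\[3\]"):
            species_means(bad)


def _ols_closed_form(x, y):
    slope = np.cov(x, y, ddof=0)[0, 1] / np.var(x)
    intercept = y.mean() - slope * x.mean()
    return intercept, slope


def _make_traits(n, seed, slope=2.0, noise=0.3):
    rng = np.random.default_rng(seed)
    x = rng.normal(0.8, 0.4, size=n)
    y = -1.0 + slope * x + noise * rng.standard_normal(n)
    species = [f"sp{i:03d}" for i in range(1, n + 1)]
    return pd.DataFrame(
        {"log_brain": y, "log_body": x}, index=pd.Index(species, name="species")
    )


class TestFitPGLS:
    def test_star_tree_equals_ols(self):
        n = 40
        traits = _make_traits(n, seed=1)
        V = CovMatrix(list(traits.index), np.eye(n))
        fit = fit_pgls(traits, V)
        b0, b1 = _ols_closed_form(
            traits["log_body"].to_numpy(), traits["log_brain"].to_numpy()
        )
        assert fit.intercept == pytest.approx(b0, abs=1e-8)
        assert fit.slope == pytest.approx(b1, abs=1e-8)
        ols_resid = traits["log_brain"] - (b0 + b1 * traits["log_body"])
        np.testing.assert_allclose(fit.residuals, ols_resid, atol=1e-8)

    def test_profile_beats_101_point_grid(self):
        tree = random_tree(60, seed=3)
        specimens = simulate_allometric_traits(tree, seed=4)
        traits = pd.DataFrame(
            {
                "log_brain": np.log(specimens["brain_mg"].to_numpy()),
                "log_body": np.log(specimens["itd_mm"].to_numpy()),
            },
            index=pd.Index(specimens["species"], name="species"),
        )
        V = phylo_covariance(tree)
        fit = fit_pgls(traits, V)
        from beebrains._gls import gls_ml

        y = traits["log_brain"].to_numpy()
        X = np.column_stack([np.ones(len(y)), traits["log_body"].to_numpy()])
        Vo = V.reorder(list(traits.index)).values
        grid_best = max(
            gls_ml(y, X, Vo, lam)[2] for lam in np.linspace(0, 1, 101)
        )
        assert fit.loglik >= grid_best - 1e-6

    def test_gls_normal_equations_satisfied(self):
        tree = random_tree(50, seed=7)
        specimens = simulate_allometric_traits(tree, seed=8)
        traits = pd.DataFrame(
            {
                "log_brain": np.log(specimens["brain_mg"].to_numpy()),
                "log_body": np.log(specimens["itd_mm"].to_numpy()),
            },
            index=pd.Index(specimens["species"], name="species"),
        )
        V = phylo_covariance(tree)
        fit = fit_pgls(traits, V)
        from beebrains._gls import lambda_cov

        Vl = lambda_cov(V.reorder(list(traits.index)).values, fit.lambda_hat)
        Vinv = np.linalg.inv(Vl)
        e = fit.residuals.to_numpy()
        x = traits["log_body"].to_numpy()
        assert abs(np.ones(len(e)) @ Vinv @ e) < 1e-6
        assert abs(x @ Vinv @ e) < 1e-6

    def test_zero_noise_gives_r2_one_and_zero_residuals(self):
        tree = random_tree(30, seed=11)
        specimens = simulate_allometric_traits(tree, sigma_resid=0.0, seed=12)
        traits = pd.DataFrame(
            {
                "log_brain": np.log(specimens["brain_mg"].to_numpy()),
                "log_body": np.log(specimens["itd_mm"].to_numpy()),
            },
            index=pd.Index(specimens["species"], name="species"),
        )
        fit = fit_pgls(traits, phylo_covariance(tree))
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-8)
        assert fit.slope == pytest.approx(2.5, abs=1e-6)

    def test_r2_in_unit_interval(self):
        traits = _make_traits(25, seed=13, noise=1.5)
        V = CovMatrix(list(traits.index), np.eye(25))
        fit = fit_pgls(traits, V)
        assert 0.0 <= fit.r2 <= 1.0

    def test_constant_body_size_raises(self):
        traits = _make_traits(10, seed=5)
        traits["log_body"] = 1.0
        V = CovMatrix(list(traits.index), np.eye(10))
        with pytest.raises(SingularDesignError):
            fit_pgls(traits, V)

    def test_too_few_species_raises(self):
        traits = _make_traits(3, seed=5)
        V = CovMatrix(list(traits.index), np.eye(3))
        with pytest.raises(ValueError, match=">= 4"):
            fit_pgls(traits, V)


class TestRelativeBrainSize:
    def test_shift_invariance_of_scores(self):
        traits = _make_traits(30, seed=21)
        V = CovMatrix(list(traits.index), np.eye(30))
        base = fit_pgls(traits, V)
        shifted = traits.assign(log_brain=traits["log_brain"] + 3.7)
        moved = fit_pgls(shifted, V)
        assert moved.intercept == pytest.approx(base.intercept + 3.7, abs=1e-8)
        np.testing.assert_allclose(moved.residuals, base.residuals, atol=1e-8)

    def test_row_order_invariance(self):
        tree = random_tree(20, seed=23)
        specimens = simulate_allometric_traits(tree, seed=24)
        traits = pd.DataFrame(
            {
                "log_brain": np.log(specimens["brain_mg"].to_numpy()),
                "log_body": np.log(specimens["itd_mm"].to_numpy()),
            },
            index=pd.Index(specimens["species"], name="species"),
        )
        V = phylo_covariance(tree)
        a = fit_pgls(traits, V)
        rng = np.random.default_rng(0)
        perm = traits.iloc[rng.permutation(len(traits))]
        b = fit_pgls(perm, V)
        for sp in traits.index:
            assert b.residuals[sp] == pytest.approx(a.residuals[sp], abs=1e-6)

    def test_score_table_ranks(self):
        traits = _make_traits(10, seed=31)
        V = CovMatrix(list(traits.index), np.eye(10))
        fit = fit_pgls(traits, V)
        table = relative_brain_size(fit)
        assert table["rank"].iloc[0] == 1
        assert table["residual"].iloc[0] == table["residual"].max()
        assert set(table.index) == set(traits.index)
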