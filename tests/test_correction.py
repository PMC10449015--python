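import subprocess

import numpy as np
import pytest

from combatcor import (
    ExpressionMatrix,
    SimScenario,
    build_design,
    combat_adjust,
    combat_fit,
    combat_residual_variance,
    meanonly_adjust,
    ols_de,
    simulate_dataset,
    unbalanced_design,
)
from combatcor.correction import BatchCorrectionFit


def _em(values, prefix="g"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return ExpressionMatrix(values,
                            [f"{prefix}{i}" for i in range(values.shape[0])],
                            [f"S{j + 1}" for j in range(values.shape[1])])


class TestMeanOnlyAdjust:
    def test_noise_free_group_structure_is_untouched(self, toy22):
        beta = np.array([[1.0, 2.5]])
        Y = _em(beta @ toy22.X1.T)
        out = meanonly_adjust(Y, toy22)
        np.testing.assert_allclose(out.values, Y.values, atol=1e-12)

    def test_six_sample_hand_oracle(self):
        """Independent oracle: solve the normal equations directly and subtract
        weighted-grand-mean-centred batch shifts."""
        d = build_design(["A", "A", "B", "A", "B", "B"],
                         ["1", "1", "1", "2", "2", "2"])
        y = np.array([1.0, 1.4, 3.0, 2.1, 4.2, 3.9])
        X = np.column_stack([d.batch_onehot, d.X1[:, 1]])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        loc = coef[:2]
        shift = loc - loc @ (d.batch_sizes / d.n)
        expected = y - d.batch_onehot @ shift
        out = meanonly_adjust(_em(y), d)
        np.testing.assert_allclose(out.values[0], expected, atol=1e-10)

    def test_group_estimates_match_one_step(self, smallsim, unbal):
        """Two-step regression adjustment and the one-step model give identical
        group-effect point estimates."""
        adj = meanonly_adjust(smallsim.Y, unbal)
        two_step = ols_de(adj, unbal, include_batch=False)
        one_step = ols_de(smallsim.Y, unbal, include_batch=True)
        np.testing.assert_allclose(two_step.estimate, one_step.estimate, atol=1e-8)

    def test_single_batch_rejected(self):
        d = build_design(["A", "B", "A", "B"], ["1", "1", "1", "1"])
        with pytest.raises(ValueError, match="single batch"):
            meanonly_adjust(_em(np.zeros(4)), d)


class TestCombatFit:
    def test_no_eb_mean_only_gamma_equals_batch_means_of_z(self, smallsim, unbal):
        fit = combat_fit(smallsim.Y, unbal, mean_only=True, eb=False)
        sd = np.sqrt(fit.sigma2)
        Z = (smallsim.Y.values - fit.stand_mean()) / sd[:, None]
        expected = (Z @ unbal.batch_onehot) / unbal.batch_sizes
        np.testing.assert_allclose(fit.gamma_star, expected, atol=1e-10)
        assert np.all(fit.delta2_star == 1.0)

    def test_singleton_batch_needs_mean_only(self):
        d = build_design(["A", "B", "A", "B", "A"], ["1", "1", "1", "1", "2"])
        Y = _em(np.random.default_rng(0).normal(size=(5, 5)))
        with pytest.raises(ValueError, match="mean_only"):
            combat_fit(Y, d)
        fit = combat_fit(Y, d, mean_only=True)  # succeeds
        assert fit.mean_only

    def test_parameter_recovery_with_informative_batches(self):
        """On data drawn from the location/scale model with three 25-sample
        batches, the shrunk estimates track the true per-batch effects.

        The model is identifiable only up to a per-gene anchoring: location
        effects are recovered relative to the batch-size-weighted grand mean,
        and squared scale effects relative to their weighted per-gene average,
        so recovery is measured against those centred/normalised truths.
        """
        groups = (["A"] * 13 + ["B"] * 12) * 3
        batches = sum([[f"b{i}"] * 25 for i in range(3)], [])
        d = build_design(groups, batches)
        hp = {"m": np.zeros(3), "v": np.ones(3), "a": np.full(3, 6.0),
              "b": np.full(3, 5.0), "gamma_off": False, "delta_off": False}
        s = SimScenario(design=d, n_genes=20_000, hyperparams=hp, seed=5,
                        de_spec=((2.0, 500), (-2.0, 500)))
        sim = simulate_dataset(s)
        fit = combat_fit(sim.Y, d)
        sd = np.sqrt(fit.sigma2)
        w = d.batch_sizes / d.n
        gamma_centred = sim.gamma - (sim.gamma @ w)[:, None]
        d2 = sim.delta**2
        d2_rel = d2 / (d2 @ w)[:, None]
        for i in range(3):
            gamma_raw = fit.gamma_star[:, i] * sd  # back to log-expression units
            r_gamma = np.corrcoef(gamma_raw, gamma_centred[:, i])[0, 1]
            r_delta2 = np.corrcoef(fit.delta2_star[:, i], d2_rel[:, i])[0, 1]
            assert r_gamma > 0.9
            assert r_delta2 > 0.8

    def test_variance_null_scale_estimates_near_one(self, unbal):
        s = SimScenario(design=unbal, mean_level="small", var_level="null",
                        n_genes=20_000, seed=3)
        sim = simulate_dataset(s)
        fit = combat_fit(sim.Y, unbal)
        med = np.median(fit.delta2_star, axis=0)
        assert np.all(med > 0.9) and np.all(med < 1.1)

    def test_constant_shift_moves_background_only(self, smallsim, unbal):
        fit0 = combat_fit(smallsim.Y, unbal)
        shifted = smallsim.Y.copy_with(smallsim.Y.values.copy())
        shifted.values[7] += 5.0
        fit1 = combat_fit(shifted, unbal)
        assert fit1.alpha[7] == pytest.approx(fit0.alpha[7] + 5.0, abs=1e-8)
        np.testing.assert_allclose(fit1.gamma_star[7], fit0.gamma_star[7], atol=1e-8)
        np.testing.assert_allclose(fit1.delta2_star[7], fit0.delta2_star[7], atol=1e-8)
        np.testing.assert_allclose(fit1.beta_group[7], fit0.beta_group[7], atol=1e-8)


class TestCombatAdjust:
    def test_mean_only_no_eb_equals_regression_adjustment(self, unbal):
        s = SimScenario(design=unbal, n_genes=100, seed=9,
                        de_spec=((2.0, 10), (-1.0, 10)))
        sim = simulate_dataset(s)
        a = meanonly_adjust(sim.Y, unbal)
        fit = combat_fit(sim.Y, unbal, mean_only=True, eb=False)
        b = combat_adjust(fit, sim.Y)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_noise_free_data_round_trip(self, toy22):
        Y = _em(np.array([[1.0, 2.5]]) @ toy22.X1.T)
        fit = combat_fit(Y, toy22, eb=False)
        out = combat_adjust(fit, Y)
        np.testing.assert_allclose(out.values, Y.values, atol=1e-8)

    def test_scale_effects_are_removed(self, unbal):
        """Under strong scale effects, adjustment pulls every batch's residual
        variance close to the pooled level (within ~30% on the log scale,
        versus many-fold disparities before adjustment)."""
        s = SimScenario(design=unbal, mean_level="small", var_level="large",
                        n_genes=20_000, seed=21)
        sim = simulate_dataset(s)
        fit = combat_fit(sim.Y, unbal)
        adj = combat_adjust(fit, sim.Y)
        w = unbal.batch_sizes / unbal.n

        def batch_ratios(values):
            resid = values - fit.stand_mean()
            per_batch = np.array([
                resid[:, unbal.batch_indices(lev)].var(axis=1).mean()
                for lev in unbal.batch_levels
            ])
            return per_batch / (w @ per_batch)

        before = np.abs(np.log(batch_ratios(sim.Y.values)))
        after = np.abs(np.log(batch_ratios(adj.values)))
        assert np.all(after < 0.35)
        assert np.all(after < 0.5 * before)

    def test_correction_is_stable_under_reapplication(self, unbal):
        """Re-fitting corrected data finds no location effects and only the
        small scale offset implied by the divisor-n variance convention, and
        a second correction changes the data far less than the first did."""
        s = SimScenario(design=unbal, mean_level="small", var_level="small",
                        n_genes=5_000, seed=13,
                        de_spec=((2.0, 125), (1.0, 125), (-1.0, 125), (-2.0, 125)))
        sim = simulate_dataset(s)
        adj = combat_adjust(combat_fit(sim.Y, unbal), sim.Y)
        refit = combat_fit(adj, unbal)
        assert np.all(np.abs(np.median(refit.gamma_star, axis=0)) < 0.05)
        assert np.all(np.abs(np.median(refit.delta2_star, axis=0) - 1) < 0.2)
        adj2 = combat_adjust(refit, adj)
        first = np.linalg.norm(adj.values - sim.Y.values)
        second = np.linalg.norm(adj2.values - adj.values)
        assert second < 0.2 * first

    def test_mismatched_matrix_rejected(self, smallsim, unbal):
        fit = combat_fit(smallsim.Y, unbal)
        other = ExpressionMatrix(smallsim.Y.values[:10],
                                 smallsim.Y.gene_ids[:10], smallsim.Y.sample_ids)
        with pytest.raises(ValueError, match="match"):
            combat_adjust(fit, other)


class TestResidualVariance:
    def _fit_with(self, d, delta2, sigma2):
        G, B = delta2.shape
        zeros = np.zeros((G, B))
        return BatchCorrectionFit(
            design=d, gene_ids=[f"g{i}" for i in range(G)],
            sample_ids=list(d.sample_ids), alpha=np.zeros(G),
            beta_group=np.zeros((G, d.p1 - 1)), sigma2=sigma2,
            gamma_hat=zeros, delta2_hat=delta2, gamma_star=zeros,
            delta2_star=delta2, gamma_bar=np.zeros(B), tau2_bar=np.ones(B),
            lambda_bar=np.ones(B), theta_bar=np.ones(B), mean_only=False,
            eb=False, parametric=True, n_iter=np.zeros(B, dtype=int))

    def test_unit_scales_return_sigma2(self, unbal):
        G = 4
        sigma2 = np.arange(1.0, G + 1)
        fit = self._fit_with(unbal, np.ones((G, 5)), sigma2)
        np.testing.assert_array_equal(combat_residual_variance(fit), sigma2)

    def test_weighted_average_arithmetic(self):
        d = build_design(["A", "B", "A", "B"], ["1", "1", "1", "2"])
        fit = self._fit_with(d, np.array([[2.0, 4.0]]), np.array([1.0]))
        assert combat_residual_variance(fit)[0] == pytest.approx(2.5)

    def test_large_scale_effects_inflate_variance(self, unbal):
        """The implied residual variance grows with the scale-effect level."""
        means = {}
        for vl in ("null", "large"):
            s = SimScenario(design=unbal, mean_level="small", var_level=vl,
                            n_genes=4_000, seed=2,
                            de_spec=((2.0, 100), (-2.0, 100)))
            sim = simulate_dataset(s)
            fit = combat_fit(sim.Y, unbal)
            means[vl] = combat_residual_variance(fit).mean()
        assert means["large"] > means["null"]


def test_combat_matches_sva_reference(tmp_path, unbal):
    """Independent cross-check: the adjusted matrix agrees with the reference
    location/scale implementation in Bioconductor's sva package."""
    s = SimScenario(design=unbal, n_genes=200, seed=7,
                    de_spec=((2.0, 20), (-1.0, 20)))
    sim = simulate_dataset(s)
    ours = combat_adjust(combat_fit(sim.Y, unbal), sim.Y)
    np.savetxt(tmp_path / "Y.tsv", sim.Y.values, delimiter="\t")
    batch = [unbal.batch_levels.index(b) + 1 for b in unbal.batch]
    group = (unbal.group == unbal.group_levels[1]).astype(int)
    np.savetxt(tmp_path / "pheno.tsv",
               np.column_stack([batch, group]), fmt="%d", delimiter="\t")
    script = f"""
    suppressMessages(library(sva))
    Y <- as.matrix(read.table("{tmp_path}/Y.tsv", sep="\\t"))
    ph <- read.table("{tmp_path}/pheno.tsv", sep="\\t")
    adj <- ComBat(dat=Y, batch=ph$V1, mod=model.matrix(~ph$V2), par.prior=TRUE)
    write.table(adj, "{tmp_path}/adj.tsv", sep="\\t", row.names=FALSE, col.names=FALSE)
    """
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    ref = np.loadtxt(tmp_path / "adj.tsv", delimiter="\t")
    np.testing.assert_allclose(ours.values, ref, atol=1e-8)
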