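"""Gibbs sampler: full conditionals, chain bookkeeping, multi-quantile fits."""

import numpy as np
import pytest

from bqrbmi.ald import mixture_constants
from bqrbmi.gibbs import (
    RESIDUAL_FLOOR,
    EncodedDataset,
    PriorSpec,
    SamplerConfig,
    beta_full_conditional,
    check_loss_minimizer,
    derive_tau_seed,
    fit_multi_quantile,
    latent_full_conditional,
    run_gibbs,
)


class TestBetaFullConditional:
    def test_flat_prior_equal_latents_is_least_squares(self, simple_dataset):
        # tau=0.5 has gamma=0; equal latents make the weights constant, so a
        # flat prior reduces the conditional mean to the OLS solution
        prior = PriorSpec(np.zeros(3), 1e8 * np.eye(3))
        latents = np.full(simple_dataset.n, 0.7)
        mean, cov = beta_full_conditional(simple_dataset, latents, 0.5, prior)
        ols = np.linalg.lstsq(simple_dataset.design, simple_dataset.outcome, rcond=None)[0]
        assert mean == pytest.approx(ols, abs=1e-6)
        assert cov == pytest.approx(cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_tight_prior_dominates(self, simple_dataset):
        prior_mean = np.array([5.0, -2.0, 1.0])
        prior = PriorSpec(prior_mean, 1e-8 * np.eye(3))
        mean, _ = beta_full_conditional(simple_dataset, np.ones(simple_dataset.n), 0.5, prior)
        assert mean == pytest.approx(prior_mean, abs=1e-6)

    def test_two_point_average(self):
        data = EncodedDataset(np.array([1.0, 3.0]), np.ones((2, 1)), ["Intercept"])
        prior = PriorSpec(np.zeros(1), 1e10 * np.eye(1))
        mean, _ = beta_full_conditional(data, np.ones(2), 0.5, prior)
        assert mean[0] == pytest.approx(2.0, abs=1e-6)

    def test_nonpositive_latent_rejected(self, simple_dataset):
        prior = PriorSpec.diffuse(3)
        latents = np.ones(simple_dataset.n)
        latents[0] = 0.0
        with pytest.raises(ValueError):
            beta_full_conditional(simple_dataset, latents, 0.5, prior)


class TestLatentFullConditional:
    def test_median_zero_residual_floored(self):
        params = latent_full_conditional(0.0, 0.5)
        assert params.order == 0.5
        assert params.a == pytest.approx(RESIDUAL_FLOOR / np.sqrt(8.0))
        assert params.b == pytest.approx(np.sqrt(2.0))

    def test_b_parameter_two_routes_agree(self):
        const = mixture_constants(0.25)
        direct = np.sqrt(const.gamma**2 / const.h**2 + 2.0)
        # independent scalar route straight from the tau formulas
        tau = 0.25
        gamma = (1 - 2 * tau) / (tau * (1 - tau))
        h2 = 2 / (tau * (1 - tau))
        assert latent_full_conditional(1.0, tau).b == pytest.approx(direct)
        assert direct == pytest.approx(np.sqrt(gamma**2 / h2 + 2.0))

    @pytest.mark.parametrize("residual", [0.3, 2.5])
    def test_sign_symmetric_in_residual(self, residual):
        assert latent_full_conditional(residual, 0.85).a == pytest.approx(
            latent_full_conditional(-residual, 0.85).a
        )


class TestRunGibbs:
    def test_default_schedule_retains_1800_draws(self):
        rng = np.random.default_rng(3)
        data = EncodedDataset(rng.standard_normal(60), np.ones((60, 1)), ["Intercept"])
        chain = run_gibbs(data, 0.5, config=SamplerConfig(seed=4))
        assert chain.n_draws == 1800
        assert chain.draws.shape == (1800, 1)

    def test_intercept_only_recovers_sample_median(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(500)
        data = EncodedDataset(y, np.ones((500, 1)), ["Intercept"])
        chain = run_gibbs(
            data, 0.5, config=SamplerConfig(iterations=3000, burn_in=500, thin=2, seed=6)
        )
        assert chain.draws.mean() == pytest.approx(np.median(y), abs=0.1)

    def test_deterministic_given_seed(self, simple_dataset):
        cfg = SamplerConfig(iterations=600, burn_in=100, thin=5, seed=7)
        a = run_gibbs(simple_dataset, 0.25, config=cfg)
        b = run_gibbs(simple_dataset, 0.25, config=cfg)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.latent_last, b.latent_last)

    def test_rank_deficient_design_rejected(self):
        design = np.column_stack([np.ones(30), np.arange(30.0), 2 * np.arange(30.0)])
        with pytest.raises(ValueError, match="rank"):
            EncodedDataset(np.zeros(30), design, ["Intercept", "x", "2x"])

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            SamplerConfig(thin=0)

    def test_scale_extension_runs_and_recovers_spread(self, simple_dataset):
        cfg = SamplerConfig(iterations=2000, burn_in=500, thin=2, seed=8, estimate_scale=True)
        chain = run_gibbs(simple_dataset, 0.5, config=cfg)
        assert chain.scale_draws is not None and chain.scale_draws.shape == (750,)
        assert np.all(chain.scale_draws > 0)

    def test_chain_csv_roundtrip(self, simple_dataset, tmp_path):
        import pandas as pd

        cfg = SamplerConfig(iterations=300, burn_in=100, thin=2, seed=9)
        chain = run_gibbs(simple_dataset, 0.5, config=cfg)
        path = tmp_path / "chain.csv"
        chain.to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == simple_dataset.column_labels
        assert frame.to_numpy() == pytest.approx(chain.draws)


class TestMultiQuantile:
    def test_single_tau_reduces_to_run_gibbs(self, simple_dataset):
        cfg = SamplerConfig(iterations=400, burn_in=100, thin=3, seed=10)
        chains = fit_multi_quantile(simple_dataset, [0.5], config=cfg)
        solo_cfg = SamplerConfig(
            iterations=400, burn_in=100, thin=3, seed=derive_tau_seed(10, 0)
        )
        solo = run_gibbs(simple_dataset, 0.5, config=solo_cfg)
        assert np.array_equal(chains[0.5].draws, solo.draws)

    def test_duplicate_taus_rejected(self, simple_dataset):
        with pytest.raises(ValueError):
            fit_multi_quantile(simple_dataset, [0.5, 0.5])

    def test_intercepts_monotone_on_location_shift_model(self):
        # pure location shift: conditional quantiles differ only through the
        # intercept, which must be non-decreasing in tau
        rng = np.random.default_rng(11)
        n = 800
        x = rng.uniform(0, 2, n)
        y = 1.0 + 0.5 * x + 1.5 * rng.standard_normal(n)
        data = EncodedDataset(y, np.column_stack([np.ones(n), x]), ["Intercept", "x"])
        cfg = SamplerConfig(iterations=2500, burn_in=500, thin=2, seed=12)
        chains = fit_multi_quantile(data, [0.05, 0.25, 0.5, 0.75, 0.85, 0.95], config=cfg)
        intercepts = [chains[t].draws.mean(axis=0)[0] for t in sorted(chains)]
        assert np.all(np.diff(intercepts) > 0)


class TestCheckLossMinimizer:
    def test_agrees_with_statsmodels_quantreg(self, simple_dataset):
        sm = pytest.importorskip("statsmodels.api")
        for tau in (0.25, 0.5, 0.85):
            ours = check_loss_minimizer(simple_dataset, tau)
            ref = (
                sm.QuantReg(simple_dataset.outcome, simple_dataset.design)
                .fit(q=tau)
                .params
            )
            assert ours == pytest.approx(np.asarray(ref), abs=5e-2)
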