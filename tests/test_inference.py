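"""Fitting, diagnostics, and posterior summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from submort.data import MortalityDataset
from submort.inference import (
    MortalityPCModel,
    PosteriorSamples,
    SamplerConfig,
    diagnostics,
    fit,
    summarize_correlations,
    summarize_rates,
)
from submort.model import ModelConfig
from submort.simulate import SimulationConfig, basis_from_curves, generate_dataset


def _make_samples(draws: dict, data=None, n_chains=2) -> PosteriorSamples:
    if data is None:
        shape = next(
            v.shape[2:] for k, v in draws.items() if k == "log_lambda"
        )
        A, S, C, T = shape
        data = MortalityDataset(
            deaths=np.ones(shape[:4], dtype=int),
            exposures=np.full(shape[:4], 100.0),
            ages=[f"a{i}" for i in range(A)],
            subpops=[f"s{i}" for i in range(S)],
            areas=[f"c{i}" for i in range(C)],
            years=list(range(T)),
        )
    return PosteriorSamples(
        draws=draws,
        data=data,
        config=ModelConfig(n_components=2),
        sampler_config=SamplerConfig(chains=n_chains, warmup=1, samples=1),
    )


class TestDiagnostics:
    def test_iid_chains_pass(self, rng):
        draws = {"mu_beta": rng.standard_normal((2, 500, 3))}
        samples = _make_samples(
            draws | {"log_lambda": rng.standard_normal((2, 500, 1, 2, 1, 1))}
        )
        out = diagnostics(samples, var_names=["mu_beta"])
        assert np.all(out["rhat"] < 1.02)
        assert out.attrs["converged"] in (True, False)

    def test_separated_chains_flagged(self, rng):
        a = rng.standard_normal((1, 400, 2))
        b = rng.standard_normal((1, 400, 2)) + 10.0
        draws = {"mu_beta": np.concatenate([a, b], axis=0)}
        samples = _make_samples(
            draws | {"log_lambda": rng.standard_normal((2, 400, 1, 2, 1, 1))}
        )
        out = diagnostics(samples, var_names=["mu_beta"])
        assert np.all(out["rhat"] > 1.5)

    def test_constant_chains_yield_nan_not_crash(self):
        draws = {"mu_beta": np.ones((2, 100, 2))}
        samples = _make_samples(
            draws | {"log_lambda": np.ones((2, 100, 1, 2, 1, 1))}
        )
        out = diagnostics(samples, var_names=["mu_beta"])
        assert out["rhat"].isna().all() or np.all(~np.isfinite(out["rhat"]))

    def test_single_chain_rejected(self, rng):
        draws = {
            "mu_beta": rng.standard_normal((1, 100, 2)),
            "log_lambda": rng.standard_normal((1, 100, 1, 2, 1, 1)),
        }
        with pytest.raises(ValueError, match="two chains"):
            diagnostics(_make_samples(draws, n_chains=1))


class TestSummaries:
    def test_degenerate_draws_give_zero_width(self):
        ll = np.full((2, 50, 1, 2, 1, 1), np.log(0.02))
        samples = _make_samples({"log_lambda": ll})
        out = summarize_rates(samples, levels=(0.8,))
        assert np.allclose(out["rate_median"], 0.02)
        assert np.allclose(out["rate_lower_80"], 0.02)
        assert np.allclose(out["rate_upper_80"], 0.02)

    def test_interval_matches_sort_oracle(self, rng):
        vals = rng.permutation(np.arange(1.0, 101.0))
        ll = np.log(vals).reshape(2, 50, 1, 1, 1, 1)
        samples = _make_samples({"log_lambda": ll})
        out = summarize_rates(samples, levels=(0.8,))
        svals = np.sort(vals)
        assert out.loc[0, "rate_lower_80"] == pytest.approx(
            np.quantile(svals, 0.1)
        )
        assert out.loc[0, "rate_upper_80"] == pytest.approx(
            np.quantile(svals, 0.9)
        )
        assert out.loc[0, "rate_median"] == pytest.approx(np.median(vals))

    def test_levels_are_nested(self, rng):
        ll = rng.standard_normal((2, 200, 2, 2, 2, 2)) - 5
        samples = _make_samples({"log_lambda": ll})
        out = summarize_rates(samples, levels=(0.8, 0.95))
        assert np.all(out["rate_lower_95"] <= out["rate_lower_80"] + 1e-12)
        assert np.all(out["rate_upper_80"] <= out["rate_upper_95"] + 1e-12)
        assert np.all(out["rate_median"] > 0)

    def test_identity_correlations_summarized_as_zero(self):
        n, P, T, S = 40, 2, 2, 2
        corr = np.broadcast_to(np.eye(S), (2, n, P, T, S, S)).copy()
        ll = np.zeros((2, n, 1, S, 1, T))
        samples = _make_samples({"corr_beta": corr, "log_lambda": ll})
        out = summarize_correlations(samples, levels=(0.9,))
        beta_rows = out[out["kind"] == "beta"]
        assert np.allclose(beta_rows["median"], 0.0)
        assert np.allclose(beta_rows["lower_90"], 0.0)
        assert np.allclose(beta_rows["upper_90"], 0.0)

    def test_constant_correlation_recovered(self):
        n, S = 30, 2
        R = np.array([[1.0, 0.9], [0.9, 1.0]])
        corr = np.broadcast_to(R, (2, n, 1, 1, S, S)).copy()
        ll = np.zeros((2, n, 1, S, 1, 1))
        samples = _make_samples({"corr_beta": corr, "log_lambda": ll})
        out = summarize_correlations(samples, levels=(0.95,))
        row = out[out["kind"] == "beta"].iloc[0]
        assert row["median"] == pytest.approx(0.9)


@pytest.fixture(scope="module")
def micro_fit():
    cfg = SimulationConfig(
        n_areas=2, n_years=3, n_subpops=2, n_ages=4, seed=5,
        pop_min=2e3, pop_max=5e4,
    )
    data, truth = generate_dataset(cfg)
    basis = basis_from_curves(truth.curves)
    sampler = SamplerConfig(
        chains=2, warmup=80, samples=60, seed=99, adapt_delta=0.9
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = fit(data, basis, ModelConfig(n_components=2), sampler)
    return data, truth, basis, sampler, post


class TestFit:
    def test_draw_counts_and_shapes(self, micro_fit):
        data, _, _, sampler, post = micro_fit
        assert post.n_chains == 2 and post.n_draws == 60
        assert post.draws["log_lambda"].shape == (2, 60) + data.shape
        assert post.draws["corr_beta"].shape[2:] == (2, 3, 2, 2)

    def test_same_seed_reproduces_draws(self, micro_fit):
        data, _, basis, sampler, post = micro_fit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = fit(data, basis, ModelConfig(n_components=2), sampler)
        assert np.array_equal(
            post.draws["log_lambda"], again.draws["log_lambda"]
        )

    def test_mean_plus_deviation_identity_each_draw(self, micro_fit):
        _, _, _, _, post = micro_fit
        beta = post.draws["beta"]
        mu = post.draws["mu_beta"]
        omega = post.draws["omega"]
        assert np.allclose(beta, mu[:, :, :, :, None, :] + omega, atol=1e-5)

    def test_summarized_rates_positive(self, micro_fit):
        _, _, _, _, post = micro_fit
        out = summarize_rates(post)
        assert np.all(out["rate_median"] > 0)

    def test_estimator_wrapper(self, micro_fit):
        data, truth, basis, _, _ = micro_fit
        model = MortalityPCModel(
            n_components=2, chains=2, warmup=40, samples=30, seed=1,
            adapt_delta=0.9, max_treedepth=8,
        )
        assert model.get_params()["chains"] == 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(data.to_long(), basis)
        assert hasattr(model, "posterior_")
        rates = model.predict_rates(levels=(0.9,))
        assert len(rates) == data.n_cells
        with pytest.raises(ValueError):
            model.set_params(nonsense=1)
        fresh = MortalityPCModel()
        with pytest.raises(AttributeError):
            fresh.predict_rates()


class TestPriorRecovery:
    """With every cell masked out of the likelihood, the posterior is the prior."""

    @pytest.fixture(scope="class")
    def prior_draws(self):
        cfg = SimulationConfig(n_areas=2, n_years=3, n_subpops=2, n_ages=3, seed=2)
        data, truth = generate_dataset(cfg)
        data.mask[:] = False
        basis = basis_from_curves(truth.curves)
        # the group means have no proper prior without data, so their
        # trajectories are ballistic; cap the tree depth to keep this cheap
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit(
                data, basis, ModelConfig(n_components=2),
                SamplerConfig(chains=2, warmup=150, samples=400, seed=3,
                              adapt_delta=0.9, max_treedepth=5),
            )
        return post

    def test_sigma_gamma_matches_halfnormal(self, prior_draws):
        draws = prior_draws.stacked("sigma_gamma").ravel()
        grid = np.linspace(0.02, 0.8, 12)
        emp = np.array([(draws <= g).mean() for g in grid])
        theo = stats.halfnorm(scale=0.25).cdf(grid)
        assert np.max(np.abs(emp - theo)) < 0.08

    def test_correlation_marginal_uniform(self, prior_draws):
        r = prior_draws.stacked("corr_beta")[:, :, :, 1, 0].ravel()
        grid = np.linspace(-0.9, 0.9, 13)
        emp = np.array([(r <= g).mean() for g in grid])
        theo = (grid + 1) / 2
        assert np.max(np.abs(emp - theo)) < 0.1
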