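"""MCMC fitting, derived quantities and posterior summaries."""

import math
import warnings

import numpy as np
import pytest

import sharedmap as sm
from sharedmap.inference import summarize
from sharedmap.model import ModelSpec, CountData, zero_state

from conftest import make_samples

INTERCEPT_ONLY = ModelSpec(shared_spatial="none", specific_unstructured=frozenset(),
                           age_effect="none", intercepts=True)


class TestFit:
    def test_same_seed_identical_draws(self, small_data, small_graph):
        data, _ = small_data
        kw = dict(chains=1, iters=80, warmup=120, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1 = sm.fit(data, ModelSpec.selected(), sm.PriorConfig(), small_graph, **kw)
            s2 = sm.fit(data, ModelSpec.selected(), sm.PriorConfig(), small_graph, **kw)
        for k in s1.draws:
            np.testing.assert_array_equal(s1.draws[k], s2.draws[k])

    def test_intercept_only_matches_poisson_glm_mle(self):
        rng = np.random.default_rng(0)
        n = np.full((2, 4, 2, 5), 1e4)
        O = rng.poisson(n * 3e-4)
        data = CountData(O=O, n=n, area_ids=tuple(f"a{i}" for i in range(4)))
        s = sm.fit(data, INTERCEPT_ONLY, sm.PriorConfig(), None,
                   chains=2, iters=1000, warmup=500, seed=11)
        alpha = s.stacked("alpha")
        for d in range(2):
            mle = math.log(O[d].sum() / n[d].sum())
            se = alpha[:, d].std() / math.sqrt(max(s.diagnostics["ess_bulk"][f"alpha{d+1}"], 10))
            assert abs(alpha[:, d].mean() - mle) < 3 * se + 1e-3

    def test_retained_kappa_satisfies_constraints(self, small_fit):
        kap = small_fit.stacked("kappa")
        sums = kap.sum(axis=1)
        assert np.max(np.abs(sums)) < 1e-8

    def test_precisions_and_delta_positive(self, small_fit):
        assert np.all(small_fit.stacked("tau_kappa") > 0)
        assert np.all(small_fit.stacked("tau_u") > 0)
        assert np.all(small_fit.stacked("tau_eta") > 0)
        assert np.all(np.isfinite(small_fit.stacked("log_delta")))

    def test_diagnostics_attached(self, small_fit):
        assert set(small_fit.diagnostics) == {"rhat", "ess_bulk"}
        assert "log_delta" in small_fit.diagnostics["rhat"]

    def test_default_scenario_converges(self, spain_graph):
        """Split-R-hat diagnostics pass on the default registry-scale
        synthetic scenario with default sampler settings."""
        data, _ = sm.simulate_dataset(seed=42, graph=spain_graph)
        s = sm.fit(data, ModelSpec.selected(), sm.PriorConfig(), spain_graph,
                   chains=2, iters=1000, warmup=1000, seed=21)
        assert max(s.diagnostics["rhat"].values()) < 1.05

    def test_isolated_area_rejected_without_optin(self, small_data):
        data, _ = small_data
        g = sm.AreaGraph(data.area_ids, frozenset({(0, 1)}))
        with pytest.raises(ValueError, match="isolated"):
            sm.fit(data, ModelSpec.selected(), sm.PriorConfig(), g,
                   chains=1, iters=50, warmup=50, seed=1)

    def test_fix_delta_removes_it_from_sampling(self, small_data, small_graph):
        data, _ = small_data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = sm.fit(data, ModelSpec.selected(), sm.PriorConfig(), small_graph,
                       chains=1, iters=60, warmup=80, seed=2, fix_delta=1.0)
        assert "log_delta" not in s.draws
        assert np.all(s.log_delta_draws() == 0.0)

    def test_invalid_sampler_config_rejected(self, small_data, small_graph):
        data, _ = small_data
        with pytest.raises(ValueError):
            sm.fit(data, ModelSpec.selected(), sm.PriorConfig(), small_graph,
                   chains=0, iters=10, warmup=10, seed=1)


class TestDerived:
    def _const_samples(self, I=3, J=5, S=50, kappa_val=0.0, u_val=0.0):
        spec = ModelSpec.selected()
        draws = {
            "alpha": np.zeros((1, S, 2)),
            "log_delta": np.zeros((1, S)),
            "kappa": np.full((1, S, I, 2), kappa_val),
            "u": np.full((1, S, 1, I), u_val),
            "eta": np.zeros((1, S, 2, J)),
            "tau_kappa": np.ones((1, S)),
            "tau_u": np.ones((1, S)),
            "tau_eta": np.ones((1, S)),
        }
        return make_samples(spec, draws)

    def _flat_data(self, I=3, J=5):
        n = np.full((2, I, 2, J), 1000.0)
        return CountData(O=np.zeros_like(n, dtype=int), n=n,
                         area_ids=tuple(f"a{i}" for i in range(I)))

    def test_zero_state_rate_is_100k(self):
        s = self._const_samples()
        rates = sm.derive_rates(s, self._flat_data())
        assert np.all(rates == 1e5)

    def test_shared_pattern_examples(self):
        assert np.all(sm.derive_shared_pattern(self._const_samples()) == 1e5)
        doubled = self._const_samples(kappa_val=math.log(2.0))
        assert np.allclose(sm.derive_shared_pattern(doubled), 2e5)

    def test_specific_pattern_examples(self):
        halved = self._const_samples(u_val=-math.log(2.0))
        assert np.allclose(sm.derive_specific_pattern(halved), 5e4)

    def test_rates_match_per_draw_recomputation(self, small_fit, small_data):
        data, _ = small_data
        rates = sm.derive_rates(small_fit, data)
        spec = small_fit.spec
        rng = np.random.default_rng(0)
        from sharedmap.inference import state_from_draw
        from sharedmap.model import linear_predictor_field
        for s_idx in rng.choice(small_fit.n_draws, 5, replace=False):
            th = state_from_draw(small_fit, int(s_idx), data.I, data.J)
            expected = np.exp(linear_predictor_field(spec, th, data.I, data.J)) * 1e5
            np.testing.assert_allclose(rates[s_idx], expected, rtol=1e-10)

    def test_median_equals_percentile_of_recomputed_draws(self, small_fit, small_data):
        data, _ = small_data
        rates = sm.derive_rates(small_fit, data)
        table = sm.summarize_rates(small_fit, data)
        med = np.percentile(rates, 50.0, axis=0)
        np.testing.assert_allclose(table["median"].to_numpy(), med.ravel(), rtol=1e-12)


class TestSummarize:
    def test_percentile_convention(self):
        draws = np.arange(1.0, 101.0)
        df = summarize(draws, axis_names=[])
        assert df.loc[0, "median"] == pytest.approx(50.5)
        assert df.loc[0, "ci_low"] == pytest.approx(3.475)
        assert df.loc[0, "ci_high"] == pytest.approx(97.525)

    def test_constant_draws(self):
        df = summarize(np.full(200, 7.0), axis_names=[])
        assert (df.loc[0, ["median", "ci_low", "ci_high"]] == 7.0).all()

    def test_standard_normal_asymptotics(self):
        rng = np.random.default_rng(12)
        df = summarize(rng.standard_normal(100_000), axis_names=[])
        assert abs(df.loc[0, "median"]) < 0.02
        assert df.loc[0, "ci_low"] == pytest.approx(-1.96, abs=0.05)
        assert df.loc[0, "ci_high"] == pytest.approx(1.96, abs=0.05)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="draws"):
            summarize(np.arange(10.0), axis_names=[])

    def test_interval_ordering_invariant(self):
        rng = np.random.default_rng(13)
        df = summarize(rng.gamma(2, size=(500, 4, 3)),
                       axis_names=["a", "b"])
        assert (df["ci_low"] <= df["median"]).all()
        assert (df["median"] <= df["ci_high"]).all()
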