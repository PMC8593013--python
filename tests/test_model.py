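"""Likelihood, linear predictors, priors and constraints."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

import sharedmap as sm
from sharedmap.model import (
    CountData,
    ModelSpec,
    ParameterState,
    PriorConfig,
    apply_constraints,
    linear_predictor,
    linear_predictor_field,
    log_likelihood,
    log_prior,
    loggamma_logpdf,
    pc_prior_logdensity,
    zero_state,
)


def _random_state(spec, I, J, rng, scale=0.5):
    th = zero_state(spec, I, J)
    th.alpha = rng.normal(0, scale, 2)
    th.log_delta = rng.normal(0, 0.2)
    if th.kappa is not None:
        th.kappa = rng.normal(0, scale, th.kappa.shape)
    if th.u is not None:
        th.u = rng.normal(0, scale, th.u.shape)
    if th.eta is not None:
        th.eta = rng.normal(0, scale, th.eta.shape)
    th.tau_kappa, th.tau_u, th.tau_eta = rng.uniform(0.5, 4, 3)
    return apply_constraints(th, spec)


class TestLinearPredictor:
    def test_all_zero_gives_unit_rate(self):
        spec = ModelSpec.selected()
        th = zero_state(spec, 3, 5)
        lp = linear_predictor_field(spec, th, 3, 5)
        assert np.all(lp == 0.0)

    def test_direct_substitution(self):
        spec = ModelSpec.selected()
        th = zero_state(spec, 2, 5)
        th.log_delta = math.log(2.0)
        th.kappa[:] = 0.5
        assert linear_predictor(spec, th, d=1, i=0, g=1, j=0) == pytest.approx(1.0)
        assert linear_predictor(spec, th, d=2, i=0, g=2, j=0) == pytest.approx(0.25)

    def test_base_model_delta_cancels(self):
        """For the simplest shared model the product of the two diseases'
        log-rates is kappa_i**2 whatever delta is."""
        spec = ModelSpec.base()
        rng = np.random.default_rng(1)
        th = zero_state(spec, 6, 5)
        th.kappa = rng.normal(0, 1, (6, 1))
        th.log_delta = 0.9
        lp = linear_predictor_field(spec, th, 6, 5)
        prod = lp[0] * lp[1]
        expected = (th.kappa[:, 0] ** 2)[:, None, None] * np.ones((6, 2, 5))
        np.testing.assert_allclose(prod, expected, rtol=1e-12)

    def test_dimension_mismatch_rejected(self):
        spec = ModelSpec.selected()
        th = zero_state(spec, 3, 5)
        th.kappa = th.kappa[:, :1]
        with pytest.raises(ValueError, match="kappa"):
            linear_predictor_field(spec, th, 3, 5)


class TestLogLikelihood:
    def _single_cell(self, O, n):
        Oa = np.zeros((2, 1, 2, 1), dtype=int)
        na = np.zeros((2, 1, 2, 1))
        Oa[0, 0, 0, 0], na[0, 0, 0, 0] = O, n
        return CountData(O=Oa, n=na, area_ids=("a",), age_labels=("30-44",))

    def test_zero_count_closed_form(self):
        spec = ModelSpec(shared_spatial="none", specific_unstructured=frozenset(),
                         age_effect="none", intercepts=True)
        data = self._single_cell(0, 1000.0)
        th = zero_state(spec, 1, 1)
        th.alpha[:] = math.log(0.001)
        assert log_likelihood(data, spec, th) == pytest.approx(-1.0)

    def test_poisson_closed_form(self):
        spec = ModelSpec(shared_spatial="none", specific_unstructured=frozenset(),
                         age_effect="none", intercepts=True)
        data = self._single_cell(3, 100.0)
        th = zero_state(spec, 1, 1)
        th.alpha[:] = math.log(0.03)
        expected = 3 * math.log(3) - 3 - math.log(6)
        assert log_likelihood(data, spec, th) == pytest.approx(expected, rel=1e-12)

    def test_matches_naive_loop_oracle(self):
        spec = ModelSpec.selected()
        rng = np.random.default_rng(3)
        I, J = 4, 5
        n = rng.uniform(100, 5000, (2, I, 2, J))
        n[0, 1, 0, 2] = 0.0
        O = rng.poisson(n * 5e-3)
        data = CountData(O=O, n=n, area_ids=tuple(f"a{i}" for i in range(I)))
        th = _random_state(spec, I, J, rng)
        vec = log_likelihood(data, spec, th)
        naive = 0.0
        for d in range(2):
            for i in range(I):
                for g in range(2):
                    for j in range(J):
                        if n[d, i, g, j] == 0:
                            continue
                        lp = linear_predictor(spec, th, d + 1, i, g + 1, j)
                        mu = n[d, i, g, j] * math.exp(lp)
                        naive += stats.poisson.logpmf(O[d, i, g, j], mu)
        assert vec == pytest.approx(naive, abs=1e-12 * abs(naive))

    def test_deaths_without_population_rejected(self):
        O = np.ones((2, 1, 2, 1), dtype=int)
        n = np.zeros((2, 1, 2, 1))
        with pytest.raises(ValueError, match="zero population"):
            CountData(O=O, n=n, area_ids=("a",), age_labels=("x",))

    def test_unimodal_in_single_count(self):
        """At fixed parameters the likelihood falls as one count moves away
        from its mean."""
        spec = ModelSpec.selected()
        rng = np.random.default_rng(4)
        I, J = 3, 5
        n = rng.uniform(1000, 2000, (2, I, 2, J))
        th = _random_state(spec, I, J, rng, scale=0.2)
        mu = n * np.exp(linear_predictor_field(spec, th, I, J))
        O = np.round(mu).astype(int)
        cell = (1, 2, 0, 3)
        lls = []
        for shift in (0, 2, 5, 9):
            Om = O.copy()
            Om[cell] += shift
            data = CountData(O=Om, n=n, area_ids=tuple("abc"))
            lls.append(log_likelihood(data, spec, th))
        assert all(a > b for a, b in zip(lls, lls[1:]))

    def test_delta_inversion_symmetry_base_model(self):
        """Swapping the diseases and inverting delta is a likelihood symmetry
        of the simplest shared model."""
        spec = ModelSpec.base()
        rng = np.random.default_rng(5)
        I, J = 5, 5
        n = rng.uniform(500, 5000, (2, I, 2, J))
        O = rng.poisson(n * 2e-3)
        th = _random_state(spec, I, J, rng)
        data = CountData(O=O, n=n, area_ids=tuple(f"a{i}" for i in range(I)))
        swapped = CountData(O=O[::-1].copy(), n=n[::-1].copy(),
                            area_ids=data.area_ids)
        th_swap = th.copy()
        th_swap.log_delta = -th.log_delta
        assert log_likelihood(data, spec, th) == log_likelihood(swapped, spec, th_swap)


class TestPcPrior:
    def test_direct_substitution(self):
        # U=1, alpha=e^-1 -> lam=1; at tau=1: log(1/2) - 1
        val = pc_prior_logdensity(1.0, 1.0, math.exp(-1))
        assert val == pytest.approx(math.log(0.5) - 1.0)

    def test_integrates_to_one(self):
        total, _ = integrate.quad(
            lambda t: math.exp(pc_prior_logdensity(t, 1.0, 0.01)), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            pc_prior_logdensity(1.0, 1.0, 1.5)


class TestLogPrior:
    def test_zero_kappa_kernel_vanishes(self, small_graph):
        struct = sm.icar_structure(small_graph)
        spec = ModelSpec.selected()
        th = zero_state(spec, small_graph.n_areas, 5)
        # difference in tau_kappa enters only through the normalising term
        th1, th2 = th.copy(), th.copy()
        th1.tau_kappa, th2.tau_kappa = 1.0, 4.0
        K = struct.rank
        diff = (log_prior(th2, spec, PriorConfig(), struct)
                - log_prior(th1, spec, PriorConfig(), struct))
        expected = (spec.n_kappa_cols * 0.5 * K * math.log(4.0)
                    + PriorConfig().precision_logpdf(4.0, "kappa")
                    - PriorConfig().precision_logpdf(1.0, "kappa"))
        assert diff == pytest.approx(expected, rel=1e-12)

    def test_iid_normal_closed_form(self):
        spec = ModelSpec(shared_spatial="none", specific_unstructured=frozenset({2}),
                         age_effect="none", intercepts=False)
        th = zero_state(spec, 3, 5)
        pri = PriorConfig()
        got = log_prior(th, spec, pri, None)
        expected = 3 * (-0.5 * math.log(2 * math.pi)) + pri.precision_logpdf(1.0, "u")
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_dense_oracle(self, small_graph):
        """Every term re-derived independently with scipy distributions."""
        struct = sm.icar_structure(small_graph)
        spec = ModelSpec.selected()
        rng = np.random.default_rng(6)
        I = small_graph.n_areas
        th = _random_state(spec, I, 5, rng)
        pri = PriorConfig()
        got = log_prior(th, spec, pri, struct)

        A, lam = struct.eigenbasis()
        oracle = 0.0
        for d in range(2):  # intercepts
            oracle += stats.norm.logpdf(th.alpha[d], 0, 0.001 ** -0.5)
        for c in range(2):  # ICAR via spectral coordinates
            z = A.T @ th.kappa[:, c]
            oracle += np.sum(stats.norm.logpdf(z, 0, (th.tau_kappa * lam) ** -0.5))
        oracle += np.sum(stats.norm.logpdf(th.u, 0, th.tau_u ** -0.5))
        oracle += np.sum(stats.norm.logpdf(th.eta, 0, th.tau_eta ** -0.5))
        oracle += pri.precision_logpdf(th.tau_kappa, "kappa")
        oracle += pri.precision_logpdf(th.tau_u, "u")
        oracle += pri.precision_logpdf(th.tau_eta, "eta")
        oracle += loggamma_logpdf(th.log_delta, 10.0, 10.0)
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_families_differ_only_in_hyperprior_terms(self, small_graph):
        struct = sm.icar_structure(small_graph)
        spec = ModelSpec.selected()
        th = _random_state(spec, small_graph.n_areas, 5, np.random.default_rng(8))
        pc = PriorConfig(precision_prior="pc")
        un = PriorConfig(precision_prior="uniform_sd")
        diff = log_prior(th, spec, pc, struct) - log_prior(th, spec, un, struct)
        expected = sum(
            pc.precision_logpdf(tau, w) - un.precision_logpdf(tau, w)
            for tau, w in ((th.tau_kappa, "kappa"), (th.tau_u, "u"), (th.tau_eta, "eta"))
        )
        assert diff == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_precision_rejected(self, small_graph):
        struct = sm.icar_structure(small_graph)
        spec = ModelSpec.selected()
        th = zero_state(spec, small_graph.n_areas, 5)
        th.tau_u = -1.0
        with pytest.raises(ValueError, match="tau_u"):
            log_prior(th, spec, PriorConfig(), struct)


class TestConstraints:
    def test_centring_example(self):
        spec = ModelSpec.selected()
        th = zero_state(spec, 3, 5)
        th.kappa[:, 0] = [1.0, 2.0, 3.0]
        out = apply_constraints(th, spec)
        np.testing.assert_allclose(out.kappa[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        spec = ModelSpec.selected()
        th = _random_state(spec, 5, 5, np.random.default_rng(9))
        once = apply_constraints(th, spec)
        twice = apply_constraints(once, spec)
        np.testing.assert_allclose(twice.kappa, once.kappa, atol=1e-14)
        np.testing.assert_allclose(twice.eta, once.eta, atol=1e-14)

    def test_random_state_sums_to_zero(self):
        spec = ModelSpec.selected()
        rng = np.random.default_rng(10)
        th = zero_state(spec, 7, 5)
        th.kappa = rng.normal(2, 1, th.kappa.shape)
        th.eta = rng.normal(-1, 1, th.eta.shape)
        out = apply_constraints(th, spec)
        assert np.all(np.abs(out.kappa.sum(axis=0)) <= 1e-12)
        assert abs(out.eta.sum()) <= 1e-12

    def test_per_component_centring(self):
        spec = ModelSpec.selected()
        th = zero_state(spec, 4, 5)
        th.kappa[:, 0] = [1.0, 3.0, 10.0, 20.0]
        labels = np.array([0, 0, 1, 1])
        out = apply_constraints(th, spec, component_labels=labels)
        np.testing.assert_allclose(out.kappa[:2, 0], [-1.0, 1.0])
        np.testing.assert_allclose(out.kappa[2:, 0], [-5.0, 5.0])


class TestConfigs:
    def test_spec_round_trip(self):
        for spec in (ModelSpec.base(), ModelSpec.selected(),
                     ModelSpec(shared_spatial="common", age_effect="by_age")):
            assert ModelSpec.from_dict(spec.to_dict()) == spec

    def test_prior_round_trip(self):
        pri = PriorConfig(precision_prior="loggamma_logprec",
                          precision_params=(1.0, 5e-5),
                          delta_prior=(10.0, 10.0),
                          intercept_prior=("loggamma", (2.0, 500.0)))
        assert PriorConfig.from_dict(pri.to_dict()) == pri

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(shared_spatial="sometimes")
        with pytest.raises(ValueError):
            ModelSpec(specific_unstructured=frozenset({3}))
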