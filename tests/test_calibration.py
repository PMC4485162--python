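"""Likelihood contracts, the Metropolis sampler, and posterior mechanics."""

import math

import numpy as np
import pytest
from scipy import stats

from xyleth.calibration import (ErrorModel, PBPKCalibration, log_likelihood,
                                run_mcmc)
from xyleth.parameters import ParameterSet
from xyleth.simulate import SolverConfig, default_study_scenario
from xyleth.synth import AssaySpec, generate_bm

SQRT2PI = math.sqrt(2.0 * math.pi)


class TestLogLikelihood:
    def _one_channel(self, obs, pred, sigma=0.5):
        t = np.arange(len(obs), dtype=float)
        return log_likelihood({"c": (t, np.asarray(obs, float))},
                              {"c": np.asarray(pred, float)}, {"c": sigma})

    def test_perfect_fit_attains_maximum(self):
        obs = [1.0, 2.0, 3.0]
        got = self._one_channel(obs, obs, sigma=0.5)
        assert got == pytest.approx(-3 * math.log(0.5 * SQRT2PI))

    def test_scale_invariance_of_log_residuals(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.array([1.1, 1.9, 3.2])
        assert self._one_channel(obs, pred) == pytest.approx(
            self._one_channel(2 * obs, 2 * pred))

    def test_unit_log_residual(self):
        got = self._one_channel([math.e], [1.0], sigma=1.0)
        assert got == pytest.approx(-0.5 - math.log(SQRT2PI))

    def test_nonpositive_prediction_is_impossible(self):
        assert self._one_channel([1.0], [0.0]) == -np.inf

    def test_below_lod_drop_vs_censor(self):
        t = np.array([0.0, 1.0])
        obs = np.array([0.05, 2.0])
        pred = np.array([0.2, 2.0])
        flags = {"c": np.array([True, False])}
        dropped = log_likelihood({"c": (t, obs)}, {"c": pred}, {"c": 0.5},
                                 lods={"c": 0.1}, below_lod=flags, lod_mode="drop")
        assert dropped == pytest.approx(-math.log(0.5 * SQRT2PI))
        censored = log_likelihood({"c": (t, obs)}, {"c": pred}, {"c": 0.5},
                                  lods={"c": 0.1}, below_lod=flags,
                                  lod_mode="censor")
        extra = stats.norm.logcdf((math.log(0.1) - math.log(0.2)) / 0.5)
        assert censored == pytest.approx(dropped + extra)


class TestSampler:
    @staticmethod
    def _lognormal_target(mu, sd):
        def lp(theta):
            z = np.log(theta)
            return float(-0.5 * np.sum(((z - mu) / sd) ** 2) - z.sum())
        return lp

    def test_recovers_analytic_moments(self):
        mu = np.array([0.0, 1.0, -0.5])
        sd = np.array([0.3, 0.2, 0.4])
        trace = run_mcmc(self._lognormal_target(mu, sd), init=np.exp(mu),
                         scales=np.full(3, 0.4), n_iter=20000, n_chains=2,
                         seed=0)
        z = np.log(trace.chains.reshape(-1, 3))
        ess = 400.0  # conservative effective-sample floor for the MC error
        assert np.all(np.abs(z.mean(axis=0) - mu) < 3 * sd / math.sqrt(ess))
        assert np.allclose(z.std(axis=0, ddof=1), sd, rtol=0.1)

    def test_seed_reproducibility(self):
        lp = self._lognormal_target(np.zeros(2), np.ones(2))
        kw = dict(init=np.ones(2), scales=np.full(2, 0.5), n_iter=500,
                  n_chains=2, seed=42)
        a = run_mcmc(lp, **kw)
        b = run_mcmc(lp, **kw)
        assert np.array_equal(a.chains, b.chains)

    def test_acceptance_falls_with_scale(self):
        lp = self._lognormal_target(np.zeros(2), np.full(2, 0.2))
        small = run_mcmc(lp, init=np.ones(2), scales=np.full(2, 0.05),
                         n_iter=1000, seed=1, adapt=False, n_chains=1)
        large = run_mcmc(lp, init=np.ones(2), scales=np.full(2, 1.0),
                         n_iter=1000, seed=1, adapt=False, n_chains=1)
        assert large.accept_rate[0] < small.accept_rate[0]
        assert 0.0 < small.accept_rate[0] < 1.0

    def test_stuck_chain_raises(self):
        lp = self._lognormal_target(np.zeros(1), np.full(1, 1e-4))
        with pytest.raises(RuntimeError, match="proposal"):
            run_mcmc(lp, init=np.ones(1), scales=np.full(1, 500.0),
                     n_iter=1000, seed=2, adapt=False, n_chains=1)

    def test_bad_inputs(self):
        lp = self._lognormal_target(np.zeros(1), np.ones(1))
        with pytest.raises(ValueError):
            run_mcmc(lp, init=np.ones(1), scales=np.array([-1.0]), n_iter=500)
        with pytest.raises(ValueError):
            run_mcmc(lp, init=np.array([-2.0]), scales=np.ones(1), n_iter=500)


@pytest.fixture(scope="module")
def noiseless_dataset():
    base = ParameterSet.central()
    scen = default_study_scenario(with_ethanol=True)
    return generate_bm(base, scen, assay=AssaySpec.uniform_cv(0.0), seed=0), base


class TestPosterior:
    def test_prior_support_boundaries(self, noiseless_dataset):
        ds, base = noiseless_dataset
        model = PBPKCalibration(ds, base_params=base,
                                error_model=ErrorModel(sigma={
                                    c: 0.1 for c in ds.channels}))
        assert model.log_prior(np.array([34.0, 18.5, 25.0])) == -np.inf  # KI > 20
        assert np.isfinite(model.log_prior(np.array([34.0, 18.5, 6.57])))

    def test_posterior_reduces_to_prior_without_likelihood(self, noiseless_dataset):
        ds, base = noiseless_dataset
        model = PBPKCalibration(ds, base_params=base,
                                error_model=ErrorModel(sigma={
                                    c: 0.1 for c in ds.channels}))
        theta = np.array([34.0, 18.5, 6.57])
        assert model.logposterior(theta) == pytest.approx(
            model.log_prior(theta) + model.loglike(theta))

    def test_self_consistency_at_truth(self, noiseless_dataset):
        # noiseless data generated at theta0: the likelihood peaks there
        ds, base = noiseless_dataset
        model = PBPKCalibration(ds, base_params=base,
                                error_model=ErrorModel(sigma={
                                    c: 0.1 for c in ds.channels}))
        theta0 = np.array([34.0, 18.5, 10.0])   # the generating values
        ll0 = model.loglike(theta0)
        for pert in ([1.2, 1.0, 1.0], [1.0, 0.8, 1.0], [1.0, 1.0, 1.7]):
            assert model.loglike(theta0 * np.array(pert)) < ll0

    def test_ki_unidentified_without_ethanol_arm(self):
        base = ParameterSet.central()
        scen = default_study_scenario(with_ethanol=False)
        ds = generate_bm(base, scen, assay=AssaySpec.uniform_cv(0.0), seed=0)
        model = PBPKCalibration(ds, base_params=base,
                                error_model=ErrorModel(sigma={
                                    c: 0.1 for c in ds.channels}))
        ll = [model.loglike(np.array([34.0, 18.5, ki])) for ki in (2.0, 15.0)]
        assert ll[0] == pytest.approx(ll[1], rel=1e-9)

    def test_modal_set_is_trace_argmax(self, noiseless_dataset):
        ds, base = noiseless_dataset
        model = PBPKCalibration(ds, base_params=base,
                                error_model=ErrorModel(sigma={
                                    c: 0.1 for c in ds.channels}),
                                solver=SolverConfig(dense_dt=0.5))
        res = model.fit(n_iter=300, n_chains=2, seed=3)
        modal = res.modal_parameters
        theta = np.array([modal[n] for n in res.names])
        # the recorded maximum is attained by the extracted parameter set
        assert model.logposterior(theta) == pytest.approx(res.max_logpost)
        assert res.max_logpost == res.trace.logpost.max()
        assert np.all((0 < res.acceptance_rate) & (res.acceptance_rate < 1))

    def test_chains_respect_prior_support(self, noiseless_dataset):
        ds, base = noiseless_dataset
        model = PBPKCalibration(ds, base_params=base,
                                error_model=ErrorModel(sigma={
                                    c: 0.1 for c in ds.channels}),
                                solver=SolverConfig(dense_dt=0.5))
        res = model.fit(n_iter=300, n_chains=2, seed=4)
        ki = res.chains[:, :, res.names.index("KI")]
        assert ki.min() >= 1.0 and ki.max() <= 20.0
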