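"""Morris and eFAST estimators against closed-form oracles; Lowry structure."""

import numpy as np
import pytest

from xyleth.parameters import PriorSpec
from xyleth.sensitivity import (FastResult, efast, lowry, morris_screen,
                                select_for_efast, timewise_sa)


def uniform(name, lo, hi):
    return PriorSpec(name=name, family="uniform", central=(lo + hi) / 2,
                     lower=lo, upper=hi)


UNIT3 = {f"x{i}": uniform(f"x{i}", 0.0, 1.0) for i in (1, 2, 3)}
ISHIGAMI_PRIORS = {f"x{i}": uniform(f"x{i}", -np.pi, np.pi) for i in (1, 2, 3)}

# closed-form Ishigami variance decomposition (a=7, b=0.1)
_A, _B = 7.0, 0.1
_V1 = 0.5 * (1.0 + _B * np.pi**4 / 5.0) ** 2
_V2 = _A**2 / 8.0
_V13 = _B**2 * np.pi**8 * (1.0 / 18.0 - 1.0 / 50.0)
_V = _V1 + _V2 + _V13
ISHIGAMI_S = np.array([_V1 / _V, _V2 / _V, 0.0])
ISHIGAMI_ST = np.array([(_V1 + _V13) / _V, _V2 / _V, _V13 / _V])


def ishigami(x):
    return np.sin(x[0]) + _A * np.sin(x[1]) ** 2 + _B * x[2] ** 4 * np.sin(x[0])


class TestMorris:
    def test_linear_function_recovers_coefficients(self):
        res = morris_screen(lambda x: 3.0 * x[0] + x[1], UNIT3, r=10, p=4, seed=0)
        mu = res.mu_star.ravel()
        assert mu[0] / mu[1] == pytest.approx(3.0, rel=1e-9)
        assert mu[2] == 0.0                       # unused parameter: exactly zero
        assert np.all(res.sigma.ravel() < 1e-9)   # linear => no dispersion

    def test_g_function_ranking(self):
        a = [0.0, 0.5, 3.0, 9.0, 99.0]
        priors = {f"x{i}": uniform(f"x{i}", 0.0, 1.0) for i in range(5)}

        def g(x):
            return np.prod([(abs(4 * x[i] - 2) + a[i]) / (1 + a[i])
                            for i in range(5)])

        res = morris_screen(g, priors, r=20, p=4, seed=1)
        assert np.all(np.diff(res.mu_star.ravel()) < 0)  # descending with a

    def test_too_few_trajectories_raise(self):
        with pytest.raises(ValueError, match="trajectories"):
            morris_screen(lambda x: x[0], UNIT3, r=1)


class TestSelection:
    def test_identity_selection(self):
        res = morris_screen(lambda x: 3.0 * x[0] + x[1], UNIT3, r=4, p=4, seed=0)
        assert set(select_for_efast(res, k=3)) == set(UNIT3)

    def test_top1_is_strongest(self):
        res = morris_screen(lambda x: 3.0 * x[0] + x[1], UNIT3, r=4, p=4, seed=0)
        assert select_for_efast(res, k=1) == ["x1"]

    def test_ties_broken_by_order(self):
        res = morris_screen(lambda x: x[0] + x[1] + x[2], UNIT3, r=4, p=4, seed=0)
        assert select_for_efast(res, k=2) == ["x1", "x2"]

    def test_k_too_large_raises(self):
        res = morris_screen(lambda x: x[0], UNIT3, r=4, p=4, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            select_for_efast(res, k=5)


class TestEfast:
    def test_single_active_input(self):
        res = efast(lambda x: x[0], UNIT3, N=257, M=4, Nr=2, seed=0)
        assert res.si[0] == pytest.approx(1.0, abs=0.02)
        assert res.sti[0] == pytest.approx(1.0, abs=0.02)
        assert np.all(res.si[1:] < 0.02)

    def test_additive_function_has_no_interactions(self):
        res = efast(lambda x: 2 * x[0] + np.sin(2 * x[1]) + x[2] ** 2,
                    UNIT3, N=513, M=4, Nr=2, seed=1)
        assert np.all(res.sti - res.si < 0.03)
        assert res.si.sum() == pytest.approx(1.0, abs=0.05)

    def test_ishigami_oracle(self):
        res = efast(ishigami, ISHIGAMI_PRIORS, N=1025, M=4, Nr=5, seed=2)
        assert np.allclose(res.si, ISHIGAMI_S, atol=0.03)
        assert res.sti[2] == pytest.approx(ISHIGAMI_ST[2], abs=0.03)

    def test_convergence_with_n(self):
        # the typical estimation error at least halves from N=65 to N=1025
        # (averaged over independent random-phase designs; a single design
        # can land close to the truth by chance at small N)
        errs = {}
        for n in (65, 1025):
            per_seed = [np.max(np.abs(
                efast(ishigami, ISHIGAMI_PRIORS, N=n, M=4, Nr=5, seed=s).si
                - ISHIGAMI_S)) for s in range(5)]
            errs[n] = np.mean(per_seed)
        assert errs[1025] <= errs[65] / 2.0

    def test_si_bounded_by_sti(self):
        res = efast(ishigami, ISHIGAMI_PRIORS, N=257, M=4, Nr=3, seed=4)
        assert np.all(res.si <= res.sti + 0.02)
        assert res.si.sum() <= 1.02

    def test_seed_determinism(self):
        a = efast(ishigami, ISHIGAMI_PRIORS, N=129, Nr=2, seed=9)
        b = efast(ishigami, ISHIGAMI_PRIORS, N=129, Nr=2, seed=9)
        assert np.array_equal(a.si, b.si) and np.array_equal(a.sti, b.sti)

    def test_aliasing_guard(self):
        with pytest.raises(ValueError, match="too small"):
            efast(ishigami, ISHIGAMI_PRIORS, N=5, M=4)

    def test_morris_and_efast_agree_on_top_parameters(self):
        a = [0.0, 0.5, 3.0, 9.0, 99.0]
        priors = {f"x{i}": uniform(f"x{i}", 0.0, 1.0) for i in range(5)}

        def g(x):
            return np.prod([(abs(4 * x[i] - 2) + a[i]) / (1 + a[i])
                            for i in range(5)])

        m = morris_screen(g, priors, r=20, p=4, seed=5)
        f = efast(g, priors, N=513, Nr=2, seed=5)
        top_m = [m.names[i] for i in np.argsort(-m.score().values)[:3]]
        top_f = [f.names[i] for i in np.argsort(-f.sti)[:3]]
        assert set(top_m) == set(top_f) == {"x0", "x1", "x2"}


class TestTimewise:
    def test_pre_exposure_indices_missing_and_design_reuse(self, central_params):
        from xyleth.simulate import ExposureScenario, SolverConfig
        from xyleth.parameters import parameter_catalogue

        scen = ExposureScenario(exposure_ppm=50.0, exposure_start=1.0)
        cat = parameter_catalogue()
        priors = {n: cat[n] for n in ("PBAXYL", "QPMC", "BW")}
        kw = dict(channels=["cv_xyl"], windows={"cv_xyl": (0.0, 2.0)},
                  grid_dt=0.5, N=65, M=4, Nr=1,
                  solver=SolverConfig(dense_dt=0.5),
                  quantile_bounds=(0.005, 0.995))
        res = timewise_sa(central_params, priors, scen, seed=0, **kw)["cv_xyl"]
        pre = res.times < 1.0
        assert np.isnan(res.si[:, pre]).all()     # zero variance -> missing
        assert np.isfinite(res.si[:, ~pre]).all()
        again = timewise_sa(central_params, priors, scen, seed=0, **kw)["cv_xyl"]
        assert np.array_equal(res.si, again.si, equal_nan=True)


class TestLowry:
    def test_plume_invariants_on_ishigami(self):
        res = efast(ishigami, ISHIGAMI_PRIORS, N=1025, M=4, Nr=5, seed=6)
        ld = lowry(res)
        assert np.all(ld.cum_lower <= ld.cum_upper + 1e-12)
        assert np.all(np.diff(ld.cum_lower) >= -1e-12)
        assert np.all(np.diff(ld.cum_upper) >= -1e-12)
        assert ld.cum_lower[-1] == pytest.approx(np.clip(res.si, 0, 1).sum())
        # interaction mass sits on x1 and x3 (closed form: ~0.24 each)
        inter = dict(zip(ld.names, ld.interaction))
        assert inter["x1"] == pytest.approx(_V13 / _V, abs=0.05)
        assert inter["x3"] == pytest.approx(_V13 / _V, abs=0.05)
        assert inter["x2"] < 0.08

    def test_no_interaction_gives_zero_width(self):
        fr = FastResult(names=["a", "b"], si=np.array([0.6, 0.4]),
                        sti=np.array([0.6, 0.4]))
        ld = lowry(fr)
        assert np.allclose(ld.interaction, 0.0)
        assert np.allclose(ld.cum_lower, ld.cum_upper)

    def test_single_dominant_parameter(self):
        fr = FastResult(names=["a"], si=np.array([1.0]), sti=np.array([1.0]))
        ld = lowry(fr)
        assert ld.cum_lower[0] == ld.cum_upper[0] == pytest.approx(1.0)

    def test_missing_indices_raise(self):
        fr = FastResult(names=["a"], si=np.array([[np.nan]]),
                        sti=np.array([[np.nan]]), times=np.array([1.0]))
        with pytest.raises(ValueError, match="missing"):
            lowry(fr, time=1.0)

    def test_plot_smoke(self):
        import matplotlib

        matplotlib.use("Agg")
        from xyleth.sensitivity import plot_lowry

        fr = FastResult(names=["a", "b"], si=np.array([0.5, 0.2]),
                        sti=np.array([0.7, 0.3]))
        ax = plot_lowry(lowry(fr))
        assert ax is not None
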