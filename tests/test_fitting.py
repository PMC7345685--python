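"""Constrained estimation: residuals, constraints, AIC, optimizers, recovery."""

import math

import numpy as np
import pytest

from aggkin import (
    FitProblem,
    KineticParams,
    OptimizerSpec,
    Variant,
    aic,
    apply_constraints,
    compare_fits,
    fit,
    pearson_correlation,
    residuals,
)
from aggkin.fitting import ConstraintError, constrained_names, rss_of
from aggkin.synthetic import SyntheticSpec, generate


def _synthetic_problem(true_params, free, seed=0, sigma=0.0, observable="od",
                       t_grid=None, N=10, **problem_kw):
    series, _ = generate(SyntheticSpec(
        true_params=true_params, observable=observable, N=N,
        t_grid=t_grid, sigma=sigma, seed=seed,
    ))
    return FitProblem(
        datasets=[(series, 1.0)], params=true_params, N=N, free=free,
        **problem_kw,
    )


class TestConstraints:
    P = KineticParams(variant=Variant.CLUSTERING,
                      k1=0.4, k2=9.9, k_m1=0.05, k_m2=7.7, p0=1.0)

    def test_mobility(self):
        q = apply_constraints(self.P, {"mobility"})
        assert q.k2 == pytest.approx(0.2)  # k1/2
        assert q.k1 == self.P.k1

    def test_detailed_balance(self):
        q = apply_constraints(self.P, {"detailed_balance"})
        assert q.k_m2 == pytest.approx(9.9 * 0.05 / 0.4)
        assert q.k2 / q.k_m2 == pytest.approx(q.k1 / q.k_m1)

    def test_both_constraints_compose(self):
        q = apply_constraints(self.P, {"mobility", "detailed_balance"})
        assert q.k2 == pytest.approx(0.2)
        # detailed balance uses the constrained k2
        assert q.k_m2 == pytest.approx(0.2 * 0.05 / 0.4)

    def test_detailed_balance_requires_k1(self):
        p = self.P.with_updates(k1=0.0)
        with pytest.raises(ConstraintError):
            apply_constraints(p, {"detailed_balance"})

    def test_unknown_flag_rejected(self):
        with pytest.raises(ValueError):
            apply_constraints(self.P, {"bogus"})

    def test_constrained_names(self):
        assert constrained_names({"mobility"}) == {"k2"}
        assert constrained_names({"detailed_balance"}) == {"k_m2"}
        assert constrained_names(set()) == set()

    def test_constraints_shrink_K(self):
        p = KineticParams(variant=Variant.CLUSTERING, k1=1e-3, k_m1=0.05, p0=1.0)
        full = _synthetic_problem(p, free=("k1", "k2", "k_m1", "k_m2"),
                                  t_grid=np.arange(0.0, 11.0, 1.0))
        tied = _synthetic_problem(p, free=("k1", "k2", "k_m1", "k_m2"),
                                  t_grid=np.arange(0.0, 11.0, 1.0),
                                  constraints=frozenset({"mobility",
                                                         "detailed_balance"}))
        assert full.K == 4
        assert tied.K == 2
        assert set(tied.free) == {"k1", "k_m1"}


class TestResiduals:
    P = KineticParams(variant=Variant.AGGREGATION,
                      k1=0.009, k2=0.0016, k_m1=0.0001, k_m2=8e-7, k3=0.0068,
                      p0=4.8)

    def test_zero_at_truth(self):
        prob = _synthetic_problem(self.P, free=("k1",),
                                  t_grid=np.arange(0.0, 61.0, 1.0))
        r = residuals(prob, self.P)
        assert np.max(np.abs(r)) < 1e-9

    def test_weight_scales_linearly(self):
        series, _ = generate(SyntheticSpec(
            true_params=self.P, t_grid=np.arange(0.0, 31.0, 1.0)))
        wrong = self.P.with_updates(k1=0.02)
        r1 = residuals(FitProblem(datasets=[(series, 1.0)], params=self.P,
                                  free=("k1",)), wrong)
        r3 = residuals(FitProblem(datasets=[(series, 3.0)], params=self.P,
                                  free=("k1",)), wrong)
        assert r3 == pytest.approx(3.0 * r1, rel=1e-12)

    def test_rss_adds_over_datasets(self):
        g = np.arange(0.0, 31.0, 1.0)
        s1, _ = generate(SyntheticSpec(true_params=self.P, t_grid=g))
        s2, _ = generate(SyntheticSpec(true_params=self.P, t_grid=g,
                                       observable="monomers"))
        wrong = self.P.with_updates(k1=0.02)
        rss1 = rss_of(FitProblem(datasets=[(s1, 1.0)], params=self.P,
                                 free=("k1",)), wrong)
        rss2 = rss_of(FitProblem(datasets=[(s2, 1.0)], params=self.P,
                                 free=("k1",)), wrong)
        rss12 = rss_of(FitProblem(datasets=[(s1, 1.0), (s2, 1.0)],
                                  params=self.P, free=("k1",)), wrong)
        assert rss12 == pytest.approx(rss1 + rss2, rel=1e-12)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            FitProblem(datasets=[], params=self.P)
        series, _ = generate(SyntheticSpec(true_params=self.P,
                                           t_grid=np.arange(0.0, 4.0, 1.0)))
        with pytest.raises(ValueError):
            FitProblem(datasets=[(series, 0.0)], params=self.P)
        with pytest.raises(ValueError):
            FitProblem(datasets=[(series, 1.0)], params=self.P,
                       bounds={"k1": (-1.0, 1.0)})


class TestAic:
    def test_worked_example(self):
        # AIC = 2*3 + 50*ln(0.5)
        assert aic(3, 50, 0.5) == pytest.approx(6.0 + 50.0 * math.log(0.5))

    def test_unit_rss(self):
        assert aic(2, 10, 1.0) == pytest.approx(4.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            aic(2, 10, 0.0)
        with pytest.raises(ValueError):
            aic(2, 0, 1.0)

    def test_compare_selects_lower_aic(self):
        from aggkin.fitting import FitResult

        def mk(K, rss):
            return FitResult(
                params=KineticParams(variant=Variant.TWO_EQUATION),
                rss=rss, K=K, n_obs=100, aic=aic(K, 100, rss),
                converged=True, seed=0, constraints=frozenset(), free=(),
            )

        # equal RSS: fewer parameters must win
        cmp_ = compare_fits(mk(5, 0.3), mk(3, 0.3), "big", "small")
        assert cmp_["selected"] == "small"
        assert cmp_["delta_aic"] == pytest.approx(4.0)
        # n mismatch is an error
        b = mk(3, 0.3)
        b.n_obs = 50
        with pytest.raises(ValueError):
            compare_fits(mk(5, 0.3), b)


class TestPearson:
    def test_perfect_and_sign(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_correlation(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_worked(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0])
        assert pearson_correlation(x, y) == pytest.approx(0.5)

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(3), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            pearson_correlation(np.array([1.0]), np.array([2.0]))
        with pytest.raises(ValueError):
            pearson_correlation(np.arange(3.0), np.arange(4.0))


class TestOptimizers:
    TRUE = KineticParams(variant=Variant.TWO_EQUATION,
                         k1=0.009, k2=0.0016, k_m1=0.0061, k_m2=8e-7, k3=0.0014,
                         p0=4.24)

    def _one_param_problem(self, method, seed=0):
        return _synthetic_problem(
            self.TRUE, free=("k2",), t_grid=np.arange(0.0, 301.0, 5.0),
            bounds={"k2": (1e-5, 1e-1)},
            optimizer=OptimizerSpec(method=method, n_starts=16, iterations=30,
                                    swarm_size=12, seed=seed),
        )

    @pytest.mark.parametrize("method", ["multistart", "lm", "pso", "hooke_jeeves"])
    def test_single_parameter_recovery(self, method):
        result = fit(self._one_param_problem(method))
        tol = 0.2 if method in ("random",) else 1e-3
        assert result.params.k2 == pytest.approx(self.TRUE.k2, rel=tol)

    def test_random_search_gets_close(self):
        result = fit(_synthetic_problem(
            self.TRUE, free=("k2",), t_grid=np.arange(0.0, 301.0, 5.0),
            bounds={"k2": (1e-5, 1e-1)},
            optimizer=OptimizerSpec(method="random", n_starts=200, seed=1),
        ))
        assert result.params.k2 == pytest.approx(self.TRUE.k2, rel=0.5)

    def test_seeded_determinism(self):
        a = fit(self._one_param_problem("multistart", seed=7))
        b = fit(self._one_param_problem("multistart", seed=7))
        assert a.params == b.params
        assert a.rss == b.rss
        assert a.to_dict() == b.to_dict()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            fit(self._one_param_problem("annealing"))

    def test_result_bookkeeping(self):
        result = fit(self._one_param_problem("multistart"))
        assert result.K == 1
        assert result.n_obs == 61
        assert result.aic == pytest.approx(aic(1, 61, result.rss))
        d = result.to_dict()
        assert d["free"] == ["k2"]
        assert d["trace"]
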