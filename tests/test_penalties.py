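"""Penalty families: closed forms, gradients, subdifferentials, optimality."""

import numpy as np
import pytest

from foldreg.objective import FitResult
from foldreg.penalties import (
    PenaltySpec,
    check_optimality,
    penalty_components,
    penalty_gradient,
    penalty_value,
    subgradient_bound,
    subgradient_interval,
)
from foldreg.regpath import fit_penalized
from conftest import QuadraticProblem

EPS = 1e-10


class TestClosedForms:
    @pytest.mark.parametrize("spec,r,expected", [
        (PenaltySpec("l1"), [1.0, -2.0], 3.0),
        (PenaltySpec("lq", deformation=0.5), [4.0], 2.0),
        (PenaltySpec("elastic_net", deformation=0.5), [2.0], 3.0),
    ])
    def test_values(self, spec, r, expected):
        assert penalty_value(spec, np.array(r)) == pytest.approx(expected)

    def test_adaptive_lasso_value(self):
        spec = PenaltySpec("adaptive_lasso", deformation=1.0).with_weights_from([2.0])
        assert penalty_value(spec, np.array([1.0])) == pytest.approx(0.5)

    def test_adaptive_lasso_without_weights_errors(self):
        with pytest.raises(ValueError, match="weights"):
            penalty_value(PenaltySpec("adaptive_lasso", deformation=1.0), [1.0])

    @pytest.mark.parametrize("spec,r,expected", [
        (PenaltySpec("l1"), [-3.0], [-1.0]),
        (PenaltySpec("elastic_net", deformation=0.25), [2.0], [0.75 + 1.0]),
    ])
    def test_gradients(self, spec, r, expected):
        assert np.allclose(penalty_gradient(spec, np.array(r)), expected)

    def test_lq_gradient_is_clamped_and_finite(self):
        spec = PenaltySpec("lq", deformation=0.5)  # q = 0.5
        g = penalty_gradient(spec, np.array([1e-12]))
        assert np.isfinite(g[0])
        assert g[0] == pytest.approx(0.5 * EPS ** (-0.5))  # 5e4

    def test_nonnegative_and_zero_at_target(self):
        rng = np.random.default_rng(0)
        specs = [PenaltySpec("l1"), PenaltySpec("lq", deformation=0.3),
                 PenaltySpec("elastic_net", deformation=0.4),
                 PenaltySpec("adaptive_lasso", deformation=0.7).with_weights_from(rng.uniform(0.5, 2, 5))]
        for spec in specs:
            assert penalty_value(spec, np.zeros(5)) == 0.0
            for _ in range(5):
                assert penalty_value(spec, rng.normal(size=5)) >= 0.0

    def test_components_sum_to_value(self):
        rng = np.random.default_rng(4)
        r = rng.normal(size=6)
        for spec in (PenaltySpec("l1"), PenaltySpec("lq", deformation=0.2),
                     PenaltySpec("elastic_net", deformation=0.3),
                     PenaltySpec("adaptive_lasso", deformation=0.5).with_weights_from(r)):
            assert np.sum(penalty_components(spec, r)) == pytest.approx(
                penalty_value(spec, r))


class TestReductionIdentities:
    def test_all_families_reduce_to_l1_at_zero_deformation(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            r = rng.normal(scale=2.0, size=6)
            ref = penalty_value(PenaltySpec("l1"), r)
            assert penalty_value(PenaltySpec("lq", deformation=0.0), r) == pytest.approx(ref)
            assert penalty_value(PenaltySpec("elastic_net", deformation=0.0), r) == pytest.approx(ref)
            al = PenaltySpec("adaptive_lasso", deformation=0.0).with_weights_from(rng.uniform(0.1, 3, 6))
            assert penalty_value(al, r) == pytest.approx(ref)

    def test_elastic_net_alpha_one_is_squared_l2(self):
        rng = np.random.default_rng(2)
        r = rng.normal(size=5)
        assert penalty_value(PenaltySpec("elastic_net", deformation=1.0), r) == \
            pytest.approx(float(np.sum(r ** 2)))

    def test_invalid_deformations_rejected(self):
        with pytest.raises(ValueError):
            PenaltySpec("lq", deformation=1.1)     # q <= 0
        with pytest.raises(ValueError):
            PenaltySpec("elastic_net", deformation=1.5)
        with pytest.raises(ValueError):
            PenaltySpec("adaptive_lasso", deformation=-0.1)


def test_gradient_matches_finite_differences_away_from_zero():
    rng = np.random.default_rng(3)
    r = np.array([0.5, -1.2, 2.0, -0.01])
    h = 1e-7
    for spec in (PenaltySpec("l1"), PenaltySpec("lq", deformation=0.2),
                 PenaltySpec("elastic_net", deformation=0.35),
                 PenaltySpec("adaptive_lasso", deformation=0.8).with_weights_from(r)):
        g = penalty_gradient(spec, r)
        for i in range(r.size):
            rp, rm = r.copy(), r.copy()
            rp[i] += h
            rm[i] -= h
            fd = (penalty_value(spec, rp) - penalty_value(spec, rm)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-6)


class TestSubgradientIntervals:
    def test_l1_interval(self):
        lo, hi = subgradient_interval(PenaltySpec("l1"), np.zeros(2), 0, lam=2.0)
        assert (lo, hi) == (-2.0, 2.0)

    def test_adaptive_lasso_interval(self):
        spec = PenaltySpec("adaptive_lasso", deformation=1.0).with_weights_from([0.25, 1.0])
        lo, hi = subgradient_interval(spec, np.zeros(2), 0, lam=1.0)
        assert hi == pytest.approx(4.0)

    def test_lq_interval_uses_clamped_gradient(self):
        spec = PenaltySpec("lq", deformation=0.2)  # q = 0.8
        lo, hi = subgradient_interval(spec, np.zeros(1), 0, lam=1.0)
        assert hi == pytest.approx(0.8 * EPS ** (-0.2))  # = 80, finite

    def test_interval_requires_effective_zero(self):
        with pytest.raises(ValueError):
            subgradient_interval(PenaltySpec("l1"), np.array([0.5]), 0, lam=1.0)


class TestSoftThreshold:
    """1-D quadratic a (r - b)^2 + lam |r| has the analytic minimizer
    sign(b) * max(0, |b| - lam / (2a))."""

    @pytest.mark.parametrize("a,b,lam", [
        (1.0, 2.0, 1.0), (1.0, 2.0, 6.0), (3.0, -0.8, 2.0), (3.0, -0.8, 10.0),
    ])
    def test_penalized_fit_equals_soft_threshold(self, a, b, lam):
        prob = QuadraticProblem(np.array([[a]]), np.array([b]), n_ref=0)
        expected = np.sign(b) * max(0.0, abs(b) - lam / (2 * a))
        pfit = fit_penalized(prob, PenaltySpec("l1"), lam, np.array([b]))
        assert pfit.r[0] == pytest.approx(expected, abs=1e-6)
        if expected == 0.0:
            assert pfit.r[0] == 0.0  # exactly on the singular manifold

    def test_zero_iff_lambda_exceeds_threshold(self):
        a, b = 1.0, 2.0  # lam_Z = 2ab = 4
        for lam, zero in ((3.9, False), (4.1, True)):
            pfit = fit_penalized(QuadraticProblem(np.array([[a]]), np.array([b])),
                                 PenaltySpec("l1"), lam, np.array([b]))
            assert bool(abs(pfit.r[0]) <= EPS) == zero


def test_lq_does_not_trap_optimizer_at_zero():
    """Fig.-2-style 1-D example: chi2 = (r - 2)^2, lq penalty, small lambda.
    Starting from a small perturbation of zero must escape to the global
    basin near r = 2 in both directions."""
    prob = QuadraticProblem(np.array([[1.0]]), np.array([2.0]), n_ref=0)
    spec = PenaltySpec("lq", deformation=0.5)  # q = 0.5, the worst case shown
    for start in (+0.05, -0.05):
        pfit = fit_penalized(prob, spec, 1.0, np.array([start]), snap_tol=0.01)
        assert pfit.r[0] > 1.5


class TestCheckOptimality:
    def test_plain_gradient_test_at_lambda_zero(self):
        A = np.diag([1.0, 2.0])
        prob = QuadraticProblem(A, np.array([0.3, -0.7]), n_ref=1)
        fit = FitResult(theta=np.array([0.3, -0.7]), chi2=0.0, n_ref=1)
        rep = check_optimality(prob, fit, PenaltySpec("l1"), lam=0.0)
        assert rep.all_ok

    def test_zero_fold_change_dominated_by_penalty(self):
        # a (r - b)^2: gradient at r=0 is -2ab; zero is optimal iff lam >= 2ab
        a, b = 1.0, 2.0
        prob = QuadraticProblem(np.array([[a]]), np.array([b]), n_ref=0)
        fit = FitResult(theta=np.array([0.0]), chi2=a * b * b, n_ref=0)
        assert check_optimality(prob, fit, PenaltySpec("l1"), lam=4.5).all_ok
        assert not check_optimality(prob, fit, PenaltySpec("l1"), lam=3.5).all_ok

    def test_interior_optimum_flagged_when_gradient_large(self):
        prob = QuadraticProblem(np.array([[1.0]]), np.array([2.0]), n_ref=0)
        fit = FitResult(theta=np.array([1.0]), chi2=1.0, n_ref=0)
        rep = check_optimality(prob, fit, PenaltySpec("l1"), lam=0.5)
        assert not rep.all_ok


def test_subgradient_bound_per_family():
    assert subgradient_bound(PenaltySpec("l1"), 0) == 1.0
    assert subgradient_bound(PenaltySpec("elastic_net", deformation=0.3), 0) == pytest.approx(0.7)
    al = PenaltySpec("adaptive_lasso", deformation=1.0).with_weights_from([0.5])
    assert subgradient_bound(al, 0) == pytest.approx(2.0)
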