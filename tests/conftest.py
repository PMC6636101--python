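"""Shared toy problems and independent oracles for the test suite."""

import numpy as np
import pytest

from foldreg.ode_core import Condition, ObservationMap, OdeModel, ParameterDef
from foldreg.objective import MeasurementSet, TwoCellTypeProblem, chi2_ml
from foldreg.penalties import PenaltySpec
from foldreg.regpath import chi2_quantile
import pandas as pd


class QuadraticProblem:
    """chi2(theta) = (theta - mu)^T A (theta - mu) + c, split into (ref, fold).

    A closed-form stand-in for the ODE likelihood: same interface
    (n_ref / n_fold / lower / upper / chi2), everything analytic.
    """

    def __init__(self, A, mu, n_ref=0, c=0.0, lower=None, upper=None):
        self.A = np.asarray(A, dtype=float)
        self.mu = np.asarray(mu, dtype=float)
        self.n_ref = n_ref
        self.n_fold = self.mu.size - n_ref
        self.c = float(c)
        dim = self.mu.size
        self.lower = np.full(dim, -10.0) if lower is None else np.asarray(lower, float)
        self.upper = np.full(dim, 10.0) if upper is None else np.asarray(upper, float)

    def chi2(self, theta):
        d = np.asarray(theta, dtype=float) - self.mu
        g = 2.0 * self.A @ d
        return float(d @ self.A @ d) + self.c, g


def l1_quadratic_oracle(A, mu, lam):
    """Exact minimizer of (r-mu)^T A (r-mu) + lam * ||r||_1 by enumeration.

    Enumerates zero subsets and sign patterns of the free coordinates,
    solves the stationarity system in closed form, keeps KKT-valid
    candidates and returns (r, value, zero_set).
    """
    A = np.asarray(A, float)
    mu = np.asarray(mu, float)
    n = mu.size
    best = None
    for zmask in range(2 ** n):
        Z = [i for i in range(n) if (zmask >> i) & 1]
        F = [i for i in range(n) if i not in Z]
        for smask in range(2 ** len(F)):
            s = np.array([1.0 if (smask >> k) & 1 else -1.0 for k in range(len(F))])
            r = np.zeros(n)
            if F:
                # grad_F = 2[A_FF (r_F - mu_F) - A_FZ mu_Z] + lam s = 0
                AFF = A[np.ix_(F, F)]
                AFZ_muZ = A[np.ix_(F, Z)] @ mu[Z] if Z else np.zeros(len(F))
                r_f = np.linalg.solve(AFF, AFF @ mu[F] + AFZ_muZ - lam * s / 2.0)
                if np.any(np.sign(r_f) != s):
                    continue
                r[F] = r_f
            d = r - mu
            grad = 2.0 * A @ d
            if Z and np.any(np.abs(grad[Z]) > lam * (1 + 1e-9)):
                continue
            val = float(d @ A @ d) + lam * float(np.sum(np.abs(r)))
            if best is None or val < best[1] - 1e-12:
                best = (r, val, frozenset(Z))
    return best


@pytest.fixture(scope="session")
def decay_model():
    """dx/dt = -k x, x(0) = x0: the simplest closed-form test system."""
    return OdeModel(
        state_names=["x"],
        rate_exprs=["-k * x"],
        parameters=[ParameterDef("k", lb=-3, ub=2), ParameterDef("x0", role="p0", lb=-2, ub=1)],
        initial=["x0"],
    )


@pytest.fixture(scope="session")
def cascade_model():
    """Linear two-state cascade dx1 = -k1 x1, dx2 = k1 x1 - k2 x2."""
    return OdeModel(
        state_names=["x1", "x2"],
        rate_exprs=["-k1 * x1", "k1 * x1 - k2 * x2"],
        parameters=[ParameterDef("k1", lb=-3, ub=2), ParameterDef("k2", lb=-3, ub=2),
                    ParameterDef("a0", role="p0", lb=-2, ub=1)],
        initial=["a0", 0.0],
    )


def make_cascade_problem(noise_sd=0.05, r_true=(0.5, 0.0), seed=11, n_times=8,
                         penalized=("k1", "k2"), noisy=True):
    """Two-cell-type estimation problem on the linear cascade.

    Cell type 1 differs by the log10 fold-changes r_true on (k1, k2); data
    for both observables on a uniform grid with known Gaussian noise.
    """
    model = OdeModel(
        state_names=["x1", "x2"],
        rate_exprs=["-k1 * x1", "k1 * x1 - k2 * x2"],
        parameters=[ParameterDef("k1", lb=-2, ub=1), ParameterDef("k2", lb=-2, ub=1),
                    ParameterDef("a0", role="p0", lb=-1, ub=1)],
        initial=["a0", 0.0],
    )
    obs = ObservationMap(observable_names=["obs1", "obs2"], exprs=["x1", "x2"])
    truth_ref = {"k1": 0.0, "k2": np.log10(0.5), "a0": 0.0}
    names = model.param_names
    ref = np.array([truth_ref[n] for n in names])
    rvec = dict(zip(penalized, r_true))
    full1 = ref.copy()
    for pname, rv in rvec.items():
        full1[names.index(pname)] += rv
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, 6.0, n_times)
    rows = []
    from foldreg.ode_core import simulate
    for ct, logp in ((0, ref), (1, full1)):
        traj = simulate(model, logp, Condition(), times)
        for j, oname in enumerate(obs.observable_names):
            y = traj.x[:, j]
            noise = rng.standard_normal(y.size) * noise_sd if noisy else 0.0
            for t, val in zip(times, y + noise):
                rows.append((oname, "base", ct, t, val, noise_sd))
    ms = MeasurementSet(pd.DataFrame(
        rows, columns=["observableId", "conditionId", "cellType", "time",
                       "measurement", "sd"]))
    problem = TwoCellTypeProblem(
        model=model, observation=obs, conditions={"base": Condition()},
        measurements=ms, penalized=list(penalized),
        fold_lb=-2.0, fold_ub=2.0, rtol=1e-8, atol=1e-10)
    truth_theta = np.concatenate([ref, [rvec.get(p, 0.0) for p in penalized]])
    return problem, truth_theta


@pytest.fixture(scope="session")
def cascade_problem():
    return make_cascade_problem()


@pytest.fixture(scope="session")
def quantile95():
    return {m: chi2_quantile(0.95, m) for m in range(1, 8)}
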