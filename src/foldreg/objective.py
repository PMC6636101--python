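"""Two-cell-type parameterization and the maximum-likelihood objective.

Cell type [0] is the reference with log10 parameters log p[0]; cell type [1]
is described through log10 fold-changes r, log p[1]_i = log p[0]_i + r_i on
the penalized subset.  r_i = 0 means parameter i is cell-type independent.
The objective is the negative two-fold log-likelihood (additive constant
dropped) for Gaussian errors with known standard deviations,

    chi2_ML = sum_ij ((y_ij - g(x_i(t_j))) / sigma_ij)^2,

summed over all conditions and both cell types, with an analytic gradient
with respect to (log p[0], r) from forward sensitivities.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .ode_core import (
    LN10,
    IntegrationError,
    simulate_with_sensitivities,
)

BIG = 1e12  # finite stand-in for a failed integration, rejected by line search

MEASUREMENT_COLUMNS = ["observableId", "conditionId", "cellType", "time", "measurement", "sd"]


@dataclass
class TwoCellTypeParameterization:
    """Reference log10 parameters plus the penalized log10 fold-change vector."""

    log_p0: np.ndarray
    r: np.ndarray
    param_names: list
    penalized: list                 # names of parameters carrying fold-changes
    fixed_zero: np.ndarray | None = None   # boolean mask over r held at exactly 0

    def __post_init__(self):
        self.log_p0 = np.asarray(self.log_p0, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.fixed_zero is None:
            self.fixed_zero = np.zeros(len(self.penalized), dtype=bool)
        if np.any(self.r[self.fixed_zero] != 0.0):
            raise ValueError("masked fold-changes must be exactly zero")
        missing = set(self.penalized) - set(self.param_names)
        if missing:
            raise ValueError(f"penalized parameters not in model: {sorted(missing)}")


def map_celltype_params(param: TwoCellTypeParameterization, cell_type):
    """Log10 parameter vector of one cell type (0: reference, 1: reference + r)."""
    if cell_type not in (0, 1):
        raise ValueError("cell_type must be 0 or 1")
    out = param.log_p0.copy()
    if cell_type == 1:
        for pos, name in enumerate(param.penalized):
            out[param.param_names.index(name)] += param.r[pos]
    return out


class MeasurementSet:
    """Measurement records: observable, condition, cell type, time, value, sd."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"measurement table missing columns {missing}")
        df = df[MEASUREMENT_COLUMNS].copy()
        df["cellType"] = df["cellType"].astype(int)
        df["time"] = df["time"].astype(float)
        df["measurement"] = df["measurement"].astype(float)
        df["sd"] = df["sd"].astype(float)
        if not (df["sd"] > 0).all():
            bad = df.index[~(df["sd"] > 0)].tolist()[:5]
            raise ValueError(f"non-positive sd in rows {bad}")
        if not df["cellType"].isin([0, 1]).all():
            raise ValueError("cellType must be 0 or 1")
        self.df = df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    @classmethod
    def from_tsv(cls, path):
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)

    def validate_against(self, observable_names, condition_ids):
        for row, rec in self.df.iterrows():
            if rec.observableId not in observable_names:
                raise ValueError(f"row {row}: unknown observable {rec.observableId!r}")
            if rec.conditionId not in condition_ids:
                raise ValueError(f"row {row}: unknown condition {rec.conditionId!r}")


@dataclass
class FitResult:
    """Outcome of one (multi-start) optimization."""

    theta: np.ndarray        # concat(log_p0 over estimated, r over penalized)
    chi2: float
    n_ref: int
    success: bool = True
    n_iter: int = 0
    n_starts: int = 1
    mask: np.ndarray | None = None     # fold-changes held at exactly zero
    start_objectives: list = field(default_factory=list)

    @property
    def log_p0(self):
        return self.theta[: self.n_ref]

    @property
    def r(self):
        return self.theta[self.n_ref:]


class TwoCellTypeProblem:
    """Estimation problem: ODE model + observation map + measurements.

    theta = concat(log10 p[0] over the estimated parameters, r over the
    penalized parameters).  Exposes chi2(theta) -> (value, gradient), which is
    the interface the fitting, regularization-path and profile modules build
    on (any object with n_ref / n_fold / lower / upper / chi2 works there).
    """

    def __init__(self, model, observation, conditions, measurements,
                 penalized=None, estimated=None,
                 fold_lb=-3.0, fold_ub=3.0, fold_bounds=None,
                 rtol=1e-8, atol=1e-10, name="problem"):
        self.model = model
        self.observation = observation
        self.conditions = dict(conditions)
        self.measurements = measurements
        self.estimated = list(estimated) if estimated is not None else list(model.param_names)
        self.penalized = list(penalized) if penalized is not None else list(self.estimated)
        self.rtol, self.atol = rtol, atol
        self.name = name

        measurements.validate_against(set(observation.observable_names), set(self.conditions))
        for pname in self.estimated + self.penalized:
            if pname not in model.param_names:
                raise ValueError(f"unknown parameter {pname!r}")

        self.n_ref = len(self.estimated)
        self.n_fold = len(self.penalized)
        lb, ub = model.log_bounds()
        self._est_idx = np.array([model.param_index(n) for n in self.estimated], dtype=int)
        self._pen_idx = np.array([model.param_index(n) for n in self.penalized], dtype=int)
        fb = fold_bounds or {}
        flb = np.array([fb.get(n, (fold_lb, fold_ub))[0] for n in self.penalized])
        fub = np.array([fb.get(n, (fold_lb, fold_ub))[1] for n in self.penalized])
        self.lower = np.concatenate([lb[self._est_idx], flb])
        self.upper = np.concatenate([ub[self._est_idx], fub])
        # defaults for non-estimated parameters: mid-bounds (overridable)
        self.fixed_log = 0.5 * (lb + ub)
        self._obs_state_idx = observation.state_indices(model)
        self._groups = self._build_groups()
        self.n_data = len(measurements)

    # -- data bookkeeping --------------------------------------------------
    def _build_groups(self):
        obs_pos = {n: i for i, n in enumerate(self.observation.observable_names)}
        groups = []
        for (cond_id, ct), sub in self.measurements.df.groupby(["conditionId", "cellType"], sort=True):
            times = np.unique(sub["time"].to_numpy())
            t_pos = {t: i for i, t in enumerate(times)}
            groups.append({
                "condition": self.conditions[cond_id],
                "cell_type": int(ct),
                "times": times,
                "t_idx": np.array([t_pos[t] for t in sub["time"]]),
                "o_idx": np.array([obs_pos[o] for o in sub["observableId"]]),
                "y": sub["measurement"].to_numpy(),
                "sd": sub["sd"].to_numpy(),
            })
        return groups

    def full_log_params(self, log_ref):
        full = self.fixed_log.copy()
        full[self._est_idx] = log_ref
        return full

    # -- objective ---------------------------------------------------------
    def chi2(self, theta):
        """chi2_ML and its gradient over (log p[0], r); BIG on solver failure."""
        theta = np.asarray(theta, dtype=float)
        log_ref = theta[: self.n_ref]
        r = theta[self.n_ref:]
        full0 = self.full_log_params(log_ref)
        full1 = full0.copy()
        full1[self._pen_idx] += r
        value = 0.0
        grad_full = [np.zeros(self.model.n_params), np.zeros(self.model.n_params)]
        try:
            for g in self._groups:
                ct = g["cell_type"]
                logp = full0 if ct == 0 else full1
                traj = simulate_with_sensitivities(
                    self.model, logp, g["condition"], g["times"],
                    rtol=self.rtol, atol=self.atol)
                p_lin = np.power(10.0, logp)
                if self._obs_state_idx is not None:
                    y_mod = traj.x[:, self._obs_state_idx]
                    dy = traj.sens[:, self._obs_state_idx, :]
                else:
                    y_mod, dy = self.observation.observe_with_sens(
                        self.model, traj, p_lin, LN10 * p_lin)
                res = (g["y"] - y_mod[g["t_idx"], g["o_idx"]]) / g["sd"]
                value += float(res @ res)
                w = (-2.0 * res / g["sd"])[:, None]
                grad_full[ct] += np.sum(w * dy[g["t_idx"], g["o_idx"], :], axis=0)
        except IntegrationError:
            return BIG, np.zeros(theta.size)
        if not np.isfinite(value):
            return BIG, np.zeros(theta.size)
        grad = np.empty(theta.size)
        grad[: self.n_ref] = (grad_full[0] + grad_full[1])[self._est_idx]
        grad[self.n_ref:] = grad_full[1][self._pen_idx]
        return value, grad

    def chi2_value(self, theta):
        return self.chi2(theta)[0]


def chi2_ml(problem, log_p0, r):
    """chi2_ML(p[0], r) and its gradient, stacking (d/d log p[0], d/d r)."""
    theta = np.concatenate([np.asarray(log_p0, float), np.asarray(r, float)])
    return problem.chi2(theta)


# ---------------------------------------------------------------------------
# local and multi-start optimization
# ---------------------------------------------------------------------------

def minimize_theta(problem, theta0, fixed_zero=None, penalty=None,
                   gtol=1e-6, ftol=1e-11, maxiter=500, pin_value=0.0):
    """Bounded local minimization of chi2 (+ optional penalty term on r).

    fixed_zero is a boolean mask over fold-change entries pinned at exactly
    pin_value (removed from the optimization).  penalty, if given, is a
    callable r -> (value, gradient) added to chi2.  Returns (theta,
    penalized_value, scipy result).
    """
    n_ref, n_fold = problem.n_ref, problem.n_fold
    dim = n_ref + n_fold
    theta0 = np.asarray(theta0, dtype=float)
    if fixed_zero is None:
        fixed_zero = np.zeros(n_fold, dtype=bool)
    free = np.concatenate([np.ones(n_ref, dtype=bool), ~fixed_zero])
    base = np.full(dim, float(pin_value))
    base[: n_ref] = theta0[: n_ref]
    base[n_ref:][~fixed_zero] = theta0[n_ref:][~fixed_zero]

    def expand(x):
        th = base.copy()
        th[free] = x
        return th

    def fun(x):
        th = expand(x)
        val, grad = problem.chi2(th)
        if penalty is not None:
            pv, pg = penalty(th[n_ref:])
            val = val + pv
            grad = grad.copy()
            grad[n_ref:] += pg
        return val, grad[free]

    if not np.any(free):  # everything pinned: nothing to optimize
        val, _ = problem.chi2(base)
        if penalty is not None:
            val += penalty(base[n_ref:])[0]
        res = optimize.OptimizeResult(x=np.empty(0), fun=float(val), nit=0,
                                      status=0, success=True,
                                      message="no free variables")
        return base.copy(), float(val), res

    x0 = np.clip(base[free], problem.lower[free], problem.upper[free])
    res = optimize.minimize(
        fun, x0, jac=True, method="L-BFGS-B",
        bounds=list(zip(problem.lower[free], problem.upper[free])),
        options={"gtol": gtol, "ftol": ftol, "maxiter": maxiter},
    )
    return expand(res.x), float(res.fun), res


def _lhs_starts(problem, n, seed):
    sampler = qmc.LatinHypercube(d=problem.n_ref + problem.n_fold, seed=seed)
    pts = problem.lower + sampler.random(n) * (problem.upper - problem.lower)
    # fold-changes start at the cell-type-independent null r = 0: uniform
    # draws mostly land in degenerate both-cell-types-wrong regimes
    pts[:, problem.n_ref:] = 0.0
    pts[0, : problem.n_ref] = 0.5 * (problem.lower + problem.upper)[: problem.n_ref]
    return list(pts)


def _multistart(problem, starts, fixed_zero, gtol, ftol, maxiter, screen_maxiter):
    """Screen every start briefly, polish the most promising basin."""
    best = None
    objectives = []
    screening = len(starts) > 1 and screen_maxiter is not None
    for s in starts:
        theta, val, res = minimize_theta(
            problem, s, fixed_zero=fixed_zero, gtol=gtol, ftol=ftol,
            maxiter=screen_maxiter if screening else maxiter)
        objectives.append(val)
        if val < BIG and (best is None or val < best[1]):
            best = (theta, val, res)
    if best is None:
        raise RuntimeError(
            f"all {len(starts)} optimization starts failed (objectives: {objectives})")
    if screening:
        theta, val, res = minimize_theta(problem, best[0], fixed_zero=fixed_zero,
                                         gtol=gtol, ftol=ftol, maxiter=maxiter)
        if val <= best[1]:
            best = (theta, val, res)
    return best, objectives


def fit_ml(problem, n_starts=10, seed=0, start=None, fixed_zero=None,
           gtol=1e-6, ftol=1e-11, maxiter=500, screen_maxiter=40,
           hierarchical=True):
    """Best-of-multi-start maximum likelihood fit of (log p[0], r).

    Starts are Latin-hypercube points within the bounds; the user-supplied
    *start*, if any, is tried first.  With several starts, each is first run
    for screen_maxiter iterations and only the most promising basin is
    polished (cheap screening; bad basins, e.g. the everything-degraded
    plateau of gene-network models, stall early).  By default the fit is
    hierarchical: the reference model (all fold-changes pinned at 0) is fitted
    by multi-start first and the fold-changes are then released from that
    optimum, which is markedly more reliable than attacking the full
    two-cell-type space at once.  Deterministic for a given seed.
    """
    rng_seed = int(seed) % (2**31)
    opts = dict(gtol=gtol, ftol=ftol, maxiter=maxiter)
    objectives = []
    if start is not None:
        starts = [np.asarray(start, dtype=float)]
        starts += _lhs_starts(problem, n_starts - 1, rng_seed) if n_starts > 1 else []
        best, objectives = _multistart(problem, starts, fixed_zero,
                                       gtol, ftol, maxiter, screen_maxiter)
    elif hierarchical and problem.n_fold and not (
            fixed_zero is not None and np.all(fixed_zero)):
        all_pinned = np.ones(problem.n_fold, dtype=bool)
        starts = _lhs_starts(problem, max(n_starts, 1), rng_seed)
        bestA, objectives = _multistart(problem, starts, all_pinned,
                                        gtol, ftol, maxiter, screen_maxiter)
        best = minimize_theta(problem, bestA[0], fixed_zero=fixed_zero, **opts)
        if bestA[1] < best[1] and (fixed_zero is None or not np.any(fixed_zero)):
            # releasing the fold-changes cannot make the optimum worse
            best = bestA
        objectives = objectives + [best[1]]
    else:
        starts = _lhs_starts(problem, max(n_starts, 1), rng_seed)
        best, objectives = _multistart(problem, starts, fixed_zero,
                                       gtol, ftol, maxiter, screen_maxiter)
    theta, val, res = best
    chi2_val, _ = problem.chi2(theta)
    return FitResult(theta=theta, chi2=float(chi2_val), n_ref=problem.n_ref,
                     success=True, n_iter=int(res.nit), n_starts=len(starts),
                     mask=None if fixed_zero is None else np.asarray(fixed_zero, bool).copy(),
                     start_objectives=objectives)


def load_measurements(path):
    return MeasurementSet.from_tsv(path)


def measurements_to_string(ms: MeasurementSet) -> str:
    buf = io.StringIO()
    ms.df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()
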