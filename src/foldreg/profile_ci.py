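"""Profile likelihood and profile-based confidence intervals.

The profile of parameter i is chi2_PL(c) = min over all other parameters of
chi2_ML with theta_i fixed at c, computed by stepping outward from the
optimum in both directions and re-optimizing warm-started from the previous
grid point.  The level set chi2_PL - chi2_min < q_alpha^(1) gives the
confidence interval; a threshold never crossed within the parameter bounds
flags practical non-identifiability (an open interval end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .objective import minimize_theta
from .regpath import chi2_quantile


@dataclass
class ProfileResult:
    index: int
    values: np.ndarray       # profiled parameter values, ascending
    chi2: np.ndarray         # chi2_PL at each value
    chi2_min: float          # objective at the global fit
    estimate: float
    lower_open: bool = False
    upper_open: bool = False

    def to_frame(self):
        return pd.DataFrame({"value": self.values, "chi2": self.chi2})


def _reoptimize(problem, theta, i, value, fixed_zero, **opts):
    """Minimize over all parameters but theta_i, held at *value*."""
    lo, up = problem.lower.copy(), problem.upper.copy()
    lo[i] = up[i] = value

    class _Pinned:
        n_ref, n_fold = problem.n_ref, problem.n_fold
        lower, upper = lo, up
        chi2 = staticmethod(problem.chi2)

    th = theta.copy()
    th[i] = value
    th_opt, val, _ = minimize_theta(_Pinned, th, fixed_zero=fixed_zero, **opts)
    return th_opt, val


def profile_likelihood(problem, fit, i, grid=None, alpha=0.95,
                       target_step=0.2, max_steps=100, init_step=0.01,
                       fixed_zero=None, **opts):
    """1-D profile of parameter i around a converged fit.

    With no explicit grid, steps adapt so each one raises chi2 by roughly
    target_step, stopping once chi2 exceeds the CI threshold plus 1 or a
    bound is reached.  Failed re-optimizations flag the grid point (dropped).
    """
    theta_hat = fit.theta
    chi2_min = fit.chi2
    thr = chi2_quantile(alpha, 1)
    if grid is not None:
        vals, chis = [], []
        th = theta_hat.copy()
        for v in np.sort(np.asarray(grid, dtype=float)):
            th, c = _reoptimize(problem, th, i, v, fixed_zero, **opts)
            vals.append(v); chis.append(c)
        vals, chis = np.asarray(vals), np.asarray(chis)
    else:
        branches = []
        for direction in (-1.0, +1.0):
            pts = []
            th = theta_hat.copy()
            v = theta_hat[i]
            step = init_step
            last = chi2_min
            bound = problem.lower[i] if direction < 0 else problem.upper[i]
            for _ in range(max_steps):
                v_new = v + direction * step
                hit = (direction < 0 and v_new <= bound) or (direction > 0 and v_new >= bound)
                v_new = np.clip(v_new, problem.lower[i], problem.upper[i])
                th, c = _reoptimize(problem, th, i, v_new, fixed_zero, **opts)
                pts.append((v_new, c))
                rise = c - last
                if rise > 1e-12:  # aim at target_step chi2 increase per step
                    step = float(np.clip(step * target_step / rise, step / 4, step * 4))
                else:
                    step = step * 2
                v, last = v_new, c
                if hit or c - chi2_min > thr + 1.0:
                    break
            branches.append(pts)
        left = branches[0][::-1]
        right = branches[1]
        vals = np.array([p[0] for p in left] + [theta_hat[i]] + [p[0] for p in right])
        chis = np.array([p[1] for p in left] + [chi2_min] + [p[1] for p in right])
    lower_open = bool(chis[0] - chi2_min < thr)
    upper_open = bool(chis[-1] - chi2_min < thr)
    return ProfileResult(index=i, values=vals, chi2=chis, chi2_min=chi2_min,
                         estimate=float(theta_hat[i]),
                         lower_open=lower_open, upper_open=upper_open)


def confidence_interval(profile: ProfileResult, alpha=0.95):
    """CI bounds at level alpha by linear interpolation of the profile.

    Returns (low, high); an end is NaN when the threshold is never crossed
    within the profiled range (open interval, practical non-identifiability).
    """
    thr = profile.chi2_min + chi2_quantile(alpha, 1)
    v, c = profile.values, profile.chi2
    k = int(np.argmin(np.abs(v - profile.estimate)))

    def cross(idx_range, prev_of):
        for j in idx_range:
            if c[j] >= thr:
                a, b = prev_of(j), j
                if c[b] == c[a]:
                    return v[b]
                w = (thr - c[a]) / (c[b] - c[a])
                return v[a] + w * (v[b] - v[a])
        return np.nan

    low = cross(range(k, -1, -1), lambda j: j + 1)
    high = cross(range(k, len(v)), lambda j: j - 1)
    return float(low), float(high)


def profile_grid_2d(problem, fit, i, j, values_i, values_j, fixed_zero=None, **opts):
    """2-D profile landscape by nested re-optimization (diagnostic only)."""
    out = np.empty((len(values_i), len(values_j)))
    th_row = fit.theta.copy()
    for a, vi in enumerate(values_i):
        th = th_row.copy()
        for b, vj in enumerate(values_j):
            lo, up = problem.lower.copy(), problem.upper.copy()
            lo[i] = up[i] = vi
            lo[j] = up[j] = vj

            class _Pinned:
                n_ref, n_fold = problem.n_ref, problem.n_fold
                lower, upper = lo, up
                chi2 = staticmethod(problem.chi2)

            th[i], th[j] = vi, vj
            th, val, _ = minimize_theta(_Pinned, th, fixed_zero=fixed_zero, **opts)
            if b == 0:
                th_row = th.copy()
            out[a, b] = val
    return out
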