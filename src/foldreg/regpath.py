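"""Two-step regularization routine over a penalty-strength scan.

For each penalty strength lambda on an ascending grid:

  step 1  minimize chi2_ML + lambda * nu(r) warm-started from the previous
          lambda, yielding the zero set Z(lambda) = {i : |r_i| <= eps};
  step 2  remove the penalty and re-optimize with Z(lambda) fixed to zero,
          removing the shrinkage bias; chi2(lambda) is this refit objective.

The likelihood-ratio statistic D(lambda) = chi2(lambda) - chi2(0) is compared
with the alpha-quantile of a chi-square distribution with #Z(lambda) degrees
of freedom; the parsimonious model sits at the largest lambda whose shrinkage
is still compatible with the data,

    lambda* = max { lambda > 0 | Z(lambda) = {} or D(lambda) < q_alpha^(#Z) }.

Scanning ascends from small lambda with warm starts so that, in particular
for the non-convex lq penalty, the optimizer is not trapped in the
artefactual local optimum at r = 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .objective import FitResult, fit_ml, minimize_theta
from .penalties import (
    PenaltySpec,
    penalty_components,
    penalty_gradient,
    penalty_value,
    subgradient_bound,
)


def zero_set(r, epsilon=1e-10):
    """Indices of (effectively) zero fold-changes, {i : |r_i| <= eps}."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    return set(np.nonzero(np.abs(r) <= epsilon)[0].tolist())


def chi2_quantile(alpha, m):
    """alpha-quantile of the chi-square distribution with m degrees of freedom."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.chi2.ppf(alpha, m))


def lrt_statistic(chi2_lambda, chi2_zero):
    """D(lambda) = chi2(lambda) - chi2(0), clamped at 0 against optimizer noise."""
    d = float(chi2_lambda) - float(chi2_zero)
    if d < -0.01:
        warnings.warn(
            f"LRT statistic {d:.4g} < 0: the restricted refit beat the "
            "unpenalized optimum; clamping to 0", stacklevel=2)
    return max(d, 0.0)


# ---------------------------------------------------------------------------
# penalized fit (step 1) with active zero set and snapping
# ---------------------------------------------------------------------------

@dataclass
class PenalizedFit:
    theta: np.ndarray
    chi2: float                # unpenalized value at theta
    penalized: float           # chi2 + lambda * nu
    zero_mask: np.ndarray      # entries pinned at the target
    n_ref: int
    success: bool = True

    @property
    def r(self):
        return self.theta[self.n_ref:]


def fit_penalized(problem, spec: PenaltySpec, lam, start,
                  snap_tol=0.05, max_outer=2, gtol=1e-6,
                  ftol=1e-11, maxiter=500, snap_polish=True):
    """Minimize chi2_ML + lam * nu(r) from a warm start, with exact zeros.

    Entries starting within eps of the target are held there but released
    whenever the likelihood gradient escapes the penalty subdifferential
    (first-order condition at zero).  After the smooth fit, entries within
    snap_tol of the target are candidates for snapping onto it exactly,
    tried greedily from the smallest |r_i| up; each snap is kept only if the
    penalized objective does not increase.  This yields exact zeros, which a
    quasi-Newton step on the clamped non-smooth objective alone would only
    approach.  snap_tol is merely the candidate window; the objective test
    decides.  With snap_polish the remaining coordinates are re-optimized
    after snapping (skippable when a bias-removing refit follows anyway, as
    in the two-step routine).
    """
    n_ref = problem.n_ref
    target = float(np.atleast_1d(spec.target)[0]) if np.ndim(spec.target) else float(spec.target)
    theta = np.asarray(start, dtype=float).copy()
    pinned = np.abs(theta[n_ref:] - target) <= spec.epsilon

    def pen(r):
        return lam * penalty_value(spec, r), lam * penalty_gradient(spec, r)

    res = None
    for _ in range(max_outer):
        # release pinned entries whose likelihood gradient dominates the penalty
        released = False
        if np.any(pinned):
            probe = theta.copy()
            probe[n_ref:][pinned] = target
            _, grad = problem.chi2(probe)
            for i in np.nonzero(pinned)[0]:
                if abs(grad[n_ref + i]) > lam * subgradient_bound(spec, i) * (1 + 1e-9):
                    pinned[i] = False
                    released = True
        theta, pval, res = minimize_theta(
            problem, theta, fixed_zero=pinned, penalty=pen,
            gtol=gtol, ftol=ftol, maxiter=maxiter, pin_value=target)
        if not released:
            break

    # snap near-target entries onto the singular manifold, smallest first;
    # the cheap test accepts a snap whose instantaneous chi2 increase is
    # already covered by the penalty saving
    dist = np.abs(theta[n_ref:] - target)
    cand = np.nonzero((~pinned) & (dist <= snap_tol) & (dist > spec.epsilon))[0]
    accepted = False
    slack = 1e-6 * (1.0 + abs(pval))
    for i in sorted(cand, key=lambda j: dist[j]):
        trial = theta.copy()
        trial[n_ref + i] = target
        cv, _ = problem.chi2(trial)
        tval = cv + lam * penalty_value(spec, trial[n_ref:])
        if tval <= pval + slack:
            theta, pval = trial, tval
            pinned[i] = True
            accepted = True
    if accepted and snap_polish:
        theta, pval, res = minimize_theta(
            problem, theta, fixed_zero=pinned, penalty=pen,
            gtol=gtol, ftol=ftol, maxiter=maxiter, pin_value=target)
    # a rejected candidate may still belong at the target once the other
    # coordinates re-adjust (correlated fold-changes): trial-pin the one with
    # the largest penalty saving and keep the pin if re-optimization confirms
    for _ in range(2):
        dist = np.abs(theta[n_ref:] - target)
        rej = np.nonzero((~pinned) & (dist <= snap_tol) & (dist > spec.epsilon))[0]
        if rej.size == 0:
            break
        comp = penalty_components(spec, theta[n_ref:])
        j = rej[int(np.argmax(comp[rej]))]
        if lam * comp[j] <= slack:
            break
        trial_pin = pinned.copy()
        trial_pin[j] = True
        th2, v2, r2 = minimize_theta(
            problem, theta, fixed_zero=trial_pin, penalty=pen,
            gtol=gtol, ftol=ftol, maxiter=maxiter, pin_value=target)
        if v2 <= pval + slack:
            theta, pval, res, pinned = th2, v2, r2, trial_pin
        else:
            break

    # canonicalize: anything inside the eps neighbourhood is exactly zero
    at_target = np.abs(theta[n_ref:] - target) <= spec.epsilon
    theta[n_ref:][at_target] = target
    pinned |= at_target
    chi2_val, _ = problem.chi2(theta)
    return PenalizedFit(theta=theta, chi2=float(chi2_val), penalized=float(pval),
                        zero_mask=pinned.copy(), n_ref=n_ref,
                        success=bool(res is None or res.status in (0, 1, 2)))


# ---------------------------------------------------------------------------
# lambda scan
# ---------------------------------------------------------------------------

@dataclass
class LambdaRecord:
    lam: float
    step1: PenalizedFit | None
    zero: frozenset
    refit: FitResult | None
    chi2: float
    D: float
    threshold: float
    admissible: bool
    failed: bool = False


@dataclass
class RegPath:
    """Per-lambda results of a two-step scan plus the selected model."""

    spec: PenaltySpec
    alpha: float
    lam_grid: np.ndarray
    records: list
    chi2_0: float
    base_fit: FitResult
    lam_star: float | None = None
    final_fit: FitResult | None = None
    final_zero: frozenset = field(default_factory=frozenset)

    def to_frame(self):
        rows = []
        for rec in self.records:
            rows.append({
                "lambda": rec.lam, "n_zero": len(rec.zero), "chi2": rec.chi2,
                "D": rec.D, "threshold": rec.threshold,
                "admissible": rec.admissible, "failed": rec.failed,
            })
        return pd.DataFrame(rows)

    def to_json(self):
        payload = {
            "family": self.spec.family,
            "deformation": self.spec.deformation,
            "alpha": self.alpha,
            "chi2_0": self.chi2_0,
            "lambda_star": self.lam_star,
            "final_zero": sorted(self.final_zero),
            "records": [
                {
                    "lambda": rec.lam,
                    "zero": sorted(rec.zero),
                    "chi2": rec.chi2,
                    "D": rec.D,
                    "threshold": rec.threshold,
                    "admissible": rec.admissible,
                    "failed": rec.failed,
                    "r": None if rec.refit is None else [repr(v) for v in rec.refit.r],
                }
                for rec in self.records
            ],
        }
        return json.dumps(payload, indent=1)


def default_lambda_grid(lam_min=1e-4, lam_max=1e6, n=41):
    """Log-spaced penalty strengths, by default 1e-4 ... 1e6."""
    return np.logspace(np.log10(lam_min), np.log10(lam_max), n)


def scan_lambda(problem, spec: PenaltySpec, lam_grid=None, seed=0,
                alpha=0.95, n_starts=10, base_fit=None, refit_cache=None,
                snap_tol=1e-3, gtol=1e-6, ftol=1e-11, maxiter=500,
                snap_polish=True, refit_gtol=None, refit_maxiter=None,
                select=True):
    """Run the two-step routine over an ascending lambda grid.

    Step-1 fits are warm-started from the previous grid point; step-2 refits
    are cached by zero set (an unchanged Z(lambda) implies an identical
    restricted refit).  A refit_cache dict may be shared across scans of the
    same problem, e.g. between penalty families on one dataset.  refit_gtol /
    refit_maxiter override the step-2 (and baseline) controls: D(lambda) is a
    difference of refit objectives, so they set its numerical resolution.
    """
    refit_gtol = gtol if refit_gtol is None else refit_gtol
    refit_maxiter = maxiter if refit_maxiter is None else refit_maxiter
    lam_grid = default_lambda_grid() if lam_grid is None else np.asarray(lam_grid, float)
    if np.any(np.diff(lam_grid) <= 0) or lam_grid[0] <= 0:
        raise ValueError("lambda grid must be positive and strictly ascending")
    if base_fit is None:
        base_fit = fit_ml(problem, n_starts=n_starts, seed=seed,
                          gtol=gtol, ftol=ftol, maxiter=maxiter)
    if spec.family == "adaptive_lasso" and spec.weights is None:
        spec = spec.with_weights_from(base_fit.r)
    chi2_0 = base_fit.chi2
    cache = {} if refit_cache is None else refit_cache
    cache.setdefault(frozenset(), base_fit)

    records = []
    prev = base_fit.theta.copy()
    full_key = frozenset(range(problem.n_fold))
    allzero_grad = None
    bound_vec = np.array([subgradient_bound(spec, i)
                          for i in range(problem.n_fold)])
    # the fully-shrunk model is the lambda -> infinity limit of every family;
    # computing its refit once lets each grid point compare its step-1 result
    # against full shrinkage, so huge lambdas collapse to r = 0 instead of
    # dragging a compensating coordinate along the warm-start chain
    if problem.n_fold and full_key not in cache:
        z_start = base_fit.theta.copy()
        z_start[problem.n_ref:] = 0.0
        cache[full_key] = fit_ml(
            problem, n_starts=1, seed=seed, start=z_start,
            fixed_zero=np.ones(problem.n_fold, dtype=bool),
            gtol=refit_gtol, ftol=ftol, maxiter=refit_maxiter)
    nu_at_zero = penalty_value(spec, np.zeros(problem.n_fold)) if problem.n_fold else 0.0
    for lam in lam_grid:
        try:
            pfit = None
            # once the path is fully shrunk and stays first-order optimal at
            # r = 0 for this lambda, the step-1 solution is the cached
            # all-zero refit itself
            if np.all(np.abs(prev[problem.n_ref:]) <= spec.epsilon) and full_key in cache:
                ref_fit = cache[full_key]
                if allzero_grad is None:
                    _, allzero_grad = problem.chi2(ref_fit.theta)
                if np.all(np.abs(allzero_grad[problem.n_ref:]) <= lam * bound_vec):
                    pfit = PenalizedFit(
                        theta=ref_fit.theta.copy(), chi2=ref_fit.chi2,
                        penalized=ref_fit.chi2,
                        zero_mask=np.ones(problem.n_fold, dtype=bool),
                        n_ref=problem.n_ref)
            if pfit is None:
                pfit = fit_penalized(problem, spec, lam, prev, snap_tol=snap_tol,
                                     gtol=gtol, ftol=ftol, maxiter=maxiter,
                                     snap_polish=snap_polish)
                z_fit = cache.get(full_key)
                if z_fit is not None:
                    pen_zero = z_fit.chi2 + lam * nu_at_zero
                    if pen_zero < pfit.penalized:
                        pfit = PenalizedFit(
                            theta=z_fit.theta.copy(), chi2=z_fit.chi2,
                            penalized=pen_zero,
                            zero_mask=np.ones(problem.n_fold, dtype=bool),
                            n_ref=problem.n_ref)
            Z = frozenset(zero_set(pfit.r, spec.epsilon))
            if Z in cache:
                refit = cache[Z]
            else:
                mask = np.zeros(problem.n_fold, dtype=bool)
                mask[list(Z)] = True
                refit = fit_ml(problem, n_starts=1, seed=seed, start=pfit.theta,
                               fixed_zero=mask, gtol=refit_gtol, ftol=ftol,
                               maxiter=refit_maxiter)
                if Z and refit.chi2 - chi2_0 >= chi2_quantile(alpha, len(Z)):
                    # the shrinkage looks data-incompatible; make sure that is
                    # not an artifact of the warm start drifting with the
                    # penalty -- retry from the unpenalized optimum
                    alt = fit_ml(problem, n_starts=1, seed=seed,
                                 start=base_fit.theta, fixed_zero=mask,
                                 gtol=refit_gtol, ftol=ftol,
                                 maxiter=refit_maxiter)
                    if alt.chi2 < refit.chi2:
                        refit = alt
                cache[Z] = refit
            chi2_lam = refit.chi2
            records.append(LambdaRecord(lam=float(lam), step1=pfit, zero=Z,
                                        refit=refit, chi2=chi2_lam, D=np.nan,
                                        threshold=np.nan, admissible=False))
            prev = pfit.theta.copy()
        except Exception as exc:  # keep scanning; flag the grid point
            warnings.warn(f"lambda = {lam:g} failed: {exc}", stacklevel=2)
            records.append(LambdaRecord(lam=float(lam), step1=None,
                                        zero=frozenset(), refit=None,
                                        chi2=np.nan, D=np.nan, threshold=np.nan,
                                        admissible=False, failed=True))
    # the unpenalized reference: if a restricted warm-started refit found a
    # better basin than the base fit (local-minimum escape along the path),
    # release the mask there and re-polish the full model, so that D(lambda)
    # compares against a baseline at least as good as every submodel found
    ok = [rec for rec in records if not rec.failed and np.isfinite(rec.chi2)]
    chi2_ref = chi2_0
    improvers = [rec for rec in ok if rec.chi2 < chi2_0 - 0.01]
    if improvers:
        best_rec = min(improvers, key=lambda rec: rec.chi2)
        theta, val, _ = minimize_theta(problem, best_rec.refit.theta,
                                       gtol=refit_gtol, ftol=ftol,
                                       maxiter=refit_maxiter)
        chi2_ref = min([chi2_0, val] + [rec.chi2 for rec in ok])
        warnings.warn(
            f"a restricted refit improved on the unpenalized fit "
            f"(chi2 {chi2_0:.4g} -> {chi2_ref:.4g}); re-polished baseline",
            stacklevel=2)
    for rec in records:
        if not rec.failed:
            rec.D = max(rec.chi2 - chi2_ref, 0.0)
    path = RegPath(spec=spec, alpha=alpha, lam_grid=lam_grid, records=records,
                   chi2_0=chi2_ref, base_fit=base_fit)
    if select:
        parsimonious_lambda(path, alpha)
    return path


def parsimonious_lambda(path: RegPath, alpha=None):
    """Select the parsimonious model from the scan and attach it to the path.

    The admissible set contains every grid point whose shrinkage is
    compatible with the data (empty Z, or D below the chi-square quantile
    with #Z degrees of freedom); admissible points after an inadmissible one
    still count.  Among admissible points the sparsest model wins — the
    model with least cell-type specific features that still agrees with the
    data; on a monotone path this is exactly the largest admissible lambda.
    Ties in sparsity are broken by the larger lambda.  With no admissible
    point the unpenalized (lambda = 0) model is returned with a warning.
    """
    alpha = path.alpha if alpha is None else alpha
    best = None
    for rec in path.records:
        if rec.failed:
            continue
        thr = chi2_quantile(alpha, len(rec.zero)) if rec.zero else np.inf
        rec.threshold = thr
        rec.admissible = (not rec.zero) or rec.D < thr
        if rec.admissible:
            key = (len(rec.zero), rec.lam)
            if best is None or key >= (len(best.zero), best.lam):
                best = rec
    if best is None:
        warnings.warn("no admissible lambda on the grid; falling back to the "
                      "unpenalized model", stacklevel=2)
        path.lam_star = 0.0
        path.final_fit = path.base_fit
        path.final_zero = frozenset()
    else:
        path.lam_star = best.lam
        path.final_fit = best.refit
        path.final_zero = best.zero
    return path.lam_star, path.final_fit, path.final_zero
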