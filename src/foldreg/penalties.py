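"""Sparsity-inducing penalty families on log-fold-changes.

Four families nu(r - r*) with a single *deformation* degree of freedom d:

    l1             nu = sum |r_i|                       (d fixed at 0)
    lq             nu = sum |r_i|^q,       q = 1 - d,   0 < q <= 1
    elastic_net    nu = (1-a) sum |r_i| + a sum r_i^2,  a = d in [0, 1]
    adaptive_lasso nu = sum |r_i| * w_i,   w_i = |r_i^ML|^-gamma, gamma = d

d = 0 reduces every family to l1.  The lq gradient diverges as r_i -> 0 and
is clamped at the value it takes at |r_i| = eps (default 1e-10), which also
defines membership of the zero set: |r_i| <= eps counts as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

FAMILIES = ("l1", "lq", "adaptive_lasso", "elastic_net")


@dataclass
class PenaltySpec:
    """Penalty family with its deformation, target and lq cut-off."""

    family: str = "l1"
    deformation: float = 0.0
    target: float | np.ndarray = 0.0
    epsilon: float = 1e-10
    weights: np.ndarray | None = None   # adaptive lasso: |r_ML|^-gamma

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}")
        d = self.deformation
        if self.family == "l1" and d != 0.0:
            raise ValueError("l1 has no deformation degree of freedom")
        if self.family == "lq" and not (0.0 <= d < 1.0):
            raise ValueError(f"lq requires 0 < q = 1 - d <= 1, got d={d}")
        if self.family == "adaptive_lasso" and d < 0.0:
            raise ValueError("adaptive lasso requires gamma >= 0")
        if self.family == "elastic_net" and not (0.0 <= d <= 1.0):
            raise ValueError("elastic net requires 0 <= alpha <= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def q(self):
        return 1.0 - self.deformation

    @property
    def gamma(self):
        return self.deformation

    @property
    def alpha(self):
        return self.deformation

    def with_weights_from(self, r_ml):
        """Adaptive-lasso weights |r_ML|^-gamma from an unpenalized fit.

        Fold-changes estimated at (effectively) zero would give an infinite
        weight; they are floored at eps, i.e. capped at eps^-gamma.
        """
        a = np.maximum(np.abs(np.asarray(r_ml, dtype=float)), self.epsilon)
        return replace(self, weights=a ** (-self.gamma))

    def _shift(self, r):
        return np.asarray(r, dtype=float) - self.target


def penalty_value(spec: PenaltySpec, r):
    """nu(r - r*); non-negative, zero at the target."""
    s = spec._shift(r)
    a = np.abs(s)
    if spec.family == "l1":
        return float(np.sum(a))
    if spec.family == "lq":
        return float(np.sum(a ** spec.q))
    if spec.family == "elastic_net":
        al = spec.alpha
        return float((1 - al) * np.sum(a) + al * np.sum(s * s))
    if spec.weights is None:
        raise ValueError("adaptive lasso requires weights from an unpenalized fit")
    return float(np.sum(a * spec.weights))


def penalty_components(spec: PenaltySpec, r):
    """Per-coordinate contributions nu_i with nu = sum_i nu_i."""
    s = spec._shift(r)
    a = np.abs(s)
    if spec.family == "l1":
        return a
    if spec.family == "lq":
        return a ** spec.q
    if spec.family == "elastic_net":
        al = spec.alpha
        return (1 - al) * a + al * s * s
    if spec.weights is None:
        raise ValueError("adaptive lasso requires weights from an unpenalized fit")
    return a * spec.weights


def penalty_gradient(spec: PenaltySpec, r):
    """Gradient of nu; lq entries with |r_i| <= eps use the clamped value
    q eps^(q-1) sign(r_i), which stays finite.  Entries at exactly the target
    get sign 0 (the subgradient interval is reported separately)."""
    s = spec._shift(r)
    sg = np.sign(s)
    a = np.abs(s)
    if spec.family == "l1":
        return sg
    if spec.family == "lq":
        q = spec.q
        out = np.empty_like(a)
        small = a <= spec.epsilon
        out[small] = q * spec.epsilon ** (q - 1.0) * sg[small]
        out[~small] = q * a[~small] ** (q - 1.0) * sg[~small]
        return out
    if spec.family == "elastic_net":
        al = spec.alpha
        return (1 - al) * sg + 2 * al * s
    if spec.weights is None:
        raise ValueError("adaptive lasso requires weights from an unpenalized fit")
    return sg * spec.weights


def subgradient_bound(spec: PenaltySpec, i):
    """Magnitude b_i with subdifferential lam * nu at zero = lam * b_i * [-1, 1]."""
    if spec.family == "l1":
        return 1.0
    if spec.family == "lq":
        return spec.q * spec.epsilon ** (spec.q - 1.0)
    if spec.family == "elastic_net":
        return 1.0 - spec.alpha
    if spec.weights is None:
        raise ValueError("adaptive lasso requires weights from an unpenalized fit")
    return float(spec.weights[i])


def subgradient_interval(spec: PenaltySpec, r, i, lam):
    """The set lam * grad nu(r)_i at a zero entry, as an interval [low, high].

    Within the eps neighbourhood the lq penalty is effectively the modulus
    function scaled by its clamped gradient, hence convex and amenable to
    subdifferential calculus.
    """
    s = spec._shift(np.atleast_1d(r))
    if abs(s[i]) > spec.epsilon:
        raise ValueError(f"r[{i}] = {np.atleast_1d(r)[i]} is not (effectively) zero")
    b = lam * subgradient_bound(spec, i)
    return (-b, b)


@dataclass
class OptimalityReport:
    """Per-parameter first-order optimality check at a penalized optimum."""

    ref_ok: np.ndarray
    fold_ok: np.ndarray
    ref_grad: np.ndarray
    fold_grad: np.ndarray
    fold_zero: np.ndarray          # entries tested against the subgradient interval
    margins: np.ndarray            # distance to violation (positive = satisfied)
    tol: float

    @property
    def all_ok(self):
        return bool(np.all(self.ref_ok) and np.all(self.fold_ok))


def check_optimality(problem, fit, spec: PenaltySpec, lam, tol=1e-3):
    """First-order conditions of the penalized objective at a fit.

    Reference parameters need a vanishing chi2 gradient; nonzero fold-changes
    need a vanishing penalized gradient; zero fold-changes are optimal when
    the chi2 gradient lies inside lam times the penalty subdifferential
    (the penalty term dominates the likelihood contribution).  Components at
    active box bounds are exempted from the interior gradient test.
    """
    theta = fit.theta
    n_ref = problem.n_ref
    _, grad = problem.chi2(theta)
    g_ref, g_r = grad[:n_ref], grad[n_ref:]
    at_bound = (np.abs(theta - problem.lower) < 1e-9) | (np.abs(theta - problem.upper) < 1e-9)
    ref_ok = (np.abs(g_ref) < tol) | at_bound[:n_ref]
    r = theta[n_ref:]
    zero = np.abs(np.atleast_1d(spec._shift(r))) <= spec.epsilon
    fold_ok = np.zeros(r.size, dtype=bool)
    margins = np.zeros(r.size)
    pg = penalty_gradient(spec, r)
    for i in range(r.size):
        if zero[i]:
            b = lam * subgradient_bound(spec, i)
            margins[i] = b + tol - abs(g_r[i])
            fold_ok[i] = abs(g_r[i]) <= b + tol
        else:
            total = g_r[i] + lam * pg[i]
            margins[i] = tol - abs(total)
            fold_ok[i] = abs(total) < tol or at_bound[n_ref + i]
    return OptimalityReport(ref_ok=ref_ok, fold_ok=fold_ok, ref_grad=g_ref,
                            fold_grad=g_r, fold_zero=zero, margins=margins, tol=tol)
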