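"""Shared ODE system for two cell types: representation, simulation, sensitivities.

A model is declared symbolically (states, rate expressions, parameters with
roles, named input constants) and compiled once into fast numerical right-hand
sides.  All parameters are positive and estimated on log10 scale; parameter
sensitivities are propagated with respect to log10-parameters via the forward
sensitivity equations

    dS/dt = (df/dx) S + df/d(log10 p),   S(0) = dx0/d(log10 p),

so that gradient-based optimization of the likelihood is cheap and accurate.
Experimental perturbations (gene knockout, 5x mRNA degradation, 2x mRNA
synthesis) act multiplicatively through named input constants and never change
the state dimension.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import sympy as sp
from scipy.integrate import odeint

LN10 = math.log(10.0)

PERTURBATION_KINDS = ("none", "knockout", "degradation_x5", "synthesis_x2")

# states are concentrations: the solver may propose tiny negative values, and
# rate-law derivatives can involve log(x); clip to a tiny positive floor
_XFLOOR = 1e-30


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces non-finite values."""


@dataclass(frozen=True)
class ParameterDef:
    """One positive model parameter, bounded on log10 scale.

    role is one of ``p0`` (initial condition), ``px`` (kinetic), ``pu``
    (input), ``py`` (observation).
    """

    name: str
    role: str = "px"
    lb: float = -5.0
    ub: float = 3.0

    def __post_init__(self):
        if self.role not in ("p0", "px", "pu", "py"):
            raise ValueError(f"unknown parameter role {self.role!r}")
        if not self.lb < self.ub:
            raise ValueError(f"parameter {self.name}: empty bounds [{self.lb}, {self.ub}]")


@dataclass(frozen=True)
class Perturbation:
    """Experimental perturbation of one gene (or none)."""

    kind: str = "none"
    gene: str | None = None

    def __post_init__(self):
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind != "none" and self.gene is None:
            raise ValueError("perturbation requires a gene")


@dataclass(frozen=True)
class Condition:
    """One experimental set-up: a perturbation plus input overrides.

    cell_type is carried for bookkeeping when a condition is tied to one cell
    type; the measurement table addresses (condition, cell_type) pairs.
    """

    perturbation: Perturbation = Perturbation()
    cell_type: int | None = None
    inputs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.cell_type not in (None, 0, 1):
            raise ValueError("cell_type must be 0 or 1")


@dataclass
class Trajectory:
    """Simulated states on a time grid, optionally with log-parameter sensitivities."""

    t: np.ndarray
    x: np.ndarray                      # (T, n_states)
    sens: np.ndarray | None = None     # (T, n_states, n_params), d x / d log10 p
    state_names: list | None = None


@dataclass
class OdeModel:
    """Declarative ODE model shared by both cell types.

    rate_exprs are strings over state, parameter and input names, one per
    state.  initial entries are either numbers or names of ``p0`` parameters.
    gene_inputs maps a gene label to the input names scaling its transcription,
    translation and mRNA degradation, enabling the perturbation catalogue.
    """

    state_names: list
    rate_exprs: list
    parameters: list            # list[ParameterDef]
    initial: list               # per state: float or parameter name
    inputs: dict = field(default_factory=dict)
    gene_inputs: dict = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self):
        if len(self.rate_exprs) != len(self.state_names):
            raise ValueError("number of rate expressions must equal number of states")
        if len(self.initial) != len(self.state_names):
            raise ValueError("one initial condition per state required")
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        self._compiled = None

    # -- bookkeeping -------------------------------------------------------
    @property
    def param_names(self):
        return [p.name for p in self.parameters]

    @property
    def n_states(self):
        return len(self.state_names)

    @property
    def n_params(self):
        return len(self.parameters)

    def param_index(self, name):
        return self.param_names.index(name)

    def log_bounds(self):
        lb = np.array([p.lb for p in self.parameters])
        ub = np.array([p.ub for p in self.parameters])
        return lb, ub

    def compiled(self):
        if self._compiled is None:
            self._compiled = _compile(self)
        return self._compiled


# ---------------------------------------------------------------------------
# symbolic compilation
# ---------------------------------------------------------------------------

def _symbols_for(model):
    all_names = list(model.state_names) + model.param_names + list(model.inputs)
    if len(set(all_names)) != len(all_names):
        raise ValueError("state, parameter and input names must be distinct")
    return {n: sp.Symbol(n, real=True) for n in all_names}


def _parse_rates(model, syms):
    exprs = []
    for raw in model.rate_exprs:
        e = sp.sympify(raw, locals=syms)
        free = e.free_symbols - set(syms.values())
        if free:
            raise ValueError(f"unknown symbols {sorted(map(str, free))} in rate {raw!r}")
        exprs.append(e)
    return exprs


def _emit(name, exprs_by_target, unpack_lines):
    """Emit python source of a function assigning CSE'd expressions into arrays."""
    from sympy.printing.pycode import pycode

    flat, slots = [], []
    for target, shape, entries in exprs_by_target:
        for idx, e in entries:
            flat.append(e)
            slots.append((target, idx))
    repl, reduced = sp.cse(flat, symbols=sp.numbered_symbols("_c"))
    lines = [f"def {name}(x, p, u):"]
    lines += [f"    {l}" for l in unpack_lines]
    for target, shape, _ in exprs_by_target:
        lines.append(f"    {target} = np.zeros({shape!r})")
    for lhs, rhs in repl:
        lines.append(f"    {lhs} = {pycode(rhs)}")
    for (target, idx), e in zip(slots, reduced):
        if e == 0:
            continue
        lines.append(f"    {target}[{idx}] = {pycode(e)}")
    ret = ", ".join(t for t, _, _ in exprs_by_target)
    lines.append(f"    return {ret}")
    return "\n".join(lines)


class CompiledModel:
    """Numerical kernels generated from one OdeModel."""

    def __init__(self, model, f, fjac):
        self.model = model
        self.n = model.n_states
        self.k = model.n_params
        self._f = f
        self._fjac = fjac
        self._rhs, self._rhs_aug = self._make_rhs()

    def _make_rhs(self):
        f, fjac, n, k = self._f, self._fjac, self.n, self.k

        def rhs(y, t, p, u):
            xc = np.maximum(y, _XFLOOR)
            return f(xc, p, u)

        def rhs_aug(y, t, p, u, colscale):
            xc = np.maximum(y[:n], _XFLOOR)
            fv, jx, jp = fjac(xc, p, u)
            S = y[n:].reshape(n, k)
            sdot = jx @ S + jp * colscale
            out = np.empty(n + n * k)
            out[:n] = fv
            out[n:] = sdot.ravel()
            return out

        if n * (k + 1) < 24:
            # tiny systems: JIT compilation costs far more than it saves
            return rhs, rhs_aug
        try:  # optional JIT; pure-numpy fallback is always available
            from numba import njit

            f_c = njit(cache=False, fastmath=True)(self._f_raw)
            fjac_c = njit(cache=False, fastmath=True)(self._fjac_raw)

            @njit(cache=False, fastmath=True)
            def rhs_j(y, t, p, u):
                return f_c(np.maximum(y, _XFLOOR), p, u)

            @njit(cache=False, fastmath=True)
            def rhs_aug_j(y, t, p, u, colscale):
                xc = np.maximum(y[:n], _XFLOOR)
                fv, jx, jp = fjac_c(xc, p, u)
                S = y[n:].copy().reshape(n, k)
                sdot = jx @ S + jp * colscale
                out = np.empty(n + n * k)
                out[:n] = fv
                out[n:] = sdot.ravel()
                return out

            # trigger + validate compilation once
            x0 = np.full(n, 0.1)
            p0 = np.full(k, 0.5)
            u0 = np.array([float(v) for v in self.model.inputs.values()])
            rhs_j(x0, 0.0, p0, u0)
            rhs_aug_j(np.concatenate([x0, np.zeros(n * k)]), 0.0, p0, u0, np.ones(k))
            return rhs_j, rhs_aug_j
        except Exception:
            return rhs, rhs_aug

    # set by _compile
    _f_raw = None
    _fjac_raw = None


_COMPILE_CACHE = {}  # kernels depend on model structure only, share them


def _structure_key(model):
    return (tuple(model.state_names), tuple(str(e) for e in model.rate_exprs),
            tuple(model.param_names), tuple(model.inputs),
            tuple(str(i) for i in model.initial))


def _compile(model):
    key = _structure_key(model)
    if key in _COMPILE_CACHE:
        return _COMPILE_CACHE[key]
    cm = _compile_uncached(model)
    _COMPILE_CACHE[key] = cm
    return cm


def _compile_uncached(model):
    syms = _symbols_for(model)
    xs = [syms[s] for s in model.state_names]
    ps = [syms[p] for p in model.param_names]
    us = [syms[u] for u in model.inputs]
    rates = _parse_rates(model, syms)

    unpack = []
    for i, s in enumerate(model.state_names):
        unpack.append(f"{s} = x[{i}]")
    for i, p in enumerate(model.param_names):
        unpack.append(f"{p} = p[{i}]")
    for i, u in enumerate(model.inputs):
        unpack.append(f"{u} = u[{i}]")

    n, k = model.n_states, model.n_params
    f_entries = [((i,), e) for i, e in enumerate(rates)]
    jx_entries, jp_entries = [], []
    for i, e in enumerate(rates):
        for j, xsym in enumerate(xs):
            jx_entries.append(((i, j), sp.diff(e, xsym)))
        for j, psym in enumerate(ps):
            jp_entries.append(((i, j), sp.diff(e, psym)))

    src_f = _emit("f_fun", [("out", (n,), f_entries)], unpack)
    src_fj = _emit(
        "fjac_fun",
        [("out", (n,), f_entries), ("jx", (n, n), jx_entries), ("jp", (n, k), jp_entries)],
        unpack,
    )
    ns = {"np": np, "math": math}
    exec(src_f, ns)
    exec(src_fj, ns)
    cm = CompiledModel.__new__(CompiledModel)
    cm.model = model
    cm.n, cm.k = n, k
    cm._f = cm._f_raw = ns["f_fun"]
    cm._fjac = cm._fjac_raw = ns["fjac_fun"]
    cm._rhs, cm._rhs_aug = CompiledModel._make_rhs(cm)
    return cm


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def apply_perturbation(model, perturbation):
    """Return a copy of *model* with the perturbation folded into its inputs.

    knockout zeroes the gene's transcription and translation scales ("not
    produced at all"); degradation_x5 multiplies its mRNA degradation scale by
    5; synthesis_x2 doubles its transcription scale.  The original model is
    untouched and the compiled kernels are shared (only input values change).
    """
    if perturbation is None or perturbation.kind == "none":
        return model
    if perturbation.gene not in model.gene_inputs:
        raise KeyError(f"unknown gene {perturbation.gene!r}")
    slots = model.gene_inputs[perturbation.gene]
    inputs = dict(model.inputs)
    if perturbation.kind == "knockout":
        inputs[slots["transcription"]] = 0.0
        inputs[slots["translation"]] = 0.0
    elif perturbation.kind == "degradation_x5":
        inputs[slots["degradation"]] = inputs[slots["degradation"]] * 5.0
    elif perturbation.kind == "synthesis_x2":
        inputs[slots["transcription"]] = inputs[slots["transcription"]] * 2.0
    new = replace(model, inputs=inputs)
    new._compiled = model._compiled  # kernels depend on structure only
    return new


def _effective_inputs(model, condition):
    pert_model = apply_perturbation(model, condition.perturbation if condition else None)
    inputs = dict(pert_model.inputs)
    if condition is not None:
        for key, val in condition.inputs.items():
            if key not in inputs:
                raise KeyError(f"unknown input {key!r}")
            inputs[key] = val
    return np.array([float(inputs[u]) for u in model.inputs])


def _initial_state(model, params_lin):
    x0 = np.empty(model.n_states)
    for i, ic in enumerate(model.initial):
        if isinstance(ic, str):
            x0[i] = params_lin[model.param_index(ic)]
        else:
            x0[i] = float(ic)
    return x0


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _odeint(rhs, y0, times, args, rtol, atol):
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0):
        raise ValueError("times must be ascending")
    prepend = t.size == 0 or t[0] > 0.0
    tt = np.concatenate([[0.0], t]) if prepend else t
    if tt.size < 2:  # single time point 0
        return np.asarray(y0)[None, :][: t.size] if not prepend else np.empty((0, len(y0)))
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            sol, info = odeint(
                rhs, y0, tt, args=args, rtol=rtol, atol=atol,
                full_output=True, mxstep=800,
            )
        except Exception as exc:  # includes ODEintWarning promoted to error
            raise IntegrationError(str(exc)) from exc
    if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
        raise IntegrationError(info["message"])
    return sol[1:] if prepend else sol


def simulate(model, log_params, condition, times, rtol=1e-8, atol=1e-10):
    """Integrate the model at log10 parameters under one condition.

    Returns a Trajectory with states at the requested times; the condition's
    perturbation is applied before integration.  Solver failures raise
    IntegrationError, which callers map to a non-finite objective.
    """
    cm = model.compiled()
    p = np.power(10.0, np.asarray(log_params, dtype=float))
    if p.size != model.n_params:
        raise ValueError("log_params length mismatch")
    u = _effective_inputs(model, condition)
    x0 = _initial_state(model, p)
    t = np.asarray(times, dtype=float)
    if t.size and t[0] == 0.0 and t.size == 1:
        return Trajectory(t=t, x=x0[None, :], state_names=model.state_names)
    sol = _odeint(cm._rhs, x0, t, (p, u), rtol, atol)
    return Trajectory(t=t, x=sol, state_names=model.state_names)


def simulate_with_sensitivities(model, log_params, condition, times,
                                rtol=1e-8, atol=1e-10, method="forward",
                                fd_step=1e-4):
    """Simulate and return d x(t) / d log10 p for every model parameter.

    method "forward" integrates the forward sensitivity equations alongside
    the states; "fd" falls back to central finite differences on the log10
    parameters with the given step.
    """
    if method == "fd":
        return _simulate_fd(model, log_params, condition, times, rtol, atol, fd_step)
    cm = model.compiled()
    logp = np.asarray(log_params, dtype=float)
    p = np.power(10.0, logp)
    u = _effective_inputs(model, condition)
    x0 = _initial_state(model, p)
    n, k = cm.n, cm.k
    S0 = np.zeros((n, k))
    for i, ic in enumerate(model.initial):
        if isinstance(ic, str):
            j = model.param_index(ic)
            S0[i, j] = LN10 * p[j]
    colscale = LN10 * p  # d p / d log10 p
    y0 = np.concatenate([x0, S0.ravel()])
    t = np.asarray(times, dtype=float)
    # sensitivity components live on a much larger scale than the states;
    # a loose absolute floor there avoids resolving their noise near zero
    atol_vec = np.concatenate([np.full(n, atol), np.full(n * k, atol * 1e3)])
    sol = _odeint(cm._rhs_aug, y0, t, (p, u, colscale), rtol, atol_vec)
    x = sol[:, :n]
    S = sol[:, n:].reshape(len(t), n, k)
    return Trajectory(t=t, x=x, sens=S, state_names=model.state_names)


def _simulate_fd(model, log_params, condition, times, rtol, atol, h):
    logp = np.asarray(log_params, dtype=float)
    base = simulate(model, logp, condition, times, rtol, atol)
    n, k = model.n_states, model.n_params
    S = np.zeros((len(times), n, k))
    for j in range(k):
        lp = logp.copy(); lp[j] += h
        hi = simulate(model, lp, condition, times, rtol, atol)
        lp = logp.copy(); lp[j] -= h
        lo = simulate(model, lp, condition, times, rtol, atol)
        S[:, :, j] = (hi.x - lo.x) / (2 * h)
    return Trajectory(t=base.t, x=base.x, sens=S, state_names=model.state_names)


# ---------------------------------------------------------------------------
# observation mapping
# ---------------------------------------------------------------------------

@dataclass
class ObservationMap:
    """Map internal states onto observables, y = g(x, p_y).

    Expressions are strings over state names and (observation) parameter
    names.  Noise standard deviations are supplied with the data and are never
    estimated.
    """

    observable_names: list
    exprs: list

    def __post_init__(self):
        if len(self.exprs) != len(self.observable_names):
            raise ValueError("one expression per observable required")
        self._cache = {}

    def _compiled_for(self, model):
        key = id(model)
        if key not in self._cache:
            syms = _symbols_for(model)
            xs = [syms[s] for s in model.state_names]
            ps = [syms[p] for p in model.param_names]
            gs = []
            for raw in self.exprs:
                e = sp.sympify(raw, locals=syms)
                if e.free_symbols - set(xs) - set(ps):
                    raise ValueError(f"unknown symbols in observable {raw!r}")
                gs.append(e)
            gmat = sp.Matrix(gs)
            args = (xs, ps)
            g_f = sp.lambdify(args, gs, modules="numpy")
            dgdx = sp.lambdify(args, gmat.jacobian(xs).tolist(), modules="numpy")
            dgdp = sp.lambdify(args, gmat.jacobian(ps).tolist(), modules="numpy")
            self._cache[key] = (g_f, dgdx, dgdp)
        return self._cache[key]

    def state_indices(self, model):
        """If every observable is a bare state, return their indices, else None."""
        try:
            return [model.state_names.index(e.strip()) for e in self.exprs]
        except ValueError:
            return None

    def observe(self, model, traj, params_lin):
        """Observable values (T, M) on a trajectory."""
        g_f, _, _ = self._compiled_for(model)
        T = len(traj.t)
        out = np.empty((T, len(self.observable_names)))
        for ti in range(T):
            out[ti] = g_f(list(traj.x[ti]), list(params_lin))
        return out

    def observe_with_sens(self, model, traj, params_lin, colscale):
        """Observables and d y / d log10 p, using trajectory sensitivities."""
        g_f, dgdx_f, dgdp_f = self._compiled_for(model)
        T, M = len(traj.t), len(self.observable_names)
        k = model.n_params
        y = np.empty((T, M))
        dy = np.empty((T, M, k))
        for ti in range(T):
            xl, pl = list(traj.x[ti]), list(params_lin)
            y[ti] = g_f(xl, pl)
            gx = np.asarray(dgdx_f(xl, pl), dtype=float)
            gp = np.asarray(dgdp_f(xl, pl), dtype=float)
            dy[ti] = gx @ traj.sens[ti] + gp * colscale
        return y, dy
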