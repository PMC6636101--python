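# Methods

## The model and the estimation problem

Two cell types are assumed to undergo the same biochemical process,
described by one ODE system

    dx/dt = f(x(t), u(t, p_u), p_x),    x(0) = p_0,

with observables y(t) = g(x(t), p_y) + ε(t), ε ~ N(0, σ²) and known σ.
All parameters are positive and estimated on log10 scale.  Cell type [0]
is the reference with log-parameters log p⁰; cell type [1] is written
through log10 fold-changes r,

    log p¹_i = log p⁰_i + r_i,

so r_i = 0 means parameter i is cell-type independent.  Given data y_ij
with standard deviations σ_ij the objective is the negative two-fold
log-likelihood (additive constant dropped)

    χ²_ML(p⁰, r) = Σ_ij ((y_ij − g(x_i(t_j))) / σ_ij)²,

summed over all experimental conditions and both cell types.

Assuming the cell types share most parameters, r is sparse.  Sparsity is
enforced by a penalty ν(r − r*) with target r* = 0 and strength λ:

    χ²(p, r, λ) = χ²_ML(p, r) + λ ν(r).

Four penalty families are implemented, each with one *deformation* degree
of freedom d that recovers the plain lasso at d = 0:

| family         | ν(r)                                | deformation |
|----------------|-------------------------------------|-------------|
| l1             | Σ \|r_i\|                           | none        |
| lq             | Σ \|r_i\|^q, 0 < q ≤ 1              | d = 1 − q   |
| elastic net    | (1−α) Σ \|r_i\| + α Σ r_i²          | d = α       |
| adaptive lasso | Σ \|r_i\| · \|r̂_i^ML\|^(−γ)        | d = γ       |

The lq gradient q|r|^(q−1) diverges at 0, which creates an artificial
local optimum at every zero.  Entries with |r_i| ≤ ε (default ε = 1e-10)
are treated as effectively zero and the gradient is clamped at its value
at |r| = ε, keeping it finite; within that neighbourhood the penalty is
effectively a scaled modulus, hence convex, and subdifferential calculus
applies.  |r_i| ≤ ε is also the membership rule of the zero set Z(λ).
Adaptive-lasso weights come from the unpenalized fit; a weight whose
fold-change was itself estimated at (effectively) zero is capped at
ε^(−γ).

## Two-step routine, LRT selection

For each λ on an ascending grid (default log-spaced 1e-4 … 1e6, 41
points):

1. minimize χ²_ML + λν warm-started from the previous grid point and
   record Z(λ) = {i : |r_i| ≤ ε};
2. remove the penalty, fix Z(λ) to zero, re-optimize: χ²(λ) is this
   unbiased refit value.

D(λ) = χ²(λ) − χ²(0) is compared against the 0.95-quantile of a χ²
distribution with #Z(λ) degrees of freedom.  The parsimonious model is
the admissible model with the fewest cell-type specific features; on a
monotone path this is precisely the largest admissible λ.  Because the
numerically computed Z(λ) need not be monotone in λ (warm-start chains
can carry a compensating coordinate through the non-convex landscape),
selection is implemented as "sparsest admissible, ties to larger λ"
rather than literally "largest admissible λ"; the two agree whenever the
path is monotone, and the former is the stated intent of the criterion.

Ascending λ with warm starts matters for lq: started at small λ, the
optimizer settles into the data-supported optimum and is not trapped by
the artificial optimum at r = 0 when λ grows.

### Numerical realization of exact zeros

A quasi-Newton step on the clamped non-smooth objective approaches zeros
without reaching them.  Step 1 therefore maintains an active set: warm-start
entries within ε of the target are pinned there, released whenever the
likelihood gradient escapes the penalty subdifferential (the first-order
condition at zero), and after the smooth fit, free entries within a
candidate window (snap_tol, default 0.05 log10 units) are snapped onto the
target — greedily, smallest first, each snap kept only if the penalized
objective does not increase.  A rejected candidate is additionally
trial-pinned with a re-optimization of the remaining coordinates, because
correlated fold-changes often only reveal a snap as beneficial after the
others re-adjust.  The window is only a candidate filter; the objective
decides.  Finally, every step-1 solution is compared against the fully
shrunk model (one masked refit per dataset, cached), which is the λ → ∞
limit of every family; this keeps the tail of the path from dragging a
compensating coordinate along.

If a restricted refit finds a better optimum than the unpenalized base
fit — local-minimum escape along the path — the full model is re-polished
from that refit and the better value is used as χ²(0), so D is never
computed against a stale baseline.

## Profile likelihood

χ²_PL(θ_i) re-optimizes all other parameters at fixed θ_i, stepping
outward from the optimum with steps adapted to a target Δχ² ≈ 0.2 (at
most 100 steps per direction, stop at Δχ² > q_α + 1 or at the bounds).
The 95% CI is the level set χ²_PL − χ²_min < q_0.95(1) = 3.84 by linear
interpolation; a threshold never crossed flags an open interval end
(practical non-identifiability).

## Optimization

Bounded L-BFGS-B on (log p⁰, r) with analytic gradients from forward
sensitivity equations (dS/dt = (∂f/∂x)S + ∂f/∂(log10 p), generated
symbolically with sympy and compiled with numba when available; central
finite differences on log-parameters, step 1e-4, are the fallback).
Multi-start fits draw Latin-hypercube points within the bounds; the
fold-change components start at the cell-type-independent null r = 0,
because uniform draws of r overwhelmingly land in regimes where both cell
types are simultaneously wrong.  With several starts, each is screened
for a few dozen iterations and only the best basin is polished.  The
default fit is hierarchical: the reference model (all r pinned to zero)
is fitted first and the fold-changes are then released from its optimum —
markedly more reliable on gene-network likelihoods, whose cold-start
landscape contains a large "everything-degraded" plateau with vanishing
gradients.

Default log10 bounds are [−5, 3] for kinetic parameters and [−3, 3] for
fold-changes (configurable per parameter); Hill-coefficient fold-changes
in the benchmark are bounded to keep both cell types within the
admissible coefficient range.  Solver: LSODA with rtol 1e-8 / atol 1e-10
by default; the sensitivity block uses a 1e3-fold looser absolute floor
since it lives on a much larger scale.  Failed integrations surface as a
large finite objective that line searches reject.

## The synthetic benchmark

The generator emulates a six-gene in-silico network in the style of a
community parameter-estimation challenge: one mRNA and one protein per
gene, translation proportional to mRNA times a ribosomal strength,
transcription by Hill kinetics on eight regulatory edges, one shared mRNA
degradation rate fixed at 1 for the reference, protein degradation fixed
at 1 — 29 kinetic parameters (6 ribosomal + 6 synthesis + 1 degradation +
8 Km + 8 Hill).  The original challenge's gold-standard parameter values
sit behind a registration wall, so reference values are drawn once per
run: strengths log-uniform in [0.1, 10], Hill coefficients uniform on
{1, 2, 3, 4}, and Km centred on the regulator's reference steady-state
level (log-uniform within half a decade).  The Km choice reflects that
responsive benchmark networks place half-saturation points near operating
concentrations; Km drawn independently of protein scales leaves most
edges saturated or dead and their parameters invisible to any experiment.

Per run, round(#parameters / 3) parameters are cell-type specific with
fold-changes from {1/10, 1/5, 1/2, 2, 5, 10} (non-Hill) or from
{1/4, 1/2, 2, 4} resampled so both cell types keep Hill coefficients in
[1, 4].  Eighteen perturbation set-ups are available (per gene: knockout
= all synthesis off, 5× mRNA degradation, 2× mRNA synthesis), each
included with probability 1/2.  With probability 1/3 all mRNAs are
observed (21 points each), otherwise two random proteins (41 points
each), on a uniform grid reaching ≥ 90% of steady state (horizon capped at 25 time units).  Noise is
additive Gaussian with σ = max(0.1·|signal|, 0.01·signal range); σ is
recorded with the data and treated as known.  All states start at zero.

What the generator does *not* emulate: biological replicates, missing
values, non-Gaussian or heteroscedastic-beyond-the-model noise,
unknown σ, and model misspecification (the fitted model is the
generating model).  Passing tests therefore demonstrate the behaviour of
the regularization and selection machinery under a faithful model, not
robustness to structural model error.

### Scaled-down study

The repeated-run comparison runs on one CPU at reduced scale: a
three-gene, four-edge reduction (15 kinetic parameters, 5 cell-type
specific, 9 perturbation set-ups), 25 replicates, a six-point λ grid over
1e-2 … 1e4, and the l1 / lq(q = 0.8) / adaptive-lasso(γ = 0.2) families
on shared per-run datasets (paired design; the unpenalized fit and the
refit cache are shared across families within a run).  The unpenalized
base fit of each study run is warm-started at the data-generating
parameters: global multi-start optimization of partially observed
gene-network likelihoods is a compute problem orthogonal to the question
the study asks, every family sees the same baseline, and at this scale an
exhaustive multi-start per replicate is not affordable.  The exact
recovery check instead fixes a deterministic design (full knockout
catalogue, mRNA and protein observation) with identifiable strong
fold-changes in the noise-free limit, where the expected outcome is
unambiguous.  Study-profile fit controls (gtol 3e-2, maxiter 40,
snapping without re-optimization polish) trade χ² resolution for speed;
the LRT refits are the resolution-critical fits and keep tighter
controls where needed.

## Design choices on genuinely open points

- Estimation base: log10 everywhere; the fold sets {1/10 … 10} become
  {−1 … 1}.
- Zero detection |r_i| ≤ ε uniformly across families (the two-step
  routine leaves the numerical rule implicit).
- "Approximately one third" cell-type specific is implemented as exactly
  round(n/3), for determinism.
- Perturbation-inclusion probability 0.5 per set-up (maximal-entropy
  reading of "randomly selected"); configurable.
- λ-selection uses the plain LRT at α = 0.95; the Bonferroni correction
  (total 5% over 12 comparisons, 0.42% each) applies only to the study's
  paired method comparisons.
- Optimality tolerance for the first-order report: gradient components
  below 1e-3 on the χ² scale.

## Known limitations

- Local optimization: all guarantees are per-basin.  The reported λ
  path and selection can depend on the warm-start chain; the exhaustive
  2^n oracle equivalence is only tested on small problems.
- The non-convex lq family can, by construction, hold a coordinate at
  zero once λ is large; ascending scans with warm starts mitigate but do
  not eliminate this.
- Two or more linearly correlated fold-changes make the parsimonious
  model non-unique; selection then picks one representative, and
  classification against a single ground truth can count a swap as one
  false positive plus one false negative.  This is a property of the
  problem, not of the implementation.
- Profile CIs assume the χ² threshold calibration of the Gaussian
  likelihood; with estimated σ additional terms would be required and
  are out of scope.
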