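# foldreg

Detection of cell-type specific parameters in mechanistic ODE models by
penalized maximum-likelihood estimation.

## The problem

Two cell types — say healthy and malignant cells — undergo the same
biochemical process, modelled by one ODE system

    dx/dt = f(x, u, p_x),   x(0) = p_0,   y = g(x, p_y) + ε,

but possibly with different parameter values.  Writing the second cell
type through log fold-changes of the first,

    log p¹_i = log p⁰_i + r_i,

the biological question "in which parameters do the cell types actually
differ?" becomes a sparse estimation problem in r.  foldreg fits both
cell types jointly by minimizing the weighted least-squares objective
χ²_ML (the negative two-fold log-likelihood for Gaussian noise with known
σ) plus a sparsity penalty λ·ν(r), scans the penalty strength λ, refits
without the penalty at each λ to remove shrinkage bias, and selects the
sparsest model still compatible with the data by a likelihood-ratio
criterion: shrinkage with zero set Z(λ) is accepted while
D(λ) = χ²(λ) − χ²(0) stays below the 0.95-χ² quantile with #Z degrees of
freedom.

Four penalty families are available — l1 (lasso), the non-convex lq
pseudo-norm, Elastic Net and Adaptive Lasso — each parameterized by a
single *deformation* d that recovers l1 at d = 0.  The deformed families
exist because l1's level lines are rigid: when two log fold-changes are
linearly correlated (a frequent consequence of products of rates under
log-transformation), the l1 diamond aligns with the likelihood's
confidence region and false cell-type-specific calls result; bending the
level lines (q < 1, γ > 0, α > 0) breaks the alignment and raises
detection specificity.

The package also ships a fully synthetic benchmark — a DREAM6-style
six-gene Hill-kinetics network with 29 kinetic parameters, knockout /
degradation / over-expression perturbations and partial observability,
plus a three-gene reduction for single-CPU studies — that generates every
input itself; no external data is needed anywhere.

## Worked example

```python
import numpy as np
from foldreg import PenaltySpec, fit_ml, scan_lambda
from foldreg import benchmark as bm

# a reproducible synthetic two-cell-type problem (3-gene network)
run = bm.generate_run(bm.three_gene_config(), seed=123)
problem = bm.make_problem(run, rtol=1e-6, atol=1e-8)

base = fit_ml(problem, n_starts=4, seed=1)          # unpenalized ML fit
path = scan_lambda(problem, PenaltySpec("lq", deformation=0.2),
                   lam_grid=np.logspace(-2, 4, 7), seed=1, base_fit=base)
print(path.to_frame())
names = problem.penalized
found = sorted(names[i] for i in range(len(names)) if i not in path.final_zero)
print("lambda* =", path.lam_star)
print("cell-type specific:", found)
print("truly specific:    ", sorted(run.truth.specific))
```

Output:

```
     lambda  n_zero         chi2            D  threshold  admissible  failed
0      0.01       8   821.503237     0.000000  15.507313        True   False
1      0.10       8   821.503237     0.000000  15.507313        True   False
2      1.00       9   821.729868     0.226617  16.918978        True   False
3     10.00       9   821.729868     0.226617  16.918978        True   False
4    100.00      10   822.948537     1.445286  18.307038        True   False
5   1000.00      11   833.918825    12.415574  19.675138        True   False
6  10000.00      13  4616.343064  3794.839813  22.362032       False   False
lambda* = 1000.0
cell-type specific: ['rbs_g1', 'rbs_g2', 'syn_g1', 'syn_g2']
truly specific:     ['h_g1_g3', 'km_g3_g1', 'rbs_g1', 'syn_g2', 'syn_g3']
```

Reading this: along the λ scan more and more fold-changes are set to
zero (`n_zero`); the 11-zero model at λ = 1000 costs D ≈ 12.4, still
below its χ² threshold 19.7 and therefore compatible with the data,
while the 13-zero model at λ = 10⁴ is firmly rejected.  The selected
parsimonious model calls four parameters cell-type specific, two of them
truly so.  The misses and false calls are instructive rather than
embarrassing: under this run's randomly drawn design (two observed
proteins, a handful of perturbations) some fold-changes are barely
visible and others are entangled with correlated partners — exactly the
regime in which the deformed penalties earn their keep over plain l1 at
full study scale.

A command-line interface wraps the same pipeline for problems stored as
YAML + TSV (`foldreg fit / scan / profile / benchmark /
deformation-scan`), e.g.

    foldreg scan --problem problem.yaml --penalty lq --deformation 0.2 \
                 --lambda-min 1e-4 --lambda-max 1e6 --n-lambda 41 --seed 1

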