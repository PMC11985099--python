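# Methods

## Model and assumptions

The simulator output is treated as a fixed (nonrandom) function
f : X → R on a box X ⊂ [0, ∞)^d with 0 ∈ X, continuous at the origin, for
which an error bound b is available or estimable: f(x) − f(0) = O(b(x)),
b(x) = 0 iff x = 0.  The prior GP(0, σ²[k₀² + b(x)b(x′)k_e(x, x′)]) places
a flat component of scale k₀ on the unknown limit and models the normalized
error e(x) = (f(x) − f(0))/b(x) as a draw-like element of the RKHS of the
base kernel k_e.  All conditioning formulas are the k₀ → ∞ limit of the
proper conjugate GP; the finite-k₀ model is retained only (a) as an
independent oracle in the test suite and (b) for off-grid prediction in the
output-index direction of the tensor-product model, where the improper
limit has no finite covariance.

The prior is deliberately *conservative*: k_e is chosen by regularity
reasoning (how many derivatives the normalized error plausibly has), not by
belief elicitation, and the data-driven scale σ_n² counteracts the
resulting pessimism.  Observations are noise-free; there is no likelihood
for stochastic simulators.

## Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| `orders r` | convergence order(s) of b | — (user/estimated) | the central modelling input |
| `smoothness s` | base-kernel smoothness, s ∈ {0, 1, 2} or ∞ | 2 | Matérn-5/2 matches the benchmark problems; misspecifying s too high empirically still extrapolates well but can overstate confidence |
| `lengthscales ℓ` | correlation length of e(x), same units as x | 1 | the benchmark scale; estimated by grid search in the workflow |
| `k₀` | prior scale on f(0) | ∞ (improper) | objective choice; finite only for off-grid index prediction |
| jitter | adaptive diagonal regularization | 1e-12·tr(K)/n, ×10 up to 6 times | Gram matrices of smooth kernels on clustered designs are near-singular |
| grid defaults | r ∈ {0.5, 1, 2}, s ∈ {0, 1, 2}, 10 log-spaced ℓ in [0.1, 10]×range(X) | — | small grids; the quasi-likelihood surface can be multimodal, so no continuous optimization is attempted |

Credible intervals are Gaussian: m_n[f](0) ± Φ⁻¹(1 − α/2)·k_n[f](0,0)^{1/2},
degenerate (width zero) when σ_n² = 0, which happens exactly for constant
data (and n = 1).  σ_n² is clipped at zero against roundoff.

## Order estimation: printed vs. profiled objective

The quasi-likelihood L(r) = −yᵀK⁻¹y + (1ᵀK⁻¹y)²/(1ᵀK⁻¹1) − logdet K is the
default objective, and its quadratic part equals −n·σ_n² (an identity the
tests verify).  This objective is *scale-sensitive*: the quadratic term
enters on the squared magnitude of the normalized error, while the Occam
(logdet) term that rewards the true order grows only logarithmically as the
design is scaled toward 0.  On a problem whose normalized error is large —
the central-difference testbed has e(0) ≈ −167 — the true order therefore
cannot win the comparison until the design scale is astronomically small
(verified in extended precision: the crossover lies beyond h ≈ e⁻⁷⁰).  The
scale-profiled variant −n·log σ_n² − logdet K removes this sensitivity, and
with it the one-sided consistency behaviour (estimated order eventually at
or above the true order) appears at desk scale on every testbed; it is
exposed via `profile_sigma=True` and used where order recovery is the goal.
Ties in the grid argmax break toward smaller r, then s, then ℓ —
conservative, since slower assumed convergence widens intervals.

## Experimental design

The objective 1ᵀK_b⁻¹1 is the inverse posterior variance at the limit with
the scale held fixed (no data exist yet from which to estimate it).  It is
monotone under subset inclusion, so designs saturate once the budget covers
every candidate.  Exhaustive search enumerates subsets with budget pruning
(cap 25 candidates, then automatic greedy fallback); greedy is forward
selection on objective gain.  Ties break toward lower total cost, then the
lexicographically smaller index set, for determinism.  For iterative
methods whose intermediate iterates are free (`cumulative_iterative` cost
models), the longest affordable prefix is returned without search.  Budget
comparisons carry a 1e-12 relative tolerance so that an exactly saturating
budget is not rejected by floating-point summation order.

The theory utilities (γ_d recursion, box fill distance with an exact gap
scan in d = 1 and bisection to 1e-6 over corner-grid boxes in d ≥ 2, and
the coverage-condition reporter ρ ≤ 1/(γ_d(r + 2s))) are diagnostics only.

## Multi-output model

Output on a Cartesian grid of n₁ fidelities × n₂ indices uses the
separable covariance σ²[k₀² + b b′k_e]·k_T with Kronecker Gram
K_X ⊗ K_T; every solve uses two small factorizations, never the n₁n₂ dense
matrix.  In the improper limit the flat directions are the per-index
constants, so the conditional mean at (0, t_j) decouples into the scalar
estimate applied to column j, while σ_n² couples columns through K_T; the
improper-limit covariance at the grid follows from the k₀ → ∞ limit of the
proper Kronecker GP (derived independently and validated numerically
against finite-k₀ solves at k₀ up to 1e8, with the Sherman–Morrison
reduction applied analytically to avoid cancellation).  Off-grid index
prediction requires finite k₀ by construction.  The default index kernel
is Gaussian with length-scale equal to the span of the index grid.

## Numerical choices

* All solves go through Cholesky with adaptive jitter (above); failure
  raises a conditioning error naming the closest pair of design points.
* The E-algorithm solves the instantiated ansatz as a linear system;
  the determinant-ratio form is retained for cross-checking.  Systems with
  condition number above 1e14 raise a degenerate-scheme error.
* Convergence studies fit the log–log error slope by least squares,
  excluding rows below a roundoff floor (1e-12·max(1, |f(0)|) in double
  precision).  An extended-precision backend (mpmath, default 50 digits)
  reruns both the simulator evaluations and the GP solve in arbitrary
  precision, letting the studies follow the error over the full dyadic
  h-range; it is practical for the n ≈ 5 designs used here.
* A query point with b(x) = 0 is treated as the origin (its cross-
  covariance with all data vanishes identically).

## Synthetic simulator: what it does and does not emulate

`synthetic_md_simulator` stands in for an expensive multi-discretization
code: f(x) = f0 + Σᵢ cᵢ xᵢ^{rᵢ}(1 + gᵢ(xᵢ)) with known limit f0, known
per-axis orders, coefficients cᵢ ∈ [0.5, 2], smooth bounded modulations
gᵢ(xᵢ) = aᵢ sin(ωᵢxᵢ + φᵢ) with |aᵢ| ≤ 0.3 and ωᵢ ∈ [0.5, 2], all fixed by
a seed, and an inverse-power cost model c(x) = Σᵢ xᵢ⁻¹.  The modulations
are separable by design, keeping the simulator consistent with the
additive error bound the workflow posits so that per-axis orders are well
defined.  It is deterministic (no observation noise), matching the
noise-free setting of the scalar model.  It does **not** emulate
cross-axis error interactions, pre-asymptotic regimes where the power law
has not set in, stochastic solver output, or cost heterogeneity beyond the
power law — so passing tests demonstrate correct behaviour of the
machinery under the model's own assumptions, not robustness to their
violation on real codes.

## Workflow problem sizes

The end-to-end workflow study uses d = 2 with true orders (1, 2), lo-fi
setting (0.4, 0.4), five probe points per axis spanning a factor 16, a 3×3
candidate grid {0.05, 0.1, 0.2}² with a saturating budget, and 20 seeds;
the scalar convergence studies use the fixed n = 5 designs {0.2, …, 1}
(central differences) and {1, …, 1/16} (trapezoid) scaled over dyadic h.
These sizes keep every study deterministic and fast while exercising the
full pipeline.

## Known limitations

* Noise-free observations only; no replicate handling.
* Order estimation is grid-only; the estimate is one-sided by nature
  (an error that decays faster than the bound legitimately inflates it).
* Design search is non-sequential; costs of candidates must be known or
  tabulated in advance, not predicted.
* Multi-output support requires a complete Cartesian grid (no imputation)
  and a uniform-in-index error bound.
* Wendland kernels are implemented for d = 1 only, matching their use in
  the benchmarks.
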