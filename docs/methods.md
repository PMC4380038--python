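# Methods

## The model class

Sites evolve independently and identically under a continuous-time,
time-homogeneous Markov process on `{A, C, G, T}` (state order fixed
everywhere). A process on one phylogenetic edge is a pair `(Q, t)`: a
4×4 generator with zero row sums and nonnegative off-diagonals, and a
nonnegative duration. Since only the product `Qt` is identifiable from
the endpoint joint distribution, edge processes are compared through the
**expected number of substitutions**

    n(t) = -∫₀ᵗ f(s) ds · diag(Q),   f(s) = f(0) exp(Qs),

which depends only on the identifiable quantities. With a stationary
start (`f(0) = π`, `πQ = 0`) this is `-Σᵢ πᵢQᵢᵢ · t`, the familiar
branch length; for a calibrated generator (`-Σᵢ πᵢQᵢᵢ = 1`, obtained by
dividing any generator by its stationary rate) it is exactly `t`.
Calibration is idempotent and scale-equivariant; it uses the generator's
own stationary distribution unless an explicit frequency vector is
given. For nonstationary fits no calibration is applied — the scaled
generator is reported as-is and ENS is the edge length.

ENS is evaluated three ways, which cross-check one another in the tests:

1. **Augmented matrix** (production route): `n(t) = f(0)·exp(Ct)[1..4,5]`
   with `C = [[Q, -diag(Q)], [0, 0]]`. One Padé/scaling-and-squaring
   matrix exponential; robust for defective generators.
2. **Quadrature oracle**: Simpson integration of `-f(s)·diag(Q)` on a
   uniform grid with stepwise-exact propagation of `f` (default 10⁴
   steps; agreement with route 1 is < 1e-6 for t ≤ 5).
3. **F81 closed form**: for `Qᵢⱼ = α πⱼ`,
   `n(t) = αt Σᵢ πᵢ(1-πᵢ) + (1-e^{-αt}) Σᵢ (1-πᵢ)(fᵢ(0)-πᵢ)`.
   The correction term is the derivative of the ENS integral under the
   known relaxation `fᵢ(s) = πᵢ + (fᵢ(0)-πᵢ)e^{-αs}`; its sign
   convention is fixed by that derivation and verified against routes
   1–2. It vanishes for uniform π (hence for JC/K2P/K3P) and for a
   stationary start, and can take either sign otherwise — a stationary
   analysis can over- **or** understate the distance.

An eigendecomposition-based evaluator for the scale profile
`s ↦ n(f₀, sA)` backs the clock constraint solver and the simulator; it
falls back to the augmented route when the generator's eigenvector matrix
is ill-conditioned (condition number > 1e8). The map is monotone
(integrand ≥ 0), so the constraint `n(f₀, sA) = target` is solved by
bracketed Brent root-finding (tolerance 1e-12).

## Triads and the model hierarchy

All fitting is to **triads**: three taxa with a declared ingroup pair and
outgroup. The two edges emanating from the tree root are not separately
identifiable, so they are merged and the process is rooted at the ingroup
ancestor — a three-edge star. Pattern probabilities are

    p(x₁,x₂,x₃) = Σ_r f(r) · P₁[r,x₁] P₂[r,x₂] P₃[r,x₃]

summed over the four root states (and averaged over four discrete rate
bins for Γ families). All data enter through the 64 ordered site-pattern
counts.

Three families, fitted by maximum likelihood in order of increasing
generality:

| family   | free parameters | dof |
|----------|-----------------|-----|
| GTR      | 5 exchangeabilities + 3 frequencies + 3 durations | 11 |
| GTR+Γ    | GTR + Γ shape (4 equal-probability bins, bin means) | 12 |
| General  | 3 root probabilities + 12 off-diagonals of `A = Qt` per edge | 39 |

Clock variants constrain the two ingroup edges to equal ENS length and
have one fewer dof (10/11/38). For GTR families the constraint is a
shared duration parameter (exact); for the General family the second
ingroup edge is parameterized as a direction whose scale is solved from
the ENS equality at every likelihood evaluation. The dof values are
derived from the parameterizations above.

GTR families share one calibrated reversible generator
(`Qᵢⱼ = Rᵢⱼπⱼ`, symmetric `R`, GT exchangeability fixed at 1) across
edges with the root distribution pinned to its stationary π. The General
family optimizes the identifiable per-edge products `A = Qt` directly
(durations fixed at 1); a calibrated `(Q, t)` decomposition can be
derived afterwards but is not unique and is never used internally.

## Optimization

All positive parameters are optimized on the log scale, the root
distribution through a softmax, with L-BFGS-B (memory 50, ftol 1e-14,
gtol 1e-9 on the per-site objective). Looser tolerances were observed to
terminate 39-parameter General fits over a hundred log-likelihood units
short of the optimum, which would corrupt likelihood-ratio statistics.
Bounds: exchangeabilities and the Γ shape in [1e-6, 200], durations in
[1e-8, 50], entries of `A` in [1e-9, 100], softmax weights in [±30].
Initial rates are floored at 1e-6 so interior iterates never produce a
zero-probability pattern; a pattern with positive count and zero model
probability is reported as an explicit `-inf` failure state, never
silently.

The General free fit uses an **analytic gradient**: the gradient with
respect to each edge's transition matrix follows from the pattern sums,
and is pulled back through the matrix exponential in one pass per edge
via the adjoint identity `⟨G, L(A,E)⟩ = ⟨L(Aᵀ,G), E⟩` for the Fréchet
derivative `L`. The clock variant additionally differentiates through
the implicitly defined scale of the constrained edge (implicit function
theorem on the ENS equality; the augmented 5×5 exponentials supply both
the transition matrices and the constraint sensitivities). Both
gradients are verified against finite differences in the test suite.
GTR-family fits (≤ 14 parameters) use finite differences.

Fits start from the seeding model when one is given (sequential chains:
GTR seeds GTR+Γ and General; clock fits seed their free counterparts),
otherwise from an empirical heuristic (pooled composition,
Jukes–Cantor-corrected pairwise times, unit exchangeabilities). Because
L-BFGS-B only accepts objective decreases, a seeded fit can never end
below its seed — this makes `lnL(General) ≥ lnL(GTR)` and
`lnL(free) ≥ lnL(clock)` structural guarantees rather than empirical
observations. Random restarts are available (`n_restarts`) but default
to zero: seeded chains converged reliably in all replicate studies, and
restart-free fits keep bootstrap and calibration suites fast.

## Diagnostics

**Goodness of fit.** `G = 2 Σ O ln(O/E)` over the 64 patterns (equal to
the likelihood-ratio statistic against the saturated multinomial). Its
null distribution is estimated by parametric bootstrap: simulate
`n_reps` alignments (default 100, P-value resolution 0.01) of the
original length from the fitted model, refit each by the *original*
procedure (heuristic start, sequential seeding), and report the fraction
of replicate G values exceeding the observed one. Refitting replicates
from the null parameters instead was found to converge the replicates
systematically better than the original fit and deflate the P-value.
Replicates whose refit fails are excluded and counted. Replicates are
not screened by the identifiability filters: the filters guard
interpretation of estimates, not the null distribution of G.

**Identifiability filters.** A fitted edge is trustworthy when its
transition matrix (a) is Diagonal-Largest-in-Column — every diagonal
entry strictly exceeds the rest of its column, ties within 1e-12
failing, which pins down internal-state labeling — and (b) passes a
conservative uniqueness check for the generator: all eigenvalues real,
strictly positive, and distinct (relative tolerance 1e-8), in which case
the principal logarithm is the only real logarithm. Repeated spectra
(e.g. any Jukes–Cantor transition matrix) fail conservatively even
though a generator obviously exists; `det P ≤ 0` always fails.

**Molecular clock.** The relative-rate test compares a clock-constrained
fit to its free counterpart: `2ΔlnL` (floored at 0) referred to χ²₁. No
boundary-mixture correction is applied — the constraint is an interior
equality, not a boundary. Mismatched families, data, or a likelihood
ordering violation beyond 1e-6 raise errors (the last signals optimizer
failure).

## The simulator

`simulate_alignment` draws i.i.d. sites: root state from the root
distribution, a rate bin for Γ families, then each leaf state directly
from its edge's transition probabilities — no waiting-time simulation,
since only end states appear in an alignment. Randomness uses one
spawned stream per role (root, bins, each edge) so draws on one edge
never perturb another.

`random_general_model` generates study processes: Dirichlet(1.5) root
composition, lognormal(0, 1) off-diagonal rate directions per edge, each
edge rescaled so its ENS is uniform on `ens_range` (default 0.05–0.5
substitutions/site, the range typical of the divergences this method
targets). Departure from stationarity is controlled by rejection
sampling on the JSD between the root composition and every leaf marginal
(`jsd_floor`). What this emulates — and what it does not: sites are
i.i.d. (no rate autocorrelation, no indels, no selection heterogeneity
along the sequence), so passing recovery and calibration tests
demonstrates correctness of the estimator under its own assumptions, not
robustness to misspecification on real data. One consequence observed
while validating the bootstrap: an arbitrary random generator is *not*
reversible, so "GTR-generated" study data must be built from a symmetric
exchangeability matrix — misspecified data inflate G honestly.

## Problem sizes used in the verification suites

Chosen as the package's own study design: recovery uses 20 replicates of
50,000 sites (General: median per-edge ENS error < 5%, median max-entry
root error < 0.02; GTR: median distance error < 3%). Clock-test
calibration uses 200 clock-true replicates of 5,000 sites (5% rejection
within [0.02, 0.09]) and 100 replicates with a twofold rate multiplier
for power (> 0.8). The bias study uses five nonstationarity strata —
JSD floors 0, 0.01, 0.03, 0.06, 0.10 paired with ENS ranges widening
from 0.05–0.5 to 0.3–1.0, since strong compositional divergence is only
reachable along longer edges — of 50 alignments × 2,000 sites each, and
checks that the median ingroup `dGTR − dENS` increases with the stratum
(positive rank correlation). Bootstrap calibration is scaled down to 20
outer replicates × 20 bootstrap replicates at 1,000 sites
(Kolmogorov–Smirnov uniformity at α = 0.01).

## Known limitations

- Nucleotides only; no amino-acid or codon state spaces.
- Triads only; no tree search, and no rate heterogeneity for the
  General (nonstationary) family — the Γ extension is defined for the
  stationary families alone.
- The General clock fit parameterizes the constrained edge by 12
  direction parameters plus an implicit scale, leaving one flat
  direction in parameter space (handled fine by L-BFGS-B, but the
  reported optimum is one point on a ridge of equivalent parameter
  vectors).
- The clock LRT statistic is mildly conservative at 5,000 sites under
  the 39-parameter General model (mean statistic ≈ 0.86 vs the χ²₁ mean
  of 1), a finite-sample effect of referring a 39-parameter model's
  1-dof comparison to its asymptotic distribution.
- The paralinear distance requires strictly positive marginal
  frequencies and a positive determinant; saturated or degenerate joints
  raise `SaturationError` rather than returning a value. A Laplace
  pseudocount mode exists but is off by default (raw frequencies are the
  documented behavior).
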