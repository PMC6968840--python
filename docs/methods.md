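# Methods

## Model and assumptions

Population structure is a connected, weighted, undirected graph on `N`
vertices with nonnegative symmetric weights and zero diagonal (no
self-loops); one haploid individual per vertex. Selection is constant:
mutants have fitness `r > 0`, residents 1. The update rule is
death-Birth (dB): a uniformly random individual dies, and neighbor `j`
of the vacancy `d` reproduces into it with probability
`f_j w_jd / Σ_k f_k w_kd` (`f` = fitness). The only initial condition
implemented is a single mutant at a uniformly random vertex, matching
the standard definition of fixation probability; per-vertex fixation
probabilities are exposed for diagnostics.

Graphs are stored densely (`N×N` float array); constructors refuse
`N > 2000`, since the pairwise coalescence system itself caps the
practical size well below that.

## Coalescence engine

Neutral dB ancestry is traced backwards by a pair of coalescing random
walkers: at each step one of the two walkers (chosen with equal
probability) moves by the step matrix `p_ij = w_ij / w_i`. Pairwise
meeting times `τ_ij` satisfy an absorbing-chain linear system whose
generator on ordered pairs has Kronecker structure
`(P ⊗ I + I ⊗ P)/2`, with diagonal pairs absorbing at time 0. We
assemble the `N² × N²` sparse system directly from that structure. The
equations for `(i,j)` and `(j,i)` coincide, so the solution is
symmetric; symmetry is enforced exactly on output.

Solver choice: the pair graph is an expander, so sparse LU fill-in
grows quickly with `N`. We use direct LU (SuperLU) with up to three
iterative-refinement passes for `N ≤ 25` — robust to the severe
ill-conditioning of tiny-`ε` family graphs, where meeting times reach
`~1/ε` — and lgmres (`rtol 1e-12`) beyond, where the dynamics mix well
and Krylov iteration converges in a handful of steps. Every equation's
residual is checked against `1e-9` and a `NumericalError` is raised on
failure, so an inaccurate solve can never silently propagate.

Derived quantities: remeeting times `τ_i = 1 + Σ_j p_ij τ_ij`,
`N_eff = Σ_i π_i τ_i`, and the Kac return-time residual
`|Σ_i π_i² τ_i − 1|`, which is reported with every result as a
solver-independent diagnostic (typical values `1e-12`, tolerance
`1e-8`). The covariance identity
`(N − N_eff)/N² = cov(π_i, π_i τ_i)` is exposed as a residual check;
its sign gives the amplifier/suppressor criterion.

All tolerances live in one frozen `Tolerances` object: equation
residual `1e-9`, Kac `1e-8`, isothermality (relative degree spread)
`1e-10`, direct-solver cutoff `N = 25`, Krylov `rtol 1e-12`,
finite-difference step `1e-5`.

## Closed forms and the neutral seam

Closed-form `ρ(r)` is provided for the complete graph, star, cycle, and
the `ε → 0` limits of the Fan `F_{n,m}`, Separated Hubs `SH_{n,m,h}`
and Star of Islands `SI_{n,m,h}`, plus the many-blade / many-island
limits. Closed-form `N_eff` is provided for the Fan at arbitrary `ε`
and for the `ε → 0` limits of all three families (`SH` at arbitrary
`ε` is served by the numeric solver instead). `ε = 0` itself
disconnects these graphs — fixation is then impossible — so the
constructors reject it and the limits live exclusively in the closed
forms.

Every closed form has a removable singularity at `r = 1`. Inside a
window `|r − 1| < 5e-7` each switches to its first-order series
`1/N + (r−1)(N_eff−2)/(2N)` using that family's `N_eff`; the window is
sized so the two branches agree to ~`2e-10`, well inside the `1e-9`
continuity budget. Large exponents (e.g. `r^{-n(m+1)}` at `n = 10^4`)
are evaluated through IEEE overflow to `inf`, which yields the correct
limiting value of the ratio.

The Star of Islands formula uses an auxiliary migration ratio

    x = [m r^{−m}(r^{m−1} − 1) + h(r^{h−1} − 1)] /
        [m r^{h}(r^{m−1} − 1) + h(r^{h−1} − 1)]

with numerator polynomial
`r^m (1 − r^{−1})(1 − r^{−(h+m)}) [h r^h (1 − r^{−(h−1)})(mn(m−1)r^m + h(h−1)) + m r^m (1 − r^{−(m−1)})(mn(m−1) + h(h−1)r^h)]`
and denominator
`(mn+h)(h(1 − r^{−(h−1)}) + m r^m (1 − r^{−(m−1)}))(m r^m (1 − r^{−(m−1)})(1 − x^n) + h(1 − r^{−(h−1)})(r^{h+m} − x^n))`.
Within the validated parameter range (`n, m, h ≤ 6`, `r ∈ [0.05, 50]`)
all intermediate quantities stay inside double range; far outside it the
formula may overflow and should be evaluated in logs.

## Exact chain and Monte Carlo

The exact solver builds the full absorbing Markov chain over mutant
subsets encoded as bitmasks and solves the absorption system by sparse
LU. The default cap is `N ≤ 14` (16384 states); in practice `N ≤ 10`
solves in well under a second and `N = 12` in a few seconds. At `r = 1`
the per-vertex fixation probabilities sum to exactly 1 (one of the
initial lineages must win), which serves as a structural self-check.

The simulator advances all trials of a run in one vectorized batch from
a single `numpy` generator seeded explicitly, so runs are
bit-reproducible given their seed. Absorption is almost sure on a
connected graph, so no step cap is applied by default; an optional
`max_steps` guards near-disconnected graphs, and capped trials are
counted and excluded from the estimate, never silently dropped. Parent
sampling uses cumulative-weight inversion over the vacancy's neighbors;
a zero total neighbor weight is impossible on a connected graph and is
asserted.

## Classification

Full-`r` verdicts compare `ρ_G` with the well-mixed `ρ_{K_N}` on a
log-spaced grid (default 0.05–50, 200 points). The two curves are
tangent at `r = 1` whenever the graph is isothermal-like, so grid
points with `|ρ_G − ρ_K| ≤ 1e-9 · max(ρ_K, 1/N)` are treated as ties
and excluded from the sign-pattern analysis. Patterns map to verdicts:
`−/+` amplifier, `+/−` suppressor, `−/−` reducer, `−/+−` transient
amplifier (with `r*` then refined by Brent bracketing to `1e-10`), all
ties neutral-equivalent; anything else — e.g. multiple sign changes
above 1 — is reported as indeterminate with the pattern attached.
Verdicts are necessarily *grid-bounded*: the defining inequalities
quantify over all `r`, which no finite computation can check; the grid
maximum of 50 plus the analytic `r → ∞` limits of the closed forms is
the evidence offered. The weak-selection verdict is separate and
exact-in-principle: the sign of `N_eff − N` at relative tolerance
`1e-9`.

Whether *all* isothermal graphs are reducers is an open question; the
package reports per-graph evidence and never asserts the conjecture.

## Random-graph generators and what they emulate

Erdős–Rényi draws link each pair independently with
`p = ⟨k⟩/(N−1)`; by default disconnected draws are rejected and
redrawn with the redraw count recorded in `meta` (`N_eff` is undefined
on disconnected graphs; the non-rejecting mode is exposed for degree
statistics). Barabási–Albert growth starts from a complete seed graph
of size `m+2`, so the minimum-size graph is complete and
`N_eff/N = 1` there. Random regular graphs come from the pairing model
with rejection of defects and of disconnected draws. These ensembles
emulate the *heterogeneity* of real contact structures, not any
particular biology: all sampled graphs turn out to suppress weak
selection, consistent with the degree-moment approximation
`N_eff ≈ N μ₁²/μ₂ ≤ N` (equality iff isothermal — note `μ₁² ≤ μ₂` is
forced by variance nonnegativity). Passing ensemble tests therefore
shows the solver and the approximation agree on these models; it says
nothing about graphs engineered to amplify, which the approximation
cannot detect by construction.

## Perturbation recipe

For a family isothermal at `ε = 0`,
`dN_eff/dε|₀ = −Σ_i τ_i dπ_i/dε|₀`, with `dπ/dε` computed analytically
from the degree perturbation (avoiding compounded finite-difference
error); the finite-difference cross-check at step `1e-5` agrees to
`1e-3` relative. The amplifier construction picks the vertex of largest
remeeting time (smallest index on ties), then the incident edge whose
down-weighting gives the largest gradient; neighbors whose perturbed
edge would disconnect the graph are passed over for the next-best
gradient, and both choices are user-overridable. Small `ε` then always
amplifies when the gradient is positive; whole-edge deletion (`ε` equal
to the edge weight) amplifies only for particular graphs, found by
search over seeds.

## Problem sizes used in validation

The shipped test suite validates: oracle equivalence chain-vs-closed
forms on `N ≤ 8` (6 fitness values each), `ε → 0` limits against
`ε = 1e-6` chains on `N ≤ 9`, the isothermal theorem on 20 graphs,
neutral-slope agreement on mixed graphs with `N ≤ 10` (central
difference, step `1e-3`, tolerance `10h²`), Kac/covariance identities
on 200 mixed random graphs (`N ≤ 40`), classification tables over
`n, m, h ≤ 6`, ensembles of 100 ER + 100 BA graphs with `N ≤ 60`, and
Monte Carlo calibration at `10⁵` trials against exact chains on
`N ≤ 10`. These sizes keep the full suite around a minute while
exercising every code path; all engine tolerances are independent of
problem size.

## Known limitations

* The exact chain is capped at `N ≤ 14`; beyond that only the
  weak-selection expansion, closed forms, and Monte Carlo are available.
* Closed-form results for the example families hold in the `ε → 0`
  limit; at small positive `ε` they are `O(ε)` approximations, and
  conclusions that combine `ε → 0` with `n → ∞` or `r → 1` can depend
  on the order of limits.
* Fixation *times* are not analyzed (they diverge in the small-`ε`
  families); step counts are recorded per trial but not reported.
* Only death-Birth updating is implemented; the coalescence machinery
  for Birth-death updating would require a different pair walk.
* Directed graphs, self-loops, multigraphs and temporal graphs are out
  of scope.
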