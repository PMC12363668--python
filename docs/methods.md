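# Methods

## Model

A population of `N` haploid individuals occupies the vertices of a strongly
connected directed graph `G = (V, E)`; edge `(u, v)` lets the offspring of
`u` replace the occupant of `v`.  All individuals have identical fitness
and there is no mutation.  One *step* is a single replacement event:

- **bd**: birth vertex `u ~ Uniform(V)`, death vertex
  `v ~ Uniform(out-neighbours(u))`; event probability `1/(N deg+(u))`.
- **db**: death vertex `v ~ Uniform(V)`, birth vertex
  `u ~ Uniform(in-neighbours(v))`; event probability `1/(N deg-(v))`.

The state is the type vector `x = (x_1, …, x_N)`.  Homogeneous states are
absorbing; the quantity of interest is the expected number of steps to
absorption from maximal diversity (type `i` at vertex `i`).  Steps that
change nothing — the offspring lands on its own type, or a self-loop
replaces a vertex with itself — consume one time unit; the closed forms
below count time the same way, so "laziness" of the chain is part of the
model, not an implementation artefact.  Self-loops count once in both
degrees, making the complete graph *with* self-loops (`deg+ = N`) the
well-mixed population.  Time is measured in steps throughout; `N` steps
correspond to one generation, and the CLI can report `steps/N` for display.

## Exact computation

**Full chain.**  Expected absorption times solve `τ_x = 0` on homogeneous
states and `τ_x = 1 + Σ_x' p(x→x') τ_x'` otherwise.  With `N^N` states this
is only an oracle; the implementation caps it at `N ≤ 5` and uses it to
validate the lumped solver.

**Lumped chain.**  Neutrality makes type labels exchangeable, so the
process on unlabelled *set partitions* of `V` (which vertices currently
share a type) is Markov: the event `(u, v)` maps partition `Ω` to the
partition in which `v` joins the block of `u` (empty blocks dropped).  The
state count is the Bell number `B_N` (4140 at `N = 8`).  States are
canonicalised as restricted-growth strings and indexed in lexicographic
order; the transient system `(I − Q) τ = 1` is solved with SuperLU through
`scipy.sparse`.  The nominal cap is `N = 12`; in practice `N ≤ 8` (a few
seconds per graph) is the routine regime and `N ≥ 9` (`B_9 = 21147`) takes
minutes, which is why the exhaustive two-rule sweeps in the tests run at
`N ≤ 6` (143 graphs, Bell(6) = 203 states) and `N = 8` exact solves are
reserved for the named families.  An exact-rational mode (`Fraction`
Gaussian elimination, `N ≤ 6`) provides bit-exact regression values such as
the 6-vertex star's bd time 1337/12.

**Fixation probabilities.**  With two types, the occupied set of the focal
type is a Markov chain on the `2^N` vertex subsets; the solver handles
`N ≤ 14` and is used both for the star-centre law `1/(1 + n²)` and for the
sum-to-one identity over singleton starts.

**Closed forms** are evaluated in rational arithmetic.  For the well-mixed
population from abundance vector `λ = (λ1 ≥ … ≥ λk)`, with
`b_h = Σ_i max(λ_i − h, 0)`:

    T = N² − N − Σ_i Σ_{ℓ=1}^{λ_i−1} (N + λ_i − 2ℓ) ℓ/(N−ℓ)
      = N (N − Σ_{h=0}^{N−1} b_h/(N−h)),

both forms evaluated and cross-asserted on every call (and exhaustively for
every partition of every `N ≤ 12` in the tests).  From maximal diversity
this is `N(N−1)`; without self-loops, `(N−1)²`.  For the cycle, where
same-type clusters stay contiguous, `T = (N+1)N(N−1)/6 − Σ_h b_h h`;
contiguity is a precondition on the caller, automatically satisfied along
any trajectory started from maximal diversity.  The star formula
`n³ − n² + n·H_n` (bd, `n` leaves) is a *conjecture*: the package flags it
as such, verifies it against the lumped solver for `n ≤ 5`, and never uses
it as ground truth elsewhere.

## Simulation

The simulator draws events with exactly the probabilities above using a
numba-compiled loop over CSR neighbour arrays, with O(1) bookkeeping of
type counts and the number of surviving types.  Replicate `r` of a run
with seed `s` uses a Philox generator seeded from `SeedSequence(s,
spawn_key=(r,))`, so results are reproducible and independent of replicate
order.  A pure-Python `step` function implements the same transition and is
what the one-step kernel audits exercise (10⁵ draws against the analytic
event probabilities, 4σ binomial bands).  Runs can be capped with
`max_steps`; capped replicates are flagged censored, never silently
truncated.  Characteristic curves record the surviving-type count at a
user-supplied increasing time grid (log-spaced by default in the CLI),
freezing a replicate's diversity at 1 after absorption.

The simulation experiments in the tests are deliberately desk-scale: 100
replicates for scaling slopes (sizes 25/50/100 for the star, 10/20/30 for
the double star), 250 replicates for characteristic curves and the
path-vs-contracting-path comparison at `N = 9`, and 250–1000 replicates for
calibration against exact values (3-standard-error bands).  These sizes
resolve the qualitative orderings and finite-size exponents tested; they do
not try to pin down asymptotic constants.

## Enumeration and graph analysis

All-connected-graph analyses need one representative per isomorphism
class.  Representatives are generated by vertex augmentation: every
connected graph on `n` vertices arises from some connected graph on `n − 1`
vertices by adding one vertex with a non-empty attachment set, so extending
each representative by every attachment subset and de-duplicating by
canonical code is exhaustive.  Canonical codes come from igraph's BLISS
canonical labelling; the test suite cross-checks them against brute-force
permutation search (`N ≤ 6`) and the class counts 1, 1, 2, 6, 21, 112, 853,
11117 for `N = 1..8` against brute-force edge-subset enumeration at
`N ≤ 5`.  Graph edit distance between equal-order graphs is the minimum
edge symmetric difference over vertex bijections, by brute force over
permutations (`N ≤ 8`); vertex insertions/deletions are out of scope.
Normalized degree entropy is the Shannon entropy of the degree-proportional
vertex distribution divided by `log N` (1 exactly on regular graphs;
minimised by the star among connected graphs at the sizes tested).

Pareto fronts are computed on (bd time, db time) with the usual weak-
dominance rule; ties on one coordinate survive unless strictly dominated.

## Graph families

Constructors are 0-based and document their layouts: star centre at vertex
0; double star centres at 0 and 1 with the extra leaf (odd `N`) on centre
0; barbell = two `n`-cliques joined by an `n`-vertex path whose endpoints
attach to exactly one clique vertex each (so path endpoints have degree 2);
contracting star = `b` blades of `m = (N−1)/b` vertices around a centre,
each blade a bidirectional path with additional one-way edges from every
blade vertex to every strictly closer vertex *of the same blade* — the
centre receives no long-range contracting edges, only the bidirectional
link to each innermost blade vertex.  A consequence worth knowing: at blade
length 2 (e.g. `N = 5`, `b = 2`) there are no pairs at distance ≥ 2 inside
a blade, so the "contracting path" degenerates to the plain path; the first
size with genuine contracting edges on two blades is `N = 7`.

## Numerical choices and limitations

- Cross-check tolerance between exact routes is 10⁻⁹ relative (double
  precision sparse solves are accurate to ~10⁻¹³ at these sizes).
- Finite-size log–log slopes carry subleading terms: the exact complete-
  graph slope on `N = 4..8` is 2.227 (not the asymptotic 2) because
  `T = N(N−1)`; slope tests therefore compare against the closed-form value
  on the same window, or use windows wide enough to admit the finite-size
  exponent.
- Stochastic tests use one fixed, package-wide seed and generous bands
  (3 SE calibration, 4σ kernel audits, α = 0.01 hypothesis tests); they are
  statistical statements, not bit-exact regressions.
- The model is strictly neutral: no fitness differences, no mutation, no
  weighted edges, no non-strongly-connected structures.  Diversity is the
  count of distinct types; frequency-aware indices (Shannon, Simpson) are
  not implemented.
- Simulated absorption times for the directed contracting families grow
  superexponentially with `N`; the CLI defaults to a 10⁹-step cap with
  explicit censoring flags rather than letting runs grind unbounded.
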