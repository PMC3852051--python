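# Methods

## Model

Two protein families A and B are given as multiple sequence alignments
whose members carry species labels s(·). The *matching graph*
G = (A ∪ B, E) has an edge (a, b) whenever s(a) = s(b); it decomposes into
one complete bipartite component per species, so every maximal matching has
the same cardinality n = Σ_t min(|A_t|, |B_t|). The search space Θ is the
set of matchings of cardinality n; sub-maximum matchings are out of scope.

For a pair of sequences within a family, Δ counts mismatched columns and ℓ
counts comparable columns (both residues non-gap; `-` and `.` are gaps,
comparison is case-insensitive and literal — ambiguity codes are not
expanded). The generative assumption is that mismatches between a pair
accrue as independent Bernoulli trials with a hidden pair rate, equal
across the two families when the pairs truly coevolve. Conditioning on
ℓ_A, ℓ_B and the total mismatch count T = Δ_A + Δ_B removes the hidden
rate: under equal rates, Δ_A follows the hypergeometric law

    f(Δ_A, Δ_B) = C(ℓ_A, Δ_A) C(ℓ_B, Δ_B) / C(ℓ_A + ℓ_B, T).

f is the value of the *unit of coevolution* ((a,b), (a′,b′)). Treating
units as independent, the log likelihood of a matching θ is the sum of
log f over its C(n, 2) unordered edge pairs; the per-pair *coevolution
degree* is the mean of the n−1 unit log scores a pair participates in.
All scores are computed in log space with log-gamma, which keeps every
value finite (the observed split always lies in the hypergeometric
support) and makes the score exactly symmetric in its two arguments.
Degenerate pairs with ℓ = 0 are legal: both Δ are then forced to 0 and the
unit scores log 1 = 0, so no special-casing is needed.

## Optimisation

Maximising the matching log likelihood is a binary quadratic program over
bipartite matchings. Two standard transformations precede the relaxation:

* **Offset shift.** Every quadruple score f is shifted by
  K = −min f + 1 (margin 1 keeps the weights safely away from zero), which
  makes all weights strictly positive, and the constant C(n, 2)·K is
  subtracted from the objective. Because every maximum-cardinality
  matching contains exactly C(n, 2) units, the shifted objective equals
  the log likelihood on all of Θ, and the strictly positive weights make
  the explicit cardinality constraint redundant. This identity is asserted
  exhaustively in the tests.
* **Quadruple orientation.** A unit is stored once, keyed (i, j, k, l)
  with i < j by family-A index and k ≠ l; any fixed total order yields the
  same likelihood.

**Lagrangian decomposition.** Each unit receives half its shifted weight
w = (f + K)/2 in each of the two *local problems* of its edges. The local
problem of edge (i, k) is a maximum-weight bipartite matching over partner
edges (j, l), j ≠ i, l ≠ k, with adjusted weight w + λ when i < j and
w − λ when j < i; only strictly positive adjusted weights participate, so
local profits v_ik(λ) ≥ 0. The master problem selects a maximum-weight
matching of the v_ik(λ) profits; cardinality n is enforced structurally by
solving one rectangular assignment per species component (profits are
non-negative and components are complete bipartite, so a full-cardinality
assignment is always among the maximum-weight ones). For any multiplier
vector λ the master value, minus the C(n, 2)·K constant, is a valid upper
bound on the optimal log likelihood: any feasible matching is available to
the master, and for its edges the local optima dominate the "pick exactly
the other matching edges" solution, whose λ contributions cancel in pairs.
The matching encoded in the master solution is feasible, so its log
likelihood is a lower bound.

One multiplier exists per oriented quadruple of distinct edges, including
cross-species units. Multipliers are tuned to shrink the bound:

* **Subgradient steps** (Held–Karp): step = μ · (best_upper −
  best_lower)/‖g‖², with g the disagreement vector between the two local
  copies of each unit restricted to master-selected edges; μ starts at 2
  and halves after 10 consecutive iterations without upper-bound
  improvement. λ starts at 0, where the bound coincides with the classical
  profit-sum bound of quadratic assignment.
* **Equalisation rounds.** Every 5th iteration takes the same step with
  μ fixed at 1 (undamped). This is this package's concrete dual-descent
  scheme: a deliberately simple disagreement-equalising move whose
  correctness rests on the bound being valid for *every* λ, which the
  property tests enforce; no claim is made that it matches any particular
  published descent scheme.
* **Primal polish.** Every extracted matching is improved by a
  deterministic local search (partner swaps between two matched A nodes of
  a species; re-pointing a matched node at an unmatched one) before it is
  scored for the lower bound.

If the subgradient vanishes, the master and local solutions are mutually
consistent and the current bound equals the selected matching's own score,
proving optimality immediately (this happens at iteration 1 on uniform
score tables). The solver stops on relative gap (upper − lower)/|lower| ≤
`gap_tol` (default 1e−6), on `max_iter` (default 500), or on `time_limit`
(default 300 s — runs not cut short by the clock are fully deterministic
for a fixed configuration; no randomness is consumed, the `seed` is
recorded for report provenance). Bound bests are monotone by construction
and the trace records (best lower, best upper) per iteration. Assignment
ties are resolved by the deterministic behaviour of the underlying
rectangular assignment solver rather than an explicit lexicographic rule;
determinism, not a particular tie order, is the contract.

Exact optimisation by enumeration (per species, all injections of the
smaller side into the larger; cross product across species, capped at 10⁶
matchings by default) backs the `method="exact"` fit and serves as the
oracle in the tests.

## Synthetic data generator

The generator realises the model's own assumptions rather than a full
phylogenetic simulation. Per family a virtual ancestral sequence is drawn;
each member mutates from it independently per column (uniform replacement
over the other 19 amino acids), so pairwise mismatch counts are Bernoulli
sums exactly as the scoring model assumes — a star phylogeny with the
virtual ancestors the model itself posits. Per species, paralog *slots*
draw substitution rates independently from `shared_rate_range`
(default 0.05–0.45, the plausible divergence range for alignable protein
families), plus m · `decoy_rate_jitter` for slot m (default 0.3), which
spreads the rates of same-species paralogs apart; the two members of a
planted pair share their slot rate exactly (the equal-rates hypothesis).
Per-family paralog counts are drawn from an inclusive range per species
(default exactly 3), surplus members acting as unmatched decoys. Gap
columns are inserted i.i.d. per sequence at `indel_rate` (default 0.03),
exercising the gap-skipping of the count routines. Sequence length
defaults to 200 columns. Everything is driven by one `numpy` generator, so
output is byte-identical per seed.

A literal per-pair draw of mismatch indicators cannot be realised as
actual sequences (pairwise mismatch patterns of three or more sequences
are not free — they must be triangle-consistent), which is why rates are
attached to sequences and pairwise Bernoulli behaviour is induced.

What passing recovery tests shows — and what it does not: the generator
produces star-tree, i.i.d.-column, equal-rate data, i.e. data for which
the scoring model is exactly correct. Success there demonstrates the
estimator and solver, not robustness to real alignments, whose shared
phylogeny, alignment errors, site-rate heterogeneity and non-independent
units violate the model to varying degrees. On ambiguous draws (two slots
with nearly equal rates) the ML optimum can legitimately differ from the
planted truth; tests therefore distinguish "solver found the certified
optimum" from "optimum equals truth".

## Evaluation conventions

Recall is 100·|predicted ∩ reference|/|reference| and precision
100·|predicted ∩ reference|/|predicted|; both are undefined (an error,
not 0) for empty reference/prediction. The average unit log likelihood
divides a matching's log likelihood by its C(n, 2) units so matchings of
different sizes are comparable. Reference matchings are read from the same
TSV dialect the mapper writes; cohort-level statistics across many
instances are left to the user.

## Numerical choices and limitations

* Scores are dense-stored per quadruple with a memo on distinct
  (Δ, ℓ, Δ′, ℓ′) count tuples; instance sizes targeted here (tens of
  sequences per family) never require an out-of-core representation.
* Optimality proofs use relative gap ≤ 1e−6; bound comparisons in tests
  allow 1e−9 absolute slack for float summation order.
* The Lagrangian dual can have a non-zero duality gap; on such instances
  the solver honestly reports lower < upper after exhausting its budget.
  The lower bound has matched the enumerated optimum on all small
  instances examined, but carries no guarantee without the matching
  upper-bound proof.
* Many-to-many mappings, sub-maximum-cardinality matchings,
  column-confidence weighting and tree-based simulation are out of scope.
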