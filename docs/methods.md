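# Methods

## Objects and definitions

The package works with three nested classes of convex bodies, all over
exact rationals:

* **s-cone** `C(S, D) = {x ∈ S : x_i ≥ 0 for i ∈ D}` — a linear subspace
  `S ⊆ Q^r` with nonnegativity constraints on a coordinate subset `D`.
  `D` is an arbitrary index set rather than a trailing block, so a flux
  cone's irreversible reactions need not be permuted to the end; the
  trailing-block form is the special case.
* **polyhedral cone** `C = {x : Ax ≥ 0}`.
* **polyhedron** `P = {x : Ax ≥ b}`, with recession cone
  `C^r = {x : Ax ≥ 0}`.

Sign vectors live in `{−, 0, +}^r` with the partial order generated by
`0 < −` and `0 < +`; `x` *conforms to* `y` iff `sign(x) ≤ sign(y)`. A
*conformal sum* is a sum whose every summand conforms to the total — no
coordinate is ever canceled.

Elementary vectors (EVs) are defined per object class:

* s-cone: the support-minimal (SM) members. For s-cones SM,
  support-wise non-decomposability, and conformal non-decomposability
  (cND) coincide, so any of the three may be taken as the definition.
* polyhedral cone: the cND members. These need *not* be support-minimal
  or extreme; they form the unique minimal *conformal* generating set.
* polyhedron: the cND members of the recession cone together with the
  convex-conformally non-decomposable (ccND) points of `P` itself.

## Exact arithmetic and determinism

Every decision in the theory is a statement about supports and sign
patterns of kernel elements, which a floating-point pivot can silently
corrupt. All arithmetic is therefore `fractions.Fraction`; file formats
accept only integers and `p/q` strings and refuse decimal notation.

Row reduction pivots deterministically (leftmost nonzero column, first
nonzero row, no magnitude heuristics), so kernel bases — and with them
every slice basis, enumeration order, and decomposition — are identical
across runs and platforms. The minimal-support search uses a fast rank
path: the subspace basis is cleared to integers once and ranks of column
subsets are computed by fraction-free Bareiss elimination over Python
ints, which is exact; it is cross-checked against the Fraction-based RREF
rank in the tests, and against sympy as an independent oracle.

## The support-minimality test

The one nontrivial soundness argument in the codebase: `x ∈ C(S, D)` is
SM **iff** the coordinate slice `{z ∈ S : supp(z) ⊆ supp(x)}` is
one-dimensional. If the slice contains a `z` independent of `x`, the
extremal step `x − λz` (λ chosen as the binding coordinate ratio) stays
sign-below `x` — hence stays in the cone, because `sign ≤ sign(x)` forces
the constrained coordinates to remain nonnegative — and loses at least one
support coordinate, so `x` is not SM. Conversely any smaller-support cone
member lies in the slice and is independent of `x`. All SM checks reduce
to one exact rank computation.

## Enumeration

**s-cones.** Supports are searched in order of increasing cardinality
with superset pruning: once any support carries a nonzero slice, all its
supersets are pruned. A pruned-lattice invariant keeps the search sound:
an unpruned support always has slice dimension ≤ 1, because a
two-dimensional slice contains an element of strictly smaller support
that would have been found earlier (this is asserted, not assumed). Each
one-dimensional slice contributes its generator `z` and/or `−z`,
whichever has nonnegative entries on the constrained coordinates — both
when the support avoids `D` entirely, neither when the constrained
entries of `z` carry mixed signs (the slice is a line, so no third
candidate exists; this case is easy to overlook). Ray classes are stored
as primitive integer vectors with gcd 1 and preserved sign.

**Polyhedral cones.** Via the graph lift `x ↦ (x, Ax)`: the lifted set
`{(x, Ax) : Ax ≥ 0}` is an s-cone in dimension `r + m` whose SM classes
correspond one-to-one to the cND classes of `C`; enumerate there and
project. The lift is taken over the full space `R^r` rather than over
`span(C)`: the lifted *set* — and therefore elementarity — is identical,
only the a-priori dimension bound of the lifted subspace weakens, and the
decomposition algorithm recovers the `dim C` bound through linear
independence of its output. (Computing `span(C)` in advance would itself
require knowing the cone's generators.)

**Polyhedra.** Via homogenization `(x, ξ, Ax − ξb)` with `ξ ≥ 0`: lifted
EV classes with `ξ = 0` dehomogenize to recession-cone ray classes, those
with `ξ > 0` are rescaled to `ξ = 1` and give ccND points. Points are
specific members of `P`, not ray classes, and are kept as exact rational
tuples. The zero vector is reported as a ccND point whenever it qualifies
(it is a vertex of `P ∩ O` for any orthant `O`, since all sign rows are
active at 0): the definition of ccND has no nonzero restriction, unlike
the cone-side predicates, and the zero point can carry weight in
decompositions of fluxes that are pure recession directions.

The subset search is exponential in the ambient dimension; a soft limit
(ambient dimension 24) raises a clear error instead of running
indefinitely. Double-description-style pivoting would extend the reach
and is deliberately out of scope — desk-scale exactness is the goal.

## Decomposition

The engine is the s-cone case, a direct implementation of the inductive
existence argument:

1. **Support reduction.** While the slice at `supp(x)` has dimension > 1,
   subtract the extremal multiple of the first slice-basis vector
   independent of the iterate. Each step strictly shrinks the support, so
   after at most `r` steps the iterate is SM and conforms to the input.
2. **Peeling.** With `e` the SM vector found, subtract `λ e` where
   `λ = min over supp(e) of x_i / e_i` (all ratios positive since `e`
   conforms to `x`); at least one coordinate is zeroed permanently.

Terms are emitted in reverse order of generation, which makes them
*triangular*: each term has a coordinate nonzero in it but zero in all
predecessors. That ordering is the corrected form of the classical
support claim (the stronger version — every term has a coordinate zero in
all *other* terms — is false) and certifies linear independence, hence
`|terms| ≤ dim S` alongside `|terms| ≤ |supp x|`.

Cones decompose through the graph lift; polyhedra through the
homogenization of the lift `(x, 1, Ax − b)`. A lifted term with `ξ_p > 0`
contributes the point `p/ξ_p` with convex weight `ξ_p`; since the lifted
target has `ξ = 1` and `ξ = 0` terms carry no ξ-mass, the weights sum to
1 exactly and at least one point term always appears. After projection
from a lift the triangular property need not survive, but linear
independence does (the lift is injective on the graph), which is what
`verify` checks there.

Conformal decompositions are not unique; the package returns one
deterministic certified decomposition and the tests assert certificate
properties, plus set-level agreement with the worked answers where the
decomposition happens to be unique (e.g. the flux `(2,1,1,1)` at sign
pattern `(+,+,+,+)` admits exactly one two-term conformal split).

## Predicates

* `is_SM` — the slice-dimension test above.
* `is_extreme` — `x ≠ 0` spans an extreme ray of `{Ax ≥ 0}` iff the rows
  active at `x` have a one-dimensional kernel.
* `is_vertex` — rows of `A` active at `x` (i.e. `A_i x = b_i`) have full
  column rank.
* `is_cND` — three interchangeable routes, kept separate so they can
  cross-check each other: SM of the lift `(x, Ax)`; extremity in
  `C ∩ O` for a closed orthant `O ∋ x` (zeros in `sign(x)` widened to `+`
  for determinism — the reduction holds for *any* closed orthant
  containing `x`, full-dimensional or not, so the choice is free); and a
  brute-force witness search.
* `is_ccND` — vertex-hood in `P ∩ O`; cross-checked in the tests against
  SM of the homogenized lift.

The witness oracle enumerates the vertices of
`D = {y : y ∈ C, x − y ∈ C, y and x − y conform to x}` by exhaustive
active-set solves. Writing the conformity conditions out shows `D` is
already a polytope — each supported coordinate of `y` is squeezed between
0 and `x_i` (sign-adjusted) and the rest are pinned to zero — so no
auxiliary normalization cut is needed. `x` is cND exactly when `D` is the
segment `{μx : 0 ≤ μ ≤ 1}`, i.e. when every vertex is 0 or `x`; any other
vertex is returned as a witness. The search is exponential in `|supp x|`
and guarded by a hard error above support size 10 — a silently truncated
oracle would be worse than none.

## Network frontend

`flux_cone` builds `C(ker N, I)` directly; `flux_polyhedron` encodes
`Nf = 0` as row pairs `(N, −N)` plus unit rows for `I` and bound rows
(`f_i ≥ lo`; `f_i ≤ up` negated), and requires at least one finite bound.
Knockouts filter EV sets by a zero coordinate; the tests confirm this
equals re-enumeration with the constraint `f_i = 0` appended. Reactions
are 1-based in files and messages, 0-based in the API.

## Synthetic instances and what the tests show

The random generators draw small integer matrices (entries in [−3, 3],
dimensions ≤ 5–6, optional density control) seeded for reproducibility —
the regime where the exhaustive oracles stay exact and fast, matching the
desk scale of the worked instances the theory is illustrated on. They
emulate the *combinatorial* structure of stoichiometry (small integer
coefficients, rank-deficient matrices with nontrivial kernels, mixed
reversibility) but not the size, sparsity patterns, or mass-balance
structure of genome-scale reconstructions; passing tests certify the
mathematics and the implementation, not performance on large models,
which the dimension guards explicitly exclude. Random cone members are
sampled as conic combinations of enumerated EVs (and convex combinations
of points for polyhedra), which by the decomposition theorems loses no
generality.

The oracle sweep runs fifty seeded cones with `r ≤ 5` (mixed sizes so the
`2^r`-orthant oracle stays fast) and demands exact set equality between
the graph-lift enumeration and the orthant-wise extreme-ray computation —
two genuinely different code paths.

## Known limitations

* Exponential enumeration: practical up to roughly 20 ambient dimensions
  (after lifting); no double-description or lrs-style pivoting.
* No SBML/COBRA import; models are plain TSV/JSON.
* No flux-balance optimization, projections/conversion cones, or facet
  enumeration.
* `is_swND` is only provided for s-cones, where it coincides with SM;
  a direct quantifier-based check for general cones is not implemented
  (the theory does not use it there).
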