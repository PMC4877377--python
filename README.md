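# confelem

Elementary vectors and conformal (cancelation-free) decompositions for
flux cones, polyhedral cones, and polyhedra — in exact rational arithmetic.

## The problem

A metabolic network with `n` internal metabolites and `r` reactions is
summarized by its stoichiometric matrix `N ∈ Q^{n×r}` and its set
`I ⊆ {1..r}` of irreversible reactions. The steady-state flux
distributions form the **flux cone**

```
C = { f ∈ R^r : N f = 0,  f_i ≥ 0 for i ∈ I },
```

and its support-minimal members are the **elementary modes** (EMs), the
smallest biochemically meaningful pathways. Every flux mode is a sum of
EMs — but an arbitrary sum may cancel: a reversible reaction cannot run in
both directions at once, so only a **conformal sum** is biochemically
meaningful, one in which every summand `e` satisfies `sign(e) ≤ sign(f)`
component-wise (zero fluxes stay zero, no sign flips).

This package computes, entirely over exact rationals:

* **Elementary vectors (EVs)** of three object classes —
  *s-cones* `C(S, D) = {x ∈ S : x_i ≥ 0, i ∈ D}` (EVs = support-minimal
  vectors; the flux cone is the instance `S = ker N`, `D = I`),
  *polyhedral cones* `{x : Ax ≥ 0}` (EVs = conformally non-decomposable
  vectors, computed through the graph lift `x ↦ (x, Ax)` to a
  higher-dimensional s-cone), and
  *polyhedra* `{x : Ax ≥ b}` (EVs = cND vectors of the recession cone plus
  convex-conformally non-decomposable points, computed through the
  homogenization `(x, ξ, Ax − ξb)`).
* **Conformal decompositions** with certified bounds: every member of an
  s-cone is a conformal sum of at most `min(dim S, |supp x|)` EVs; for a
  cone at most `dim C`; for a polyhedron at most `dim P + 1` terms with
  the point weights `λ_e ≥ 0` summing to 1. A `verify` function re-checks
  every certificate.
* **Predicate checkers** for all the special-vector notions
  (support-minimal, support-wise/conformally/convex-conformally
  non-decomposable, extreme, vertex), each by an exact algebraic test,
  plus a brute-force witness oracle.
* **Network operations**: elementary modes, flux polyhedra from bounds,
  cancelation-free flux decomposition, and knockout filtering of EV sets
  without re-enumeration.

Everything is `fractions.Fraction` end to end: supports and sign vectors —
the combinatorial core of the theory — are never perturbed by rounding.

## Worked example

The classic two-metabolite, four-reaction network (import → convert →
export, with a reversible exchange) has the stoichiometric matrix

```
N = [ 1 -1  0 -1 ]      irreversible: reactions 1-3
    [ 0  1 -1  0 ]
```

Files (`model.tsv`, `constraints.json`, `flux.tsv`):

```
	R1	R2	R3	R4
X1	1	-1	0	-1
X2	0	1	-1	0
```
```json
{"irreversible": [1, 2, 3], "bounds": {"R1": [null, 2]}}
```
```
R1	2
R2	1
R3	1
R4	1
```

Elementary modes of the flux cone (ignoring the bound):

```
$ confelem ems --model model.tsv --out ems.tsv && cat ems.tsv
kind	R1	R2	R3	R4
ray	0	1	1	-1
ray	1	0	0	1
ray	1	1	1	0
```

Three EM classes: the through-pathway `(1,0,0,1)`, the internal cycle
`(0,1,1,-1)`, and the full chain `(1,1,1,0)`. The flux `f = (2,1,1,1)`
can be written as `2·(1,0,0,1) + (0,1,1,-1)` — but that cancels reaction 4
— or as `(1,0,0,1) + (1,1,1,0)`, which is conformal. The decomposer finds
the cancelation-free sum; with the bound `f1 ≤ 2` active the feasible set
is a flux polyhedron and the answer becomes a convex combination of its
ccND points:

```
$ confelem decompose --model model.tsv --constraints constraints.json \
      --flux flux.tsv --out sum.json && cat sum.json
{
  "target": ["2", "1", "1", "1"],
  "cone_terms": [],
  "convex_terms": [
    {"point": ["2", "0", "0", "2"], "weight": "1/2"},
    {"point": ["2", "2", "2", "0"], "weight": "1/2"}
  ],
  "certificate": {"ok": true, "problems": []}
}
```

The flux polyhedron's full EV set is one recession ray class plus three
ccND points (including the zero flux); knocking out reaction 4 keeps
exactly the EVs with `f4 = 0`, with no re-enumeration:

```
$ confelem evs --model model.tsv --constraints constraints.json --out evs.tsv
kind	R1	R2	R3	R4
ray	0	1	1	-1
point	0	0	0	0
point	2	0	0	2
point	2	2	2	0

$ confelem knockout --model model.tsv --constraints constraints.json \
      --reaction R4 --out ko.tsv && cat ko.tsv
kind	R1	R2	R3	R4
point	0	0	0	0
point	2	2	2	0
```

The same operations are available as library calls (`elementary_modes`,
`evs_polyhedron`, `decompose_flux`, `knockout_filter`, …); see
`docs/methods.md` for the algorithms and their guarantees.

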