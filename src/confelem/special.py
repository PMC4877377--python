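"""Predicate checkers for the six special-vector notions.

For a convex cone member x, four properties are in play: support-minimal
(SM), support-wise non-decomposable (swND), conformally non-decomposable
(cND), and extreme (EX), with the implication chain SM => swND <= EX => cND.
For a polyhedron member the analogues are vertex (VE) and convex-conformally
non-decomposable (ccND), with VE => ccND.

The nontrivial soundness argument in this module is the algebraic SM test
for s-cones: x in C(S, D) is support-minimal iff the coordinate slice
``{z in S : supp(z) subseteq supp(x)}`` is one-dimensional. If the slice
had a second direction, a combination of x with it kills a coordinate of
supp(x) while keeping sign(.) <= sign(x) (choose the extremal step size),
producing a *cone* member with strictly smaller support — so x is not SM.
Conversely a smaller-support cone member is itself a slice element
independent of x. Hence slice dimension 1 is exactly support-minimality.

Extreme/vertex tests use the standard active-set characterizations:
x != 0 spans an extreme ray of {Ax >= 0} iff the rows active at x have a
one-dimensional kernel (the minimal face containing x is a ray), and x is a
vertex of {Ax >= b} iff the rows active at x have full column rank.

cND and ccND are decided by reduction: either lift to the related s-cone
and test SM there, or intersect with a closed orthant containing x and test
EX/VE there. A brute-force witness search over an exactly-enumerated
polytope of candidate decompositions serves as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Literal, Sequence

from .exactla import (
    RationalMatrix,
    Vector,
    dot,
    is_zero,
    kernel_basis,
    proportionality,
    rank,
    solve_unique,
    support,
    vec,
    vsub,
)
from .geometry import (
    Orthant,
    PolyCone,
    Polyhedron,
    SCone,
    conforms,
    graph_lift,
    orthant_of,
    restrict_to_orthant,
)

__all__ = [
    "Witness",
    "is_SM",
    "is_swND",
    "is_extreme",
    "is_vertex",
    "is_cND",
    "is_ccND",
    "witness_decomposition",
]


@dataclass(frozen=True)
class Witness:
    """A conformal decomposition x = x1 + x2 demonstrating decomposability.

    Both parts are nonzero cone members conforming to x, and x1 is not a
    positive multiple of x2.
    """

    x1: Vector
    x2: Vector


def _require_member(obj, x: Sequence[Fraction], *, allow_zero: bool = False) -> Vector:
    xs = vec(x)
    if not obj.contains(xs):
        raise ValueError(f"vector {tuple(map(str, xs))} is not a member")
    if not allow_zero and is_zero(xs):
        raise ValueError("the zero vector is excluded by this predicate")
    return xs


def is_SM(C: SCone, x: Sequence[Fraction]) -> bool:
    """Support-minimality of a nonzero s-cone member, decided algebraically.

    True iff no nonzero member of C has support strictly inside supp(x),
    i.e. iff the coordinate slice of S at supp(x) is one-dimensional (see
    the module docstring for the soundness argument).
    """
    xs = _require_member(C, x)
    return C.subspace.slice_dim(support(xs)) == 1


def is_swND(C: SCone, x: Sequence[Fraction]) -> bool:
    """Support-wise non-decomposability of an s-cone member.

    For s-cones, SM, swND, and cND coincide, so this delegates to the SM
    test. Only valid for s-cones; the notion is not used elsewhere.
    """
    return is_SM(C, x)


def _active_rows(A: RationalMatrix, x: Vector, b: Vector | None = None) -> list[int]:
    prod = A.matvec(x)
    if b is None:
        return [i for i, v in enumerate(prod) if v == 0]
    return [i for i, (v, bi) in enumerate(zip(prod, b)) if v == bi]


def is_extreme(C: PolyCone, x: Sequence[Fraction]) -> bool:
    """True iff nonzero x spans an extreme ray of C = {x : Ax >= 0}.

    The minimal face containing x is ker(A_Z) for the active row set Z;
    x is extreme iff that face is one-dimensional.
    """
    xs = _require_member(C, x)
    Z = _active_rows(C.A, xs)
    AZ = RationalMatrix([C.A.row(i) for i in Z], ncols=C.ambient_dim)
    return C.ambient_dim - rank(AZ) == 1


def is_vertex(P: Polyhedron, x: Sequence[Fraction]) -> bool:
    """True iff x is a vertex of P: the rows active at x have rank r."""
    xs = _require_member(P, x, allow_zero=True)
    Z = _active_rows(P.A, xs, P.b)
    AZ = RationalMatrix([P.A.row(i) for i in Z], ncols=P.ambient_dim)
    return rank(AZ) == P.ambient_dim


def is_cND(
    C: PolyCone,
    x: Sequence[Fraction],
    method: Literal["lift", "orthant", "witness"] = "lift",
) -> bool:
    """Conformal non-decomposability of a nonzero cone member.

    Three equivalent routes (they must and do agree):

    * ``lift`` — x is cND in C iff (x, Ax) is SM in the graph-lift s-cone.
    * ``orthant`` — x is cND in C iff x is extreme in C intersected with a
      closed orthant containing x.
    * ``witness`` — direct search for a conformal decomposition; cND iff
      none exists.
    """
    xs = _require_member(C, x)
    if method == "lift":
        lifted = graph_lift(C)
        return is_SM(lifted, lifted.lift(xs))
    if method == "orthant":
        CO = restrict_to_orthant(C, orthant_of(xs))
        return is_extreme(CO, xs)
    if method == "witness":
        return witness_decomposition(C, xs) is None
    raise ValueError(f"unknown method {method!r}")


def is_ccND(P: Polyhedron, x: Sequence[Fraction]) -> bool:
    """Convex-conformal non-decomposability of a polyhedron member.

    Decided as vertex-hood of x in P intersected with a closed orthant
    containing x. Unlike the cone predicates, x = 0 is allowed: the zero
    vector is a legitimate ccND point whenever 0 lies in P (it is a vertex
    of the intersection of P with any orthant, since all sign rows are
    active there).
    """
    xs = _require_member(P, x, allow_zero=True)
    PO = restrict_to_orthant(P, orthant_of(xs))
    return is_vertex(PO, xs)


def _polytope_vertices(
    rows: list[list[Fraction]], rhs: list[Fraction], k: int
) -> list[Vector]:
    """Vertices of {u in Q^k : rows . u >= rhs} by exhaustive active sets.

    Assumes the feasible set is bounded; every vertex is the unique solution
    of some k active constraints, so enumerating k-subsets is complete.
    """
    verts: list[Vector] = []
    seen: set[Vector] = set()
    M = [vec(r) for r in rows]
    for comb in combinations(range(len(M)), k):
        sub = RationalMatrix([M[i] for i in comb], ncols=k)
        sol = solve_unique(sub, [rhs[i] for i in comb])
        if sol is None:
            continue
        if sol in seen:
            continue
        if all(dot(row, sol) >= c for row, c in zip(M, rhs)):
            seen.add(sol)
            verts.append(sol)
    return verts


def witness_decomposition(
    C: PolyCone, x: Sequence[Fraction], max_support: int = 10
) -> Witness | None:
    """Brute-force search for a conformal decomposition of x in C.

    The candidate set ``D = {y : y in C, x - y in C, y and x - y conform to
    x}`` is a polytope: conformity pins y to zero off supp(x) and squeezes
    each supported coordinate between 0 and x_i (sign-adjusted). x is cND
    exactly when D is the segment {mu*x : 0 <= mu <= 1}, i.e. when every
    vertex of D is 0 or x; any other vertex yields a valid witness.

    The vertex enumeration is exponential in |supp(x)|; a hard guard raises
    above ``max_support`` rather than silently truncating.
    """
    xs = _require_member(C, x)
    T = sorted(support(xs))
    k = len(T)
    if k > max_support:
        raise ValueError(
            f"witness search limited to support size {max_support}, got {k}"
        )
    Ax = C.A.matvec(xs)
    rows: list[list[Fraction]] = []
    rhs: list[Fraction] = []
    # A y >= 0 and A(x - y) >= 0, restricted to the support coordinates
    for i in range(C.A.nrows):
        arow = [C.A.row(i)[j] for j in T]
        rows.append(arow)
        rhs.append(Fraction(0))
        rows.append([-v for v in arow])
        rhs.append(-Ax[i])
    # conformity box: 0 <= y_j <= x_j (sign-adjusted) on the support
    for pos, j in enumerate(T):
        unit = [Fraction(0)] * k
        unit[pos] = Fraction(1) if xs[j] > 0 else Fraction(-1)
        rows.append(unit)
        rhs.append(Fraction(0))
        rows.append([-v for v in unit])
        rhs.append(-abs(xs[j]))
    x_restricted = tuple(xs[j] for j in T)
    zero = tuple(Fraction(0) for _ in T)
    for u in _polytope_vertices(rows, rhs, k):
        if u == zero or u == x_restricted:
            continue
        y = [Fraction(0)] * len(xs)
        for pos, j in enumerate(T):
            y[j] = u[pos]
        y = tuple(y)
        comp = vsub(xs, y)
        # sanity: the polytope constraints certify all witness invariants
        assert C.contains(y) and C.contains(comp)
        assert conforms(y, xs) and conforms(comp, xs)
        assert proportionality(y, comp) is None or proportionality(y, comp) < 0
        return Witness(x1=y, x2=comp)
    return None
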