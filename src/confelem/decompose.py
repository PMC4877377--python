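"""Constructive conformal decomposition into elementary vectors.

Every member of an s-cone, a polyhedral cone, or a polyhedron is a
*conformal* sum of elementary vectors — a sum in which no coordinate is
ever canceled: each term's sign vector lies below the target's. This
module constructs such sums with certified bounds on the number of terms.

The engine is the s-cone case. Given x in C(S, D):

1. *Support reduction.* While the slice of S at supp(x) has dimension
   above one, subtract the extremal multiple of an independent slice vector
   (the step-size rule below); the result stays in the cone, conforms to x,
   and has strictly smaller support. Iterating yields a support-minimal
   vector conforming to x.
2. *Peeling.* Subtract the largest multiple of that elementary vector that
   keeps the remainder conforming — ``lambda = min over supp(e) of
   x_i / e_i``, all ratios positive because e conforms to x — and repeat on
   the remainder.

Each peel zeroes at least one coordinate permanently, so the loop runs at
most |supp(x)| times and the terms, read in reverse order of generation,
are triangular: each has a coordinate nonzero in it but zero in all its
predecessors. That ordering certifies linear independence, hence the bound
|terms| <= dim(S) as well.

The step-size rule (the largest lambda > 0, or when sign(-x') <= sign(x)
the smallest lambda < 0, with sign(x - lambda*x') <= sign(x)) is the
extremal ratio x_i / x'_i over coordinates where the constraint binds.

General cones decompose through the graph lift, polyhedra through
homogenization: lifted terms with xi = 0 become recession-cone terms,
terms with xi > 0 contribute the point p/xi with convex weight equal to
their xi-mass — the weights sum to 1 automatically because the lifted
target has xi = 1 and xi = 0 terms carry no xi-mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

from .exactla import (
    Vector,
    is_zero,
    proportionality,
    support,
    vec,
    vscale,
    vsub,
)
from .geometry import (
    PolyCone,
    Polyhedron,
    SCone,
    conforms,
    graph_lift,
    homogenize,
    recession_cone,
)
from . import special

__all__ = [
    "ConformalSum",
    "VerificationResult",
    "lemma2_step",
    "find_conformal_SM",
    "conformal_sum_scone",
    "conformal_sum_cone",
    "conformal_sum_polyhedron",
    "verify",
]


@dataclass(frozen=True)
class ConformalSum:
    """An ordered conformal decomposition of a target vector.

    ``cone_terms`` are positive multiples of elementary ray classes (for a
    polyhedron: of its recession cone), ordered so that every term has a
    coordinate nonzero in it but zero in all predecessors. ``convex_terms``
    are (ccND point, weight) pairs with weights summing to one; they are
    empty unless the target lives in a polyhedron.
    """

    target: Vector
    cone_terms: tuple[Vector, ...]
    convex_terms: tuple[tuple[Vector, Fraction], ...] = field(default_factory=tuple)

    def reconstruct(self) -> Vector:
        total = tuple(Fraction(0) for _ in self.target)
        for t in self.cone_terms:
            total = tuple(a + b for a, b in zip(total, t))
        for p, w in self.convex_terms:
            total = tuple(a + w * b for a, b in zip(total, p))
        return total

    @property
    def n_terms(self) -> int:
        return len(self.cone_terms) + len(self.convex_terms)

    @property
    def weight_total(self) -> Fraction:
        return sum((w for _, w in self.convex_terms), Fraction(0))


def _extremal_lambda(x: Vector, xp: Vector) -> Fraction:
    """The extremal step size of the support-reduction argument.

    Requires supp(xp) subseteq supp(x), xp nonzero. Feasible step sizes
    (those keeping sign(x - lambda*xp) <= sign(x)) form an interval whose
    endpoints are coordinate ratios; the largest positive ratio bound is
    returned when one exists, otherwise the least-negative bound. Either
    way the binding coordinate vanishes, so the support strictly shrinks.
    """
    ratios = [x[i] / xp[i] for i in support(xp)]
    positive = [r for r in ratios if r > 0]
    if positive:
        return min(positive)
    return max(ratios)


def lemma2_step(
    C: SCone, x: Sequence[Fraction], xp: Sequence[Fraction]
) -> tuple[Fraction, Vector]:
    """One support-reduction step between two s-cone members.

    Given nonzero, non-proportional x, xp in C with supp(xp) subseteq
    supp(x), returns ``(lambda, x2 = x - lambda*xp)`` with x2 nonzero, in
    C, conforming to x, and of strictly smaller support. lambda is positive
    whenever xp conforms to x.
    """
    xs, xps = vec(x), vec(xp)
    for v, name in ((xs, "x"), (xps, "xp")):
        if not C.contains(v):
            raise ValueError(f"{name} is not a member of the s-cone")
        if is_zero(v):
            raise ValueError(f"{name} must be nonzero")
    if proportionality(xs, xps) is not None:
        raise ValueError("x and xp must not be proportional")
    if not support(xps) <= support(xs):
        raise ValueError("supp(xp) must be contained in supp(x)")
    lam = _extremal_lambda(xs, xps)
    x2 = vsub(xs, vscale(lam, xps))
    assert not is_zero(x2) and conforms(x2, xs)
    assert support(x2) < support(xs)
    return lam, x2


def find_conformal_SM(C: SCone, x: Sequence[Fraction]) -> Vector:
    """A support-minimal cone member conforming to x, by support reduction.

    Deterministic: the slice vector subtracted at each step is the first
    vector of the RREF-derived slice basis that is independent of the
    current iterate, so identical inputs give identical outputs.
    """
    cur = vec(x)
    if not C.contains(cur):
        raise ValueError("x is not a member of the s-cone")
    if is_zero(cur):
        raise ValueError("x must be nonzero")
    while True:
        sb = C.subspace.slice_basis(support(cur))
        if len(sb) == 1:
            return cur  # support-minimal: the slice is the line through cur
        z = next(v for v in sb if proportionality(v, cur) is None)
        lam = _extremal_lambda(cur, z)
        cur = vsub(cur, vscale(lam, z))


def conformal_sum_scone(C: SCone, x: Sequence[Fraction]) -> ConformalSum:
    """Decompose an s-cone member into a conformal sum of elementary vectors.

    The zero vector yields the empty sum. Terms are returned in the
    triangular order of the theory: every term has a coordinate nonzero in
    it but zero in all predecessors, which certifies linear independence
    and the bounds |terms| <= dim(S) and |terms| <= |supp(x)|.
    """
    xs = vec(x)
    if not C.contains(xs):
        raise ValueError("x is not a member of the s-cone")
    terms: list[Vector] = []
    cur = xs
    while not is_zero(cur):
        e = find_conformal_SM(C, cur)
        lam = min(cur[i] / e[i] for i in support(e))
        term = vscale(lam, e)
        terms.append(term)
        cur = vsub(cur, term)
        assert conforms(cur, xs)
    return ConformalSum(target=xs, cone_terms=tuple(reversed(terms)))


def conformal_sum_cone(C: PolyCone, x: Sequence[Fraction]) -> ConformalSum:
    """Decompose a polyhedral-cone member into a conformal sum of EVs.

    Works in the graph-lift s-cone and projects the terms back; exactness
    and conformity transfer, and the terms inherit linear independence from
    the lifted triangular order, giving |terms| <= dim(C) and
    |terms| <= |supp(x)| + |supp(Ax)|.
    """
    xs = vec(x)
    if not C.contains(xs):
        raise ValueError("x is not a member of the cone")
    lifted = graph_lift(C)
    inner = conformal_sum_scone(lifted, lifted.lift(xs))
    return ConformalSum(
        target=xs,
        cone_terms=tuple(lifted.project(t) for t in inner.cone_terms),
    )


def conformal_sum_polyhedron(P: Polyhedron, x: Sequence[Fraction]) -> ConformalSum:
    """Decompose a polyhedron member into recession EVs plus a conformal
    convex combination of ccND points.

    Works in the homogenization s-cone on the lift (x, 1, Ax - b). Lifted
    terms with xi = 0 dehomogenize to recession-cone terms; terms with
    xi > 0 contribute (point, weight) with weight equal to their xi-mass,
    so the weights sum to one exactly and at least one point appears.
    Bounds: |terms| <= dim(P) + 1 and <= |supp(x)| + |supp(Ax)| + 1.
    """
    xs = vec(x)
    if not P.contains(xs):
        raise ValueError("x is not a member of the polyhedron")
    H = homogenize(P)
    inner = conformal_sum_scone(H, H.lift_point(xs))
    cone_terms: list[Vector] = []
    convex_terms: list[tuple[Vector, Fraction]] = []
    for t in inner.cone_terms:
        xi = t[H.xi_index]
        kind, value = H.dehomogenize(t)
        if kind == "ray":
            cone_terms.append(value)
        else:
            convex_terms.append((value, xi))
    result = ConformalSum(
        target=xs, cone_terms=tuple(cone_terms), convex_terms=tuple(convex_terms)
    )
    assert result.weight_total == 1 and len(convex_terms) >= 1
    return result


@dataclass
class VerificationResult:
    """Outcome of a certificate check; falsy when any invariant fails."""

    ok: bool
    problems: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def verify(
    csum: ConformalSum, against: SCone | PolyCone | Polyhedron
) -> VerificationResult:
    """Re-check every invariant of a conformal sum against its object.

    Checks exact reconstruction, conformity of every term, membership of
    cone terms (in the object, or in the recession cone for a polyhedron),
    membership of convex points in the polyhedron, nonnegative weights
    summing to one, the triangular ordering of the cone terms, and
    elementarity of every term via the predicate checkers. Collects
    diagnostics instead of raising.
    """
    problems: list[str] = []
    x = csum.target

    if csum.reconstruct() != x:
        problems.append("reconstruction does not equal the target")

    if csum.convex_terms and not isinstance(against, Polyhedron):
        problems.append("convex terms present for a non-polyhedral object")

    for k, t in enumerate(csum.cone_terms):
        if is_zero(t):
            problems.append(f"cone term {k} is zero")
            continue
        if not conforms(t, x):
            problems.append(f"cone term {k} does not conform to the target")
        obj = recession_cone(against) if isinstance(against, Polyhedron) else against
        if not obj.contains(t):
            problems.append(f"cone term {k} is not a member")
            continue
        try:
            if isinstance(obj, SCone):
                elementary = special.is_SM(obj, t)
            else:
                elementary = special.is_cND(obj, t)
        except ValueError as exc:
            problems.append(f"cone term {k}: {exc}")
            continue
        if not elementary:
            problems.append(f"cone term {k} is not elementary")

    # the triangular certificate (each term owns a coordinate zero in all
    # predecessors) is stated in s-cone coordinates; after projection from a
    # lift only linear independence survives, so that is what is checked
    if isinstance(against, SCone):
        for k, t in enumerate(csum.cone_terms):
            preceding = csum.cone_terms[:k]
            if not any(
                t[i] != 0 and all(p[i] == 0 for p in preceding)
                for i in range(len(t))
            ):
                problems.append(f"cone term {k} violates the triangular ordering")
    elif csum.cone_terms:
        from .exactla import RationalMatrix, rank as _rank

        stacked = RationalMatrix(
            [list(t) for t in csum.cone_terms], ncols=len(x)
        )
        if _rank(stacked) != len(csum.cone_terms):
            problems.append("cone terms are linearly dependent")

    if csum.convex_terms:
        if csum.weight_total != 1:
            problems.append("convex weights do not sum to one")
        for k, (p, w) in enumerate(csum.convex_terms):
            if w < 0:
                problems.append(f"convex term {k} has negative weight")
            if not conforms(p, x):
                problems.append(f"convex point {k} does not conform to the target")
            if not isinstance(against, Polyhedron):
                continue
            if not against.contains(p):
                problems.append(f"convex point {k} is not a member of the polyhedron")
            elif not special.is_ccND(against, p):
                problems.append(f"convex point {k} is not ccND")
    elif isinstance(against, Polyhedron) and not is_zero(x):
        problems.append("polyhedral decomposition requires at least one convex term")
    elif isinstance(against, Polyhedron) and not csum.cone_terms and not is_zero(x):
        problems.append("empty decomposition of a nonzero target")

    if not csum.cone_terms and not csum.convex_terms and not is_zero(x):
        problems.append("empty decomposition of a nonzero target")

    return VerificationResult(ok=not problems, problems=problems)
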