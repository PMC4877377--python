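"""Sign vectors, orthants, and the geometric objects of the theory.

Three objects carry the whole development:

* :class:`SCone` — a *subspace cone* ``C(S, D) = {x in S : x_i >= 0 for i
  in D}``: a linear subspace with nonnegativity constraints on a coordinate
  subset. The flux cone of a metabolic network is the motivating instance,
  with ``S = ker(N)`` and ``D`` the irreversible reactions.
* :class:`PolyCone` — a general polyhedral cone ``{x : Ax >= 0}``.
* :class:`Polyhedron` — ``{x : Ax >= b}``.

General cones and polyhedra are analyzed through higher-dimensional s-cones:
:func:`graph_lift` maps a cone to the s-cone over its constraint graph
``{(x, Ax)}``, and :func:`homogenize` maps a polyhedron to the s-cone over
``{(x, xi, Ax - xi*b) : xi >= 0}``. Membership, elementarity, and conformal
decompositions transfer exactly along these lifts.

Sign vectors live in {-, 0, +}^n (encoded -1/0/+1) with the partial order
generated by 0 < - and 0 < +; ``x`` *conforms to* ``y`` when
``sign(x) <= sign(y)``, i.e. x introduces no sign flips and no new support.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

from .exactla import (
    RationalMatrix,
    Subspace,
    Vector,
    dot,
    vec,
)

__all__ = [
    "SignVector",
    "sign_of",
    "sign_leq",
    "conforms",
    "format_sign_vector",
    "Orthant",
    "orthant_of",
    "SCone",
    "PolyCone",
    "Polyhedron",
    "LiftedSCone",
    "HomogenizedSCone",
    "graph_lift",
    "homogenize",
    "recession_cone",
    "contains",
    "restrict_to_orthant",
    "scone_to_polycone",
]

#: Component-wise sign pattern; entries are -1, 0, +1.
SignVector = tuple[int, ...]

_SIGN_CHARS = {-1: "-", 0: "0", 1: "+"}


def sign_of(x: Sequence[Fraction]) -> SignVector:
    """Component-wise sign vector of ``x``."""
    return tuple((v > 0) - (v < 0) for v in vec(x))


def sign_leq(X: SignVector, Y: SignVector) -> bool:
    """Partial order on sign vectors: X <= Y iff X_i is 0 or equals Y_i."""
    if len(X) != len(Y):
        raise ValueError("sign vector length mismatch")
    return all(a == 0 or a == b for a, b in zip(X, Y))


def conforms(x: Sequence[Fraction], y: Sequence[Fraction]) -> bool:
    """True iff ``x`` conforms to ``y``: sign(x) <= sign(y)."""
    return sign_leq(sign_of(x), sign_of(y))


def format_sign_vector(X: SignVector) -> str:
    return "(" + "".join(_SIGN_CHARS[s] for s in X) + ")"


@dataclass(frozen=True)
class Orthant:
    """Closed orthant {x : sign(x) <= pattern}."""

    pattern: SignVector

    def __post_init__(self):
        if any(s not in (-1, 0, 1) for s in self.pattern):
            raise ValueError("orthant pattern entries must be -1, 0, or +1")

    @property
    def ambient_dim(self) -> int:
        return len(self.pattern)

    def contains(self, x: Sequence[Fraction]) -> bool:
        return sign_leq(sign_of(x), self.pattern)


def orthant_of(x: Sequence[Fraction], fill: int = 1) -> Orthant:
    """A deterministic closed orthant containing ``x``.

    Zero components of ``x`` are widened to ``fill`` (default +) so the
    orthant is full-dimensional; any closed orthant containing x works for
    the elementarity reductions, so the choice is free and fixed here for
    reproducibility.
    """
    if fill not in (-1, 1):
        raise ValueError("fill must be -1 or +1")
    return Orthant(tuple(s if s != 0 else fill for s in sign_of(x)))


@dataclass(frozen=True, eq=False)
class SCone:
    """Subspace cone C(S, D) = {x in S : x_i >= 0 for all i in D}.

    ``D`` is an arbitrary coordinate subset (0-based): flux cones constrain
    an arbitrary irreversible reaction set without permuting coordinates,
    and the 'last d coordinates' form is the special case D = {r-d..r-1}.
    """

    ambient_dim: int
    subspace: Subspace
    nonneg: frozenset[int]

    def __post_init__(self):
        object.__setattr__(self, "nonneg", frozenset(self.nonneg))
        if self.subspace.ambient_dim != self.ambient_dim:
            raise ValueError("subspace ambient dimension mismatch")
        for i in self.nonneg:
            if not 0 <= i < self.ambient_dim:
                raise IndexError(f"nonneg index {i} out of range")

    def contains(self, x: Sequence[Fraction]) -> bool:
        xs = vec(x)
        if len(xs) != self.ambient_dim:
            raise ValueError("dimension mismatch")
        return self.subspace.contains(xs) and all(xs[i] >= 0 for i in self.nonneg)


@dataclass(frozen=True, eq=False)
class PolyCone:
    """Polyhedral cone C = {x : Ax >= 0}."""

    A: RationalMatrix

    @property
    def ambient_dim(self) -> int:
        return self.A.ncols

    def contains(self, x: Sequence[Fraction]) -> bool:
        xs = vec(x)
        return all(v >= 0 for v in self.A.matvec(xs))


@dataclass(frozen=True, eq=False)
class Polyhedron:
    """Polyhedron P = {x : Ax >= b}."""

    A: RationalMatrix
    b: Vector

    def __post_init__(self):
        object.__setattr__(self, "b", vec(self.b))
        if len(self.b) != self.A.nrows:
            raise ValueError("right-hand side length must equal number of rows")

    @property
    def ambient_dim(self) -> int:
        return self.A.ncols

    def contains(self, x: Sequence[Fraction]) -> bool:
        xs = vec(x)
        return all(v >= bi for v, bi in zip(self.A.matvec(xs), self.b))


@dataclass(frozen=True, eq=False)
class LiftedSCone(SCone):
    """The s-cone over the constraint graph of a polyhedral cone.

    Coordinates are ``(x, y)`` with ``y = Ax`` enforced by the subspace and
    ``y >= 0`` by the nonnegativity set; membership of ``x`` in the source
    cone is equivalent to membership of ``lift(x)`` here.
    """

    source: PolyCone = None  # set by graph_lift

    def lift(self, x: Sequence[Fraction]) -> Vector:
        xs = vec(x)
        return xs + self.source.A.matvec(xs)

    def project(self, z: Sequence[Fraction]) -> Vector:
        return vec(z)[: self.source.ambient_dim]


@dataclass(frozen=True, eq=False)
class HomogenizedSCone(SCone):
    """The s-cone over the homogenization of a polyhedron.

    Coordinates are ``(x, xi, s)`` with ``s = Ax - xi*b`` enforced by the
    subspace and ``xi >= 0``, ``s >= 0`` by the nonnegativity set. Members
    with xi > 0 dehomogenize to points ``x/xi`` of P; members with xi = 0
    dehomogenize to recession-cone directions.
    """

    source: Polyhedron = None  # set by homogenize
    xi_index: int = -1

    def lift_point(self, x: Sequence[Fraction]) -> Vector:
        """Lift a point of P: (x, 1, Ax - b)."""
        xs = vec(x)
        slack = tuple(v - bi for v, bi in zip(self.source.A.matvec(xs), self.source.b))
        return xs + (Fraction(1),) + slack

    def lift_direction(self, d: Sequence[Fraction]) -> Vector:
        """Lift a recession direction: (d, 0, Ad)."""
        ds = vec(d)
        return ds + (Fraction(0),) + self.source.A.matvec(ds)

    def dehomogenize(
        self, z: Sequence[Fraction]
    ) -> tuple[Literal["ray", "point"], Vector]:
        """Classify a lifted vector: xi = 0 gives a recession direction,
        xi > 0 gives the point x/xi of P."""
        zs = vec(z)
        xi = zs[self.xi_index]
        r = self.source.ambient_dim
        if xi < 0:
            raise ValueError("lifted vector has negative homogenization coordinate")
        if xi == 0:
            return ("ray", zs[:r])
        return ("point", tuple(v / xi for v in zs[:r]))


def graph_lift(C: PolyCone) -> LiftedSCone:
    """Lift a polyhedral cone to the s-cone over its constraint graph.

    The subspace is the graph ``{(x, Ax) : x in R^r}`` (kernel of
    ``[A | -I]``) and the last ``m`` coordinates are constrained
    nonnegative. The lift is taken over the full space rather than over
    span(C): the lifted *set* is identical, so elementarity is unchanged;
    only the a-priori dimension bound weakens, and the decomposition
    algorithm recovers the dim(C) bound through linear independence of its
    output terms.
    """
    r, m = C.ambient_dim, C.A.nrows
    rows = []
    for i in range(m):
        row = list(C.A.row(i)) + [Fraction(0)] * m
        row[r + i] = Fraction(-1)
        rows.append(row)
    subspace = Subspace.from_constraints(RationalMatrix(rows, ncols=r + m))
    return LiftedSCone(
        ambient_dim=r + m,
        subspace=subspace,
        nonneg=frozenset(range(r, r + m)),
        source=C,
    )


def homogenize(P: Polyhedron) -> HomogenizedSCone:
    """Lift a polyhedron to the s-cone over its homogenization.

    Coordinates ``(x, xi, s)`` in dimension r+1+m with subspace
    ``s = Ax - xi*b`` (kernel of ``[A | -b | -I]``) and nonnegativity on xi
    and the m slack coordinates.
    """
    r, m = P.ambient_dim, P.A.nrows
    rows = []
    for i in range(m):
        row = list(P.A.row(i)) + [-P.b[i]] + [Fraction(0)] * m
        row[r + 1 + i] = Fraction(-1)
        rows.append(row)
    subspace = Subspace.from_constraints(RationalMatrix(rows, ncols=r + 1 + m))
    return HomogenizedSCone(
        ambient_dim=r + 1 + m,
        subspace=subspace,
        nonneg=frozenset({r}) | frozenset(range(r + 1, r + 1 + m)),
        source=P,
        xi_index=r,
    )


def recession_cone(P: Polyhedron) -> PolyCone:
    """Recession cone {x : Ax >= 0}: same constraint matrix, b dropped."""
    return PolyCone(P.A)


def scone_to_polycone(C: SCone) -> PolyCone:
    """Encode an s-cone as an inequality system {x : Ax >= 0}.

    The subspace membership Mx = 0 becomes the row pairs (M, -M) and each
    nonnegativity constraint a unit row. The encoding has the same members,
    and support-minimality in the s-cone coincides with conformal
    non-decomposability in the encoding.
    """
    M = C.subspace.constraints
    rows = [list(r) for r in M.entries]
    rows += [[-v for v in r] for r in M.entries]
    for i in sorted(C.nonneg):
        unit = [Fraction(0)] * C.ambient_dim
        unit[i] = Fraction(1)
        rows.append(unit)
    return PolyCone(RationalMatrix(rows, ncols=C.ambient_dim))


def contains(obj: SCone | PolyCone | Polyhedron, x: Sequence[Fraction]) -> bool:
    """Exact membership test, dispatching on the object kind."""
    return obj.contains(x)


def _sign_rows(pattern: SignVector, r: int) -> list[list[Fraction]]:
    rows = []
    for i, p in enumerate(pattern):
        if p >= 0:
            row = [Fraction(0)] * r
            row[i] = Fraction(1)
            rows.append(row)
        if p <= 0:
            row = [Fraction(0)] * r
            row[i] = Fraction(-1)
            rows.append(row)
    return rows


def restrict_to_orthant(obj, orthant: Orthant):
    """Intersect a PolyCone or Polyhedron with a closed orthant.

    The intersection is expressed by appending signed unit rows (both signs
    for coordinates pinned to zero by the pattern); for a polyhedron the
    appended rows carry right-hand side 0.
    """
    r = obj.ambient_dim
    if orthant.ambient_dim != r:
        raise ValueError("orthant dimension mismatch")
    extra = _sign_rows(orthant.pattern, r)
    A = RationalMatrix(list(obj.A.entries) + extra, ncols=r)
    if isinstance(obj, Polyhedron):
        return Polyhedron(A, obj.b + tuple(Fraction(0) for _ in extra))
    if isinstance(obj, PolyCone):
        return PolyCone(A)
    raise TypeError(f"cannot restrict {type(obj).__name__} to an orthant")
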