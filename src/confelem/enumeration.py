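"""Exhaustive enumeration of elementary vectors.

For an s-cone the elementary vectors are the support-minimal members, and
they are found by a minimal-support search over the subset lattice: a
support T can carry an elementary vector only if the coordinate slice of
the subspace at T is one-dimensional and no strictly smaller support
already carries a nonzero slice. The search walks supports in order of
increasing cardinality with superset pruning, so every slice it actually
ranks is at most one-dimensional (a two-dimensional slice always contains
an element with strictly smaller support, which would have pruned it).

Each one-dimensional slice contributes its generator z and/or -z: whichever
of the two has nonnegative entries on the sign-constrained coordinates is a
cone member (both, when the support avoids the constrained set entirely;
neither, when the constrained entries of z carry both signs — the slice is
a line, so no third option exists).

General polyhedral cones are enumerated through the graph lift and
projection; polyhedra through homogenization, with lifted classes split by
the homogenization coordinate into recession-cone ray classes (xi = 0) and
ccND points (xi > 0, rescaled to xi = 1). Ray classes are stored as
canonical primitive-integer representatives; ccND points are specific
points of P, not ray classes, and are kept as exact rational tuples.

The subset search is exponential in the ambient dimension; a soft limit
raises a clear error beyond dimension 24. Desk-scale correctness is the
goal here — double-description-style pivoting is a known optimization and
deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Sequence

from .exactla import Vector, canonical_ray, is_zero, vec, vneg
from .geometry import PolyCone, Polyhedron, SCone, graph_lift, homogenize

__all__ = [
    "EVSet",
    "EnumerationLimitError",
    "evs_scone",
    "evs_cone",
    "evs_polyhedron",
    "is_conformal_generating_set",
]

_SOFT_DIMENSION_LIMIT = 24


class EnumerationLimitError(RuntimeError):
    """Raised when an instance exceeds the supported search dimension."""


@dataclass(frozen=True)
class EVSet:
    """A finite set of canonical elementary-vector representatives.

    ``rays`` holds one primitive integer vector per ray class (cND classes
    up to positive scaling); ``points`` holds exact rational ccND points
    and is empty unless the source object is a polyhedron.
    """

    ambient_dim: int
    rays: frozenset[tuple[int, ...]]
    points: frozenset[Vector] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.rays) + len(self.points)

    @property
    def has_zero_point(self) -> bool:
        return any(is_zero(p) for p in self.points)

    def sorted_rays(self) -> list[tuple[int, ...]]:
        return sorted(self.rays)

    def sorted_points(self) -> list[Vector]:
        return sorted(self.points)


def evs_scone(C: SCone) -> EVSet:
    """All elementary (support-minimal) vector classes of an s-cone."""
    n = C.ambient_dim
    if n > _SOFT_DIMENSION_LIMIT:
        raise EnumerationLimitError(
            f"ambient dimension {n} exceeds the supported limit "
            f"{_SOFT_DIMENSION_LIMIT} for exhaustive support search"
        )
    S = C.subspace
    rays: set[tuple[int, ...]] = set()
    if S.dim == 0:
        return EVSet(n, frozenset())
    minimal_masks: list[int] = []
    for size in range(1, n + 1):
        for T in combinations(range(n), size):
            mask = 0
            for i in T:
                mask |= 1 << i
            if any(f & mask == f for f in minimal_masks):
                continue
            d = S.slice_dim(T)
            if d == 0:
                continue
            # an unpruned slice cannot have dimension >= 2: it would contain
            # an element of strictly smaller support, found at an earlier size
            assert d == 1, "superset pruning invariant violated"
            minimal_masks.append(mask)
            (z,) = S.slice_basis(T)
            constrained = C.nonneg.intersection(T)
            if all(z[i] > 0 for i in constrained):
                rays.add(canonical_ray(z))
                if not constrained:
                    rays.add(canonical_ray(vneg(z)))
            elif all(z[i] < 0 for i in constrained):
                rays.add(canonical_ray(vneg(z)))
            # mixed signs on the constrained coordinates: the slice is a
            # line, so neither +z nor -z lies in the cone; no class emitted
    return EVSet(n, frozenset(rays))


def evs_cone(C: PolyCone) -> EVSet:
    """All elementary (cND) ray classes of a polyhedral cone, via the lift."""
    lifted = graph_lift(C)
    r = C.ambient_dim
    rays = {canonical_ray(z[:r]) for z in _ray_members(evs_scone(lifted))}
    return EVSet(r, frozenset(rays))


def evs_polyhedron(P: Polyhedron) -> EVSet:
    """All elementary vectors of a polyhedron, via homogenization.

    Lifted classes with xi = 0 dehomogenize to recession-cone ray classes;
    those with xi > 0 are rescaled to xi = 1 and dehomogenize to ccND
    points (including the zero vector whenever it is one).
    """
    H = homogenize(P)
    rays: set[tuple[int, ...]] = set()
    points: set[Vector] = set()
    for z in _ray_members(evs_scone(H)):
        kind, value = H.dehomogenize(z)
        if kind == "ray":
            rays.add(canonical_ray(value))
        else:
            points.add(value)
    return EVSet(P.ambient_dim, frozenset(rays), frozenset(points))


def _ray_members(evs: EVSet) -> Iterable[Vector]:
    for ray in evs.rays:
        yield vec(ray)


def is_conformal_generating_set(
    C: PolyCone, G: Iterable[Sequence[Fraction]]
) -> bool:
    """True iff G is a conformal generating set of C.

    Sufficiency and necessity reduce the check to class containment: G
    generates conformally iff every elementary ray class of C has a
    representative in G (up to positive scaling). Zero vectors in G are
    ignored (they generate nothing); members outside C are an error.
    """
    classes: set[tuple[int, ...]] = set()
    for g in G:
        gs = vec(g)
        if not C.contains(gs):
            raise ValueError("generating-set candidate contains a vector outside C")
        if not is_zero(gs):
            classes.add(canonical_ray(gs))
    return evs_cone(C).rays <= classes
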