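"""Worked-example registry, random instance generators, and oracles.

The theory is exactly reproducible at desk scale, so the test surface is
built from (a) the small worked examples with hand-verified expected
elementary-vector sets and (b) seeded random instances checked against
brute-force oracles that take a code path independent of the production
enumeration: the production route goes subspace-slice search through the
graph lift, while :func:`bruteforce_evs` intersects the cone with every
closed orthant and tests extremity of active-set kernels directly.

All randomness is seeded and the seed appears in generated names so that a
failing instance is reproducible from its repr alone.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations, product
from typing import Mapping, Sequence

from .enumeration import EVSet
from .exactla import (
    RationalMatrix,
    Subspace,
    Vector,
    canonical_ray,
    dot,
    is_zero,
    kernel_basis,
    rank,
    solve_unique,
    vec,
    vneg,
)
from .geometry import PolyCone, Polyhedron, SCone, conforms
from .metnet import MetabolicNetwork

__all__ = [
    "WorkedExample",
    "worked_examples",
    "random_network",
    "random_scone",
    "random_polycone",
    "random_polyhedron",
    "conic_member",
    "polyhedron_member",
    "bruteforce_evs",
    "all_two_term_decompositions",
]


@dataclass(frozen=True)
class WorkedExample:
    """A small instance with hand-verified expected results."""

    name: str
    obj: object  # SCone | PolyCone | Polyhedron | MetabolicNetwork
    expected: EVSet
    decompositions: Mapping[Vector, frozenset] = field(default_factory=dict)


def _evset(dim, rays=(), points=()):
    return EVSet(
        ambient_dim=dim,
        rays=frozenset(tuple(r) for r in rays),
        points=frozenset(vec(p) for p in points),
    )


def running_example_network(
    bound_f1: Fraction | None = None, knockout_f4: bool = False
) -> MetabolicNetwork:
    """The two-metabolite, four-reaction network used throughout.

    Reaction 1 imports X1, reaction 2 converts X1 to X2, reaction 3 exports
    X2, reaction 4 reversibly exchanges X1; reactions 1-3 are irreversible.
    Optionally adds the bound f1 <= 2 and/or the knockout f4 = 0.
    """
    bounds: dict[int, tuple[Fraction | None, Fraction | None]] = {}
    if bound_f1 is not None:
        bounds[0] = (None, Fraction(bound_f1))
    if knockout_f4:
        bounds[3] = (Fraction(0), Fraction(0))
    return MetabolicNetwork(
        metabolites=("X1", "X2"),
        reactions=("R1", "R2", "R3", "R4"),
        N=RationalMatrix([[1, -1, 0, -1], [0, 1, -1, 0]]),
        irreversible=frozenset({0, 1, 2}),
        bounds=bounds,
    )


def worked_examples() -> tuple[WorkedExample, ...]:
    """The six instances every test layer shares.

    Expected values: the flux-cone EMs, the flux-polyhedron EVs, and the
    Example 1 rays are stated results of the theory's source examples; the
    Example 2/3 ray and vertex coordinates were derived by hand (facet
    kernels and active-set vertex solves) and double-checked against the
    stated counts.
    """
    from .metnet import flux_cone, flux_polyhedron  # local to avoid cycle

    net = running_example_network()
    flux_cone_ex = WorkedExample(
        name="running-example flux cone",
        obj=flux_cone(net),
        expected=_evset(4, rays=[(1, 0, 0, 1), (0, 1, 1, -1), (1, 1, 1, 0)]),
        decompositions={
            vec((2, 1, 1, 1)): frozenset({(1, 0, 0, 1), (1, 1, 1, 0)}),
        },
    )
    quadrant = WorkedExample(
        name="Example 1: nonnegative quadrant as s-cone",
        obj=SCone(
            ambient_dim=2,
            subspace=Subspace.from_basis([[1, 0], [0, 1]], ambient_dim=2),
            nonneg=frozenset({0, 1}),
        ),
        expected=_evset(2, rays=[(1, 0), (0, 1)]),
        decompositions={vec((1, 1)): frozenset({(1, 0), (0, 1)})},
    )
    cone2 = WorkedExample(
        name="Example 2: planar cone [[3,1],[-1,1]]",
        obj=PolyCone(RationalMatrix([[3, 1], [-1, 1]])),
        expected=_evset(2, rays=[(-1, 3), (0, 1), (1, 1)]),
        decompositions={
            vec((1, 2)): frozenset({(0, 1), (1, 1)}),
            vec((-1, 4)): frozenset({(-1, 3), (0, 1)}),
        },
    )
    poly3 = WorkedExample(
        name="Example 3: planar polyhedron",
        obj=Polyhedron(RationalMatrix([[3, 1], [-3, 3], [0, 2]]), vec((1, -1, 1))),
        expected=_evset(
            2,
            rays=[(-1, 3), (0, 1), (1, 1)],
            points=[(0, 1), ("1/6", "1/2"), ("5/6", "1/2")],
        ),
    )
    flux_poly = WorkedExample(
        name="flux polyhedron with f1 <= 2",
        obj=flux_polyhedron(running_example_network(bound_f1=2)),
        expected=_evset(
            4,
            rays=[(0, 1, 1, -1)],
            points=[(2, 0, 0, 2), (2, 2, 2, 0), (0, 0, 0, 0)],
        ),
    )
    knockout = WorkedExample(
        name="flux polyhedron with f1 <= 2 and reaction 4 knocked out",
        obj=flux_polyhedron(running_example_network(bound_f1=2, knockout_f4=True)),
        expected=_evset(4, points=[(2, 2, 2, 0), (0, 0, 0, 0)]),
    )
    return (flux_cone_ex, quadrant, cone2, poly3, flux_poly, knockout)


def random_network(
    n: int,
    r: int,
    seed: int,
    density: float = 1.0,
    frac_irreversible: float = 0.75,
) -> MetabolicNetwork:
    """A random integer stoichiometric matrix with a nontrivial kernel.

    Entries are integers in [-3, 3] (zeroed with probability 1 - density);
    the matrix is resampled until its rank is below r, so the flux cone is
    never just the origin. Reproducible from the seed.
    """
    if n < 1 or r < 2:
        raise ValueError("need n >= 1 and r >= 2")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if not 0 <= frac_irreversible <= 1:
        raise ValueError("frac_irreversible must be in [0, 1]")
    rng = random.Random(seed)
    for _ in range(1000):
        rows = [
            [
                rng.randint(-3, 3) if rng.random() < density else 0
                for _ in range(r)
            ]
            for _ in range(n)
        ]
        N = RationalMatrix(rows, ncols=r)
        if rank(N) < r:
            break
    else:  # pragma: no cover - practically unreachable for r >= 2
        raise RuntimeError("could not sample a rank-deficient matrix")
    n_irr = round(frac_irreversible * r)
    irreversible = frozenset(rng.sample(range(r), n_irr))
    return MetabolicNetwork(
        metabolites=tuple(f"X{j + 1}" for j in range(n)),
        reactions=tuple(f"R{i + 1}" for i in range(r)),
        N=N,
        irreversible=irreversible,
    )


def random_scone(r: int, n_constraints: int, seed: int) -> SCone:
    """A random s-cone: kernel of a small integer matrix plus a random
    nonnegativity set."""
    rng = random.Random(seed)
    rows = [[rng.randint(-2, 2) for _ in range(r)] for _ in range(n_constraints)]
    nonneg = frozenset(i for i in range(r) if rng.random() < 0.5)
    return SCone(
        ambient_dim=r,
        subspace=Subspace.from_constraints(RationalMatrix(rows, ncols=r)),
        nonneg=nonneg,
    )


def random_polycone(r: int, m: int, seed: int) -> PolyCone:
    rng = random.Random(seed)
    rows = [[rng.randint(-2, 2) for _ in range(r)] for _ in range(m)]
    return PolyCone(RationalMatrix(rows, ncols=r))


def random_polyhedron(r: int, m: int, seed: int) -> Polyhedron:
    rng = random.Random(seed)
    rows = [[rng.randint(-2, 2) for _ in range(r)] for _ in range(m)]
    rhs = [rng.randint(-2, 1) for _ in range(m)]
    return Polyhedron(RationalMatrix(rows, ncols=r), vec(rhs))


def conic_member(evs: EVSet, seed: int) -> Vector:
    """A random conic combination of elementary rays (a guaranteed member)."""
    if not evs.rays:
        raise ValueError("cannot sample a member of the trivial cone")
    rng = random.Random(seed)
    total = [Fraction(0)] * evs.ambient_dim
    for ray in sorted(evs.rays):
        c = rng.randint(0, 3)
        for i, v in enumerate(ray):
            total[i] += c * v
    return tuple(total)


def polyhedron_member(evs: EVSet, seed: int) -> Vector:
    """A random member of a polyhedron from its EV set: a convex combination
    of ccND points plus a conic combination of recession rays."""
    if not evs.points:
        raise ValueError("EV set has no points; not a polyhedron EV set")
    rng = random.Random(seed)
    weights = [Fraction(rng.randint(0, 3)) for _ in evs.points]
    if sum(weights) == 0:
        weights[0] = Fraction(1)
    total_w = sum(weights)
    total = [Fraction(0)] * evs.ambient_dim
    for w, p in zip(weights, evs.sorted_points()):
        for i, v in enumerate(p):
            total[i] += (w / total_w) * v
    for ray in sorted(evs.rays):
        c = rng.randint(0, 2)
        for i, v in enumerate(ray):
            total[i] += c * v
    return tuple(total)


def bruteforce_evs(C: PolyCone, max_dim: int = 8) -> EVSet:
    """Elementary ray classes of a cone by the orthant characterization.

    For each of the 2^r closed orthants O, enumerates extreme rays of
    C intersected with O by exhaustive active-subset kernel checks, and
    deduplicates by canonical representative. Independent of the graph-lift
    enumeration code path; intended as a test oracle.

    The dimension guard is a hard error, never a silent truncation.
    """
    r = C.ambient_dim
    if r > max_dim:
        raise ValueError(f"bruteforce oracle limited to dimension {max_dim}")
    rays: set[tuple[int, ...]] = set()
    base_rows = list(C.A.entries)
    for pattern in product((1, -1), repeat=r):
        sign_rows = []
        for i, p in enumerate(pattern):
            unit = [Fraction(0)] * r
            unit[i] = Fraction(p)
            sign_rows.append(tuple(unit))
        rows = base_rows + sign_rows
        M = RationalMatrix(rows, ncols=r)
        for comb in combinations(range(len(rows)), r - 1):
            sub = RationalMatrix([rows[i] for i in comb], ncols=r)
            kb = kernel_basis(sub)
            if len(kb) != 1:
                continue
            (z,) = kb
            for cand in (z, vneg(z)):
                prods = M.matvec(cand)
                if any(v < 0 for v in prods):
                    continue
                active = [rows[i] for i, v in enumerate(prods) if v == 0]
                if r - rank(RationalMatrix(active, ncols=r)) == 1:
                    rays.add(canonical_ray(cand))
    return EVSet(r, frozenset(rays))


def all_two_term_decompositions(
    evs: EVSet, x: Sequence[Fraction]
) -> set[frozenset[tuple[Fraction, tuple[int, ...]]]]:
    """All ways to write x as a positive combination of two distinct EV
    classes: solves ``alpha*e + beta*e' = x`` exactly for every unordered
    pair and keeps the solvable ones with alpha, beta > 0.
    """
    xs = vec(x)
    found: set[frozenset] = set()
    for e, ep in combinations(sorted(evs.rays), 2):
        cols = RationalMatrix(
            ([Fraction(a), Fraction(b)] for a, b in zip(e, ep)),
            ncols=2,
        )
        sol = solve_unique(cols, xs)
        if sol is None:
            continue
        alpha, beta = sol
        if alpha > 0 and beta > 0:
            found.add(frozenset({(alpha, e), (beta, ep)}))
    return found
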