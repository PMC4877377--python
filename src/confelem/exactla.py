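"""Exact rational linear algebra.

Every geometric decision made downstream — support minimality, sign-vector
comparison, elementarity — is a statement about the *exact* sign pattern of
kernel elements. A floating-point pivot that turns a true zero into 1e-17
silently changes a support and with it the whole combinatorial answer, so
this module performs all arithmetic over :class:`fractions.Fraction` and
refuses floats at the boundary.

Row reduction uses deterministic pivoting (leftmost nonzero column, first
nonzero row, no pivot-size heuristics) so that kernel bases — and therefore
every enumeration and decomposition built on them — are reproducible across
runs and platforms.

Linear subspaces are represented dually: as the kernel of a constraint
matrix (the primary form, e.g. ``S = ker(N)`` for a stoichiometric matrix
``N``) or as a spanned basis; :class:`Subspace` converts between the two on
demand.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Iterable, Sequence

__all__ = [
    "Vector",
    "RationalMatrix",
    "Subspace",
    "as_rational",
    "format_rational",
    "vec",
    "vadd",
    "vsub",
    "vneg",
    "vscale",
    "dot",
    "is_zero",
    "support",
    "proportionality",
    "rank",
    "kernel_basis",
    "solve_unique",
    "slice_dim",
    "canonical_ray",
]

#: An exact rational vector: a tuple of Fractions.
Vector = tuple[Fraction, ...]


def as_rational(value: int | str | Fraction) -> Fraction:
    """Convert ``value`` to an exact rational; floats are rejected.

    Accepted string forms are ``"p/q"`` and bare integers (``"-3"``);
    decimal or scientific notation is refused rather than silently
    reinterpreted, because a file containing ``0.1`` almost certainly does
    not mean 1/10 exactly.
    """
    if isinstance(value, bool):
        raise TypeError("booleans are not rational scalars")
    if isinstance(value, float):
        raise TypeError(
            f"refusing float {value!r}: supply an int, Fraction, or 'p/q' string"
        )
    if isinstance(value, str):
        text = value.strip()
        if "." in text or "e" in text.lower():
            raise ValueError(f"not an exact rational literal: {value!r}")
        return Fraction(text)
    return Fraction(value)


def format_rational(q: Fraction) -> str:
    """Serialize a rational as ``"p/q"`` or a bare integer string."""
    q = Fraction(q)
    if q.denominator == 1:
        return str(q.numerator)
    return f"{q.numerator}/{q.denominator}"


def vec(values: Iterable) -> Vector:
    return tuple(as_rational(v) for v in values)


def vadd(x: Sequence[Fraction], y: Sequence[Fraction]) -> Vector:
    if len(x) != len(y):
        raise ValueError(f"dimension mismatch: {len(x)} vs {len(y)}")
    return tuple(a + b for a, b in zip(x, y))


def vsub(x: Sequence[Fraction], y: Sequence[Fraction]) -> Vector:
    if len(x) != len(y):
        raise ValueError(f"dimension mismatch: {len(x)} vs {len(y)}")
    return tuple(a - b for a, b in zip(x, y))


def vneg(x: Sequence[Fraction]) -> Vector:
    return tuple(-a for a in x)


def vscale(lam: Fraction, x: Sequence[Fraction]) -> Vector:
    lam = as_rational(lam)
    return tuple(lam * a for a in x)


def dot(x: Sequence[Fraction], y: Sequence[Fraction]) -> Fraction:
    if len(x) != len(y):
        raise ValueError(f"dimension mismatch: {len(x)} vs {len(y)}")
    return sum((a * b for a, b in zip(x, y)), Fraction(0))


def is_zero(x: Sequence[Fraction]) -> bool:
    return all(a == 0 for a in x)


def support(x: Sequence[Fraction]) -> frozenset[int]:
    """Indices of the nonzero components, supp(x)."""
    return frozenset(i for i, a in enumerate(x) if a != 0)


def proportionality(x: Sequence[Fraction], y: Sequence[Fraction]) -> Fraction | None:
    """Return the factor mu with ``x == mu * y``, or None if not proportional.

    Both vectors must be nonzero; proportional vectors necessarily have
    equal supports, which is checked first.
    """
    if len(x) != len(y):
        raise ValueError("dimension mismatch")
    if is_zero(x) or is_zero(y):
        raise ValueError("proportionality is defined for nonzero vectors")
    sx, sy = support(x), support(y)
    if sx != sy:
        return None
    i0 = min(sx)
    mu = Fraction(x[i0]) / Fraction(y[i0])
    if all(x[i] == mu * y[i] for i in sx):
        return mu
    return None


class RationalMatrix:
    """Dense matrix with exact rational entries.

    Immutable; rows are tuples of Fractions. An empty matrix (zero rows)
    needs an explicit ``ncols`` so that kernels of empty constraint sets are
    well defined.
    """

    __slots__ = ("entries", "_ncols")

    def __init__(self, rows: Iterable[Iterable], ncols: int | None = None):
        ents = tuple(vec(r) for r in rows)
        widths = {len(r) for r in ents}
        if len(widths) > 1:
            raise ValueError("ragged rows")
        if ents:
            inferred = widths.pop()
            if ncols is not None and ncols != inferred:
                raise ValueError(f"ncols={ncols} but rows have length {inferred}")
            ncols = inferred
        elif ncols is None:
            raise ValueError("empty matrix requires explicit ncols")
        if ncols < 0:
            raise ValueError("ncols must be nonnegative")
        object.__setattr__(self, "entries", ents)
        object.__setattr__(self, "_ncols", ncols)

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("RationalMatrix is immutable")

    @property
    def nrows(self) -> int:
        return len(self.entries)

    @property
    def ncols(self) -> int:
        return self._ncols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self._ncols)

    def row(self, i: int) -> Vector:
        return self.entries[i]

    def column(self, j: int) -> Vector:
        if not 0 <= j < self._ncols:
            raise IndexError(f"column {j} out of range")
        return tuple(r[j] for r in self.entries)

    def matvec(self, x: Sequence[Fraction]) -> Vector:
        if len(x) != self._ncols:
            raise ValueError(
                f"dimension mismatch: matrix has {self._ncols} columns, vector has {len(x)}"
            )
        return tuple(dot(r, x) for r in self.entries)

    def transpose(self) -> "RationalMatrix":
        return RationalMatrix(
            ([r[j] for r in self.entries] for j in range(self._ncols)),
            ncols=self.nrows,
        )

    @classmethod
    def identity(cls, n: int) -> "RationalMatrix":
        return cls(
            ([Fraction(int(i == j)) for j in range(n)] for i in range(n)), ncols=n
        )

    @classmethod
    def vstack(cls, blocks: Iterable["RationalMatrix"]) -> "RationalMatrix":
        blocks = list(blocks)
        if not blocks:
            raise ValueError("vstack of no blocks")
        ncols = blocks[0].ncols
        rows: list[Vector] = []
        for b in blocks:
            if b.ncols != ncols:
                raise ValueError("column-count mismatch in vstack")
            rows.extend(b.entries)
        return cls(rows, ncols=ncols)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RationalMatrix):
            return NotImplemented
        return self.entries == other.entries and self._ncols == other._ncols

    def __hash__(self) -> int:
        return hash((self.entries, self._ncols))

    def __repr__(self) -> str:
        rows = ", ".join(
            "[" + ", ".join(format_rational(v) for v in r) + "]" for r in self.entries
        )
        return f"RationalMatrix([{rows}], ncols={self._ncols})"


def _rref(rows: list[list[Fraction]], ncols: int) -> tuple[list[list[Fraction]], list[int]]:
    """Reduced row echelon form with deterministic pivoting.

    Pivot rule: scan columns left to right, take the first row (top to
    bottom) with a nonzero entry. Returns the nonzero rows and the pivot
    column indices.
    """
    rows = [list(r) for r in rows]
    m = len(rows)
    pivots: list[int] = []
    pr = 0
    for c in range(ncols):
        piv = next((i for i in range(pr, m) if rows[i][c] != 0), None)
        if piv is None:
            continue
        rows[pr], rows[piv] = rows[piv], rows[pr]
        inv = rows[pr][c]
        rows[pr] = [v / inv for v in rows[pr]]
        for i in range(m):
            if i != pr and rows[i][c] != 0:
                f = rows[i][c]
                rows[i] = [a - f * b for a, b in zip(rows[i], rows[pr])]
        pivots.append(c)
        pr += 1
        if pr == m:
            break
    return rows[:pr], pivots


def rank(M: RationalMatrix) -> int:
    """Dimension of the row space, by exact Gaussian elimination."""
    _, pivots = _rref([list(r) for r in M.entries], M.ncols)
    return len(pivots)


def kernel_basis(M: RationalMatrix) -> tuple[Vector, ...]:
    """Deterministic basis of ``ker(M) = {v : Mv = 0}``.

    The basis is derived from the RREF: one vector per free column, free
    columns in increasing order, with a 1 in the free coordinate. Every
    returned vector satisfies ``Mv = 0`` exactly.
    """
    reduced, pivots = _rref([list(r) for r in M.entries], M.ncols)
    pivot_set = set(pivots)
    free = [c for c in range(M.ncols) if c not in pivot_set]
    basis: list[Vector] = []
    for f in free:
        v = [Fraction(0)] * M.ncols
        v[f] = Fraction(1)
        for prow, pcol in zip(reduced, pivots):
            v[pcol] = -prow[f]
        basis.append(tuple(v))
    return tuple(basis)


def solve_unique(M: RationalMatrix, b: Sequence[Fraction]) -> Vector | None:
    """Solve ``Mx = b`` exactly; None if inconsistent or non-unique."""
    b = vec(b)
    if len(b) != M.nrows:
        raise ValueError("right-hand side length mismatch")
    aug = [list(r) + [bi] for r, bi in zip(M.entries, b)]
    if not aug:
        return None if M.ncols else ()
    reduced, pivots = _rref(aug, M.ncols + 1)
    if M.ncols in pivots:
        return None  # inconsistent
    if len(pivots) < M.ncols:
        return None  # underdetermined
    x = [Fraction(0)] * M.ncols
    for prow, pcol in zip(reduced, pivots):
        x[pcol] = prow[-1]
    return tuple(x)


def _int_rank(rows: list[list[int]]) -> int:
    """Rank of an integer matrix by fraction-free (Bareiss) elimination.

    Fast path for the minimal-support search, where many small ranks are
    computed; exactness is preserved because all divisions are exact.
    """
    if not rows:
        return 0
    a = [r[:] for r in rows]
    m, n = len(a), len(a[0])
    prev = 1
    rk = 0
    for col in range(n):
        piv = next((i for i in range(rk, m) if a[i][col]), None)
        if piv is None:
            continue
        a[rk], a[piv] = a[piv], a[rk]
        pivot = a[rk][col]
        for i in range(rk + 1, m):
            ai = a[i]
            ar = a[rk]
            f = ai[col]
            for j in range(col + 1, n):
                ai[j] = (pivot * ai[j] - f * ar[j]) // prev
            ai[col] = 0
        prev = pivot
        rk += 1
        if rk == m:
            break
    return rk


def canonical_ray(x: Sequence[Fraction]) -> tuple[int, ...]:
    """Canonical representative of the ray class {lambda*x : lambda > 0}.

    The unique positive scalar multiple of ``x`` with integer entries of
    overall gcd 1; the sign pattern of ``x`` is preserved exactly (the ray
    is never flipped).
    """
    xs = vec(x)
    if is_zero(xs):
        raise ValueError("the zero vector has no ray class")
    scale = math.lcm(*(v.denominator for v in xs))
    ints = [int(v * scale) for v in xs]
    g = math.gcd(*ints)
    return tuple(i // g for i in ints)


class Subspace:
    """A linear subspace of Q^n.

    Construct either from a constraint matrix (``S = ker(M)``, the primary
    form) or from a spanned set of vectors. The basis exposed is always the
    deterministic RREF-derived one, so identical inputs give identical
    bases, slices, and downstream enumerations.
    """

    __slots__ = ("ambient_dim", "_constraints", "_basis", "_int_cols")

    def __init__(
        self,
        ambient_dim: int,
        *,
        constraints: RationalMatrix | None = None,
        basis: Sequence[Sequence] | None = None,
    ):
        if (constraints is None) == (basis is None):
            raise ValueError("provide exactly one of constraints= or basis=")
        if ambient_dim < 0:
            raise ValueError("ambient_dim must be nonnegative")
        self.ambient_dim = ambient_dim
        self._int_cols: tuple[tuple[int, ...], ...] | None = None
        if constraints is not None:
            if constraints.ncols != ambient_dim:
                raise ValueError("constraint matrix width must equal ambient_dim")
            self._constraints: RationalMatrix | None = constraints
            self._basis: tuple[Vector, ...] | None = None
        else:
            raw = [vec(v) for v in basis]
            for v in raw:
                if len(v) != ambient_dim:
                    raise ValueError("basis vector length must equal ambient_dim")
            # canonicalize: RREF rows of the spanned matrix
            reduced, _ = _rref([list(v) for v in raw], ambient_dim)
            self._basis = tuple(tuple(r) for r in reduced)
            self._constraints = None

    @classmethod
    def from_constraints(cls, M: RationalMatrix) -> "Subspace":
        """The kernel {v : Mv = 0}."""
        return cls(M.ncols, constraints=M)

    @classmethod
    def from_basis(cls, vectors: Sequence[Sequence], ambient_dim: int) -> "Subspace":
        """The span of the given vectors."""
        return cls(ambient_dim, basis=vectors)

    @property
    def basis(self) -> tuple[Vector, ...]:
        if self._basis is None:
            self._basis = kernel_basis(self._constraints)
        return self._basis

    @property
    def constraints(self) -> RationalMatrix:
        """A matrix M with S = ker(M) (rows span the annihilator of S)."""
        if self._constraints is None:
            B = RationalMatrix(self.basis, ncols=self.ambient_dim) if self.basis \
                else RationalMatrix([], ncols=self.ambient_dim)
            self._constraints = RationalMatrix(
                kernel_basis(B), ncols=self.ambient_dim
            )
        return self._constraints

    @property
    def dim(self) -> int:
        return len(self.basis)

    def contains(self, x: Sequence[Fraction]) -> bool:
        xs = vec(x)
        if len(xs) != self.ambient_dim:
            raise ValueError("dimension mismatch")
        return is_zero(self.constraints.matvec(xs))

    def _integer_columns(self) -> tuple[tuple[int, ...], ...]:
        # per-coordinate integer columns of the basis (denominators cleared
        # row-wise); rank computations over column subsets are unaffected
        if self._int_cols is None:
            cleared = []
            for v in self.basis:
                scale = math.lcm(*(q.denominator for q in v)) if v else 1
                cleared.append([int(q * scale) for q in v])
            self._int_cols = tuple(
                tuple(row[i] for row in cleared) for i in range(self.ambient_dim)
            )
        return self._int_cols

    def _check_indices(self, keep: Iterable[int]) -> frozenset[int]:
        keep = frozenset(keep)
        for i in keep:
            if not 0 <= i < self.ambient_dim:
                raise IndexError(f"coordinate index {i} out of range")
        return keep

    def slice_dim(self, keep: Iterable[int]) -> int:
        """dim{z in S : z_i = 0 for all i not in ``keep``}."""
        keep = self._check_indices(keep)
        s = self.dim
        if s == 0:
            return 0
        comp = [i for i in range(self.ambient_dim) if i not in keep]
        if not comp:
            return s
        cols = self._integer_columns()
        return s - _int_rank([list(cols[i]) for i in comp])

    def slice_basis(self, keep: Iterable[int]) -> list[Vector]:
        """Deterministic basis of the coordinate slice of S."""
        keep = self._check_indices(keep)
        B = self.basis
        s = len(B)
        if s == 0:
            return []
        comp = [i for i in range(self.ambient_dim) if i not in keep]
        if not comp:
            return list(B)
        K = RationalMatrix(([B[j][i] for j in range(s)] for i in comp), ncols=s)
        out: list[Vector] = []
        for c in kernel_basis(K):
            v = [Fraction(0)] * self.ambient_dim
            for j, cj in enumerate(c):
                if cj != 0:
                    for i in range(self.ambient_dim):
                        v[i] += cj * B[j][i]
            out.append(tuple(v))
        return out

    def __repr__(self) -> str:
        return f"Subspace(dim={self.dim}, ambient_dim={self.ambient_dim})"


def slice_dim(S: Subspace, keep: Iterable[int]) -> int:
    """Module-level alias for :meth:`Subspace.slice_dim`."""
    return S.slice_dim(keep)
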