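"""Metabolic-network frontend: flux cones, elementary modes, decomposition.

A network is a stoichiometric matrix N (n internal metabolites times r
reactions, exact rational entries), a set I of irreversible reactions, and
optional flux bounds. The steady-state flux distributions form the flux
cone ``{f : Nf = 0, f_i >= 0 for i in I}`` — an s-cone with S = ker(N) —
and its support-minimal members are the elementary modes (EMs). With at
least one finite bound the feasible set becomes a flux polyhedron, whose
elementary vectors split into recession-cone ray classes and ccND points.

Decomposing a flux mode into EMs without cancelations means: a reaction
carrying zero flux is zero in every contributing EM, and a reversible
reaction never runs in both directions across contributing EMs. This is
exactly a conformal sum, delegated to :mod:`confelem.decompose`.

File formats (all exact; floats are rejected):

* model TSV — header row of reaction identifiers, first column of
  metabolite identifiers, entries rational ``p/q`` or integer strings;
* constraints JSON — ``{"irreversible": [...], "bounds": {...}}`` where
  reactions are referenced by name or by 1-based position, and bounds are
  ``[lower, upper]`` pairs with ``null`` for unbounded sides.

Reactions are 1-based in files and messages, 0-based in the API.

Exchange ("external") metabolites are simply absent from N; no special
handling is applied or needed, but model authors must leave them out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .decompose import ConformalSum, conformal_sum_polyhedron, conformal_sum_scone
from .enumeration import EVSet, evs_polyhedron, evs_scone
from .exactla import (
    RationalMatrix,
    Subspace,
    Vector,
    as_rational,
    format_rational,
    vec,
)
from .geometry import Polyhedron, SCone

__all__ = [
    "MetabolicNetwork",
    "read_network",
    "read_flux",
    "flux_cone",
    "flux_polyhedron",
    "elementary_modes",
    "decompose_flux",
    "knockout_filter",
    "evset_to_frame",
    "write_evset",
    "conformal_sum_to_dict",
]

Bound = tuple[Fraction | None, Fraction | None]


@dataclass(frozen=True, eq=False)
class MetabolicNetwork:
    """Stoichiometric matrix plus irreversibility and optional bounds."""

    metabolites: tuple[str, ...]
    reactions: tuple[str, ...]
    N: RationalMatrix
    irreversible: frozenset[int]
    bounds: Mapping[int, Bound] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "irreversible", frozenset(self.irreversible))
        object.__setattr__(self, "bounds", dict(self.bounds))
        if self.N.shape != (len(self.metabolites), len(self.reactions)):
            raise ValueError("stoichiometric matrix shape mismatch")
        for i in self.irreversible:
            if not 0 <= i < self.n_reactions:
                raise IndexError(f"irreversible index {i} out of range")
        for i, (lo, up) in self.bounds.items():
            if not 0 <= i < self.n_reactions:
                raise IndexError(f"bound on unknown reaction index {i}")
            if lo is not None and up is not None and lo > up:
                raise ValueError(
                    f"reaction {self.reactions[i]!r}: lower bound exceeds upper bound"
                )

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def has_finite_bounds(self) -> bool:
        return any(
            lo is not None or up is not None for lo, up in self.bounds.values()
        )

    def reaction_index(self, key: str | int) -> int:
        """Resolve a reaction by name or 1-based position to a 0-based index."""
        if isinstance(key, int):
            if not 1 <= key <= self.n_reactions:
                raise IndexError(f"reaction position {key} out of range (1-based)")
            return key - 1
        if key in self.reactions:
            return self.reactions.index(key)
        try:
            pos = int(key)
        except ValueError:
            raise KeyError(f"unknown reaction identifier {key!r}") from None
        return self.reaction_index(pos)


def read_network(
    model_path: str | Path, constraints_path: str | Path | None = None
) -> MetabolicNetwork:
    """Read a stoichiometric TSV plus an optional JSON constraints sidecar."""
    with open(model_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header[1:])) != len(header[1:]):
        raise ValueError("duplicate reaction identifiers in model header")
    frame = pd.read_csv(model_path, sep="\t", index_col=0, dtype=str)
    reactions = tuple(str(c) for c in frame.columns)
    metabolites = tuple(str(i) for i in frame.index)
    if len(set(metabolites)) != len(metabolites):
        raise ValueError("duplicate metabolite identifiers in model")
    N = RationalMatrix(
        ([as_rational(v) for v in row] for row in frame.itertuples(index=False)),
        ncols=len(reactions),
    )
    irreversible: frozenset[int] = frozenset()
    bounds: dict[int, Bound] = {}
    if constraints_path is not None:
        with open(constraints_path) as fh:
            sidecar = json.load(fh)
        stub = MetabolicNetwork(metabolites, reactions, N, frozenset())
        irreversible = frozenset(
            stub.reaction_index(k) for k in sidecar.get("irreversible", [])
        )
        for key, pair in sidecar.get("bounds", {}).items():
            lo, up = pair
            bounds[stub.reaction_index(key)] = (
                None if lo is None else as_rational(lo),
                None if up is None else as_rational(up),
            )
    return MetabolicNetwork(metabolites, reactions, N, irreversible, bounds)


def read_flux(path: str | Path, net: MetabolicNetwork) -> Vector:
    """Read a flux vector: two-column TSV (reaction, value) or a JSON map."""
    path = Path(path)
    values: dict[int, Fraction] = {}
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        items = data.items()
    else:
        items = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("\t")
            if key.strip().lower() == "reaction":
                continue  # optional header line
            items.append((key.strip(), value.strip()))
    for key, value in items:
        values[net.reaction_index(key)] = as_rational(value)
    missing = [net.reactions[i] for i in range(net.n_reactions) if i not in values]
    if missing:
        raise ValueError(f"flux file missing reactions: {missing}")
    return tuple(values[i] for i in range(net.n_reactions))


def flux_cone(net: MetabolicNetwork) -> SCone:
    """The flux cone {f : Nf = 0, f_i >= 0 for irreversible i} as an s-cone."""
    return SCone(
        ambient_dim=net.n_reactions,
        subspace=Subspace.from_constraints(net.N),
        nonneg=net.irreversible,
    )


def flux_polyhedron(net: MetabolicNetwork) -> Polyhedron:
    """The flux polyhedron: steady state, irreversibility, and finite bounds.

    The equalities Nf = 0 are encoded as inequality pairs so that a single
    ``Ax >= b`` representation suffices; the s-cone route via
    :func:`flux_cone` avoids this doubling and is preferred when no finite
    bounds are present (which is an error here).
    """
    if not net.has_finite_bounds:
        raise ValueError("no finite bounds: use flux_cone instead")
    r = net.n_reactions
    rows: list[list[Fraction]] = []
    rhs: list[Fraction] = []
    for j in range(net.n_metabolites):
        row = list(net.N.row(j))
        rows.append(row)
        rhs.append(Fraction(0))
        rows.append([-v for v in row])
        rhs.append(Fraction(0))
    for i in sorted(net.irreversible):
        unit = [Fraction(0)] * r
        unit[i] = Fraction(1)
        rows.append(unit)
        rhs.append(Fraction(0))
    for i in sorted(net.bounds):
        lo, up = net.bounds[i]
        if lo is not None:
            unit = [Fraction(0)] * r
            unit[i] = Fraction(1)
            rows.append(unit)
            rhs.append(lo)
        if up is not None:
            unit = [Fraction(0)] * r
            unit[i] = Fraction(-1)
            rows.append(unit)
            rhs.append(-up)
    return Polyhedron(RationalMatrix(rows, ncols=r), tuple(rhs))


def elementary_modes(net: MetabolicNetwork) -> EVSet:
    """All elementary modes of the network, as canonical ray classes."""
    return evs_scone(flux_cone(net))


def decompose_flux(net: MetabolicNetwork, f: Sequence[Fraction]) -> ConformalSum:
    """Decompose a flux mode into elementary modes without cancelations.

    Uses the flux polyhedron when finite bounds are present, otherwise the
    flux cone. Every contributing term conforms to f: zero components stay
    zero, and no reversible reaction runs in both directions across terms.
    """
    fs = vec(f)
    if net.has_finite_bounds:
        P = flux_polyhedron(net)
        if not P.contains(fs):
            raise ValueError("flux vector violates the flux polyhedron")
        return conformal_sum_polyhedron(P, fs)
    C = flux_cone(net)
    if not C.contains(fs):
        raise ValueError("flux vector is not a steady-state flux mode")
    return conformal_sum_scone(C, fs)


def knockout_filter(evs: EVSet, reaction: int) -> EVSet:
    """Elementary vectors surviving a knockout of ``reaction`` (0-based).

    Retains exactly the EVs with zero flux through the reaction; this
    equals recomputing the EVs of the model with the reaction forced to
    zero, without recalculating generators.
    """
    if not 0 <= reaction < evs.ambient_dim:
        raise IndexError(f"reaction index {reaction} out of range")
    return EVSet(
        ambient_dim=evs.ambient_dim,
        rays=frozenset(ray for ray in evs.rays if ray[reaction] == 0),
        points=frozenset(p for p in evs.points if p[reaction] == 0),
    )


def evset_to_frame(evs: EVSet, names: Sequence[str] | None = None) -> pd.DataFrame:
    """Tabulate an EV set: one row per EV, kind column in {ray, point}."""
    if names is None:
        names = [f"r{i + 1}" for i in range(evs.ambient_dim)]
    records = []
    for ray in evs.sorted_rays():
        records.append(["ray"] + [str(v) for v in ray])
    for p in evs.sorted_points():
        records.append(["point"] + [format_rational(v) for v in p])
    return pd.DataFrame(records, columns=["kind"] + list(names))


def write_evset(
    evs: EVSet, path: str | Path, names: Sequence[str] | None = None
) -> None:
    evset_to_frame(evs, names).to_csv(path, sep="\t", index=False)


def conformal_sum_to_dict(csum: ConformalSum) -> dict:
    """JSON-ready representation of a conformal sum."""
    return {
        "target": [format_rational(v) for v in csum.target],
        "cone_terms": [
            [format_rational(v) for v in t] for t in csum.cone_terms
        ],
        "convex_terms": [
            {
                "point": [format_rational(v) for v in p],
                "weight": format_rational(w),
            }
            for p, w in csum.convex_terms
        ],
    }
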