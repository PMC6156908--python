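"""Basins, saddles and their hierarchical organization (the Omega list)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .boundary import BoundaryPolygon


@dataclass
class Basin:
    """A connected sublevel-set component with polygonal boundary.

    ``birth_level`` is the energy level at which the component appeared as a
    separate basin during the descent; ``deepest_point`` / ``deepest_energy``
    locate the minimum-energy grid point inside.
    """

    id: int
    grid_points: np.ndarray          # (k, 2) world coordinates
    boundary: BoundaryPolygon
    birth_level: float
    deepest_point: tuple[float, float]
    deepest_energy: float
    parent_id: int | None = None

    def __post_init__(self) -> None:
        self.grid_points = np.asarray(self.grid_points, dtype=float).reshape(-1, 2)

    @property
    def n_grid_points(self) -> int:
        return len(self.grid_points)


@dataclass
class SaddlePoint:
    """A basin-joining saddle.

    ``method`` records provenance: ``bdr_midpoint`` for the working-definition
    saddle (midpoint of the minimum-length segment between two basin
    boundaries) and ``sdr_critical`` for a true critical point (zero gradient,
    Hessian eigenvalues of opposite signs).
    """

    location: tuple[float, float]
    energy: float
    method: str                      # "bdr_midpoint" | "sdr_critical"
    basin_a: int | None = None
    basin_b: int | None = None
    hessian_eigenvalues: tuple[float, float] | None = None


@dataclass
class LocalMinimum:
    """A local minimum of the smoothed surface, with its seed cluster size."""

    location: tuple[float, float]
    energy: float
    cluster_size: int = 1


@dataclass
class Hierarchy:
    """Nested basins and saddles produced by a reconstruction (Omega)."""

    basins: list[Basin] = field(default_factory=list)
    saddles: list[SaddlePoint] = field(default_factory=list)
    minima: list[LocalMinimum] = field(default_factory=list)
    variant_label: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        self._by_id = {b.id: b for b in self.basins}

    def basin(self, basin_id: int) -> Basin:
        return self._by_id[basin_id]

    @property
    def parent_of(self) -> dict[int, int | None]:
        return {b.id: b.parent_id for b in self.basins}

    def children(self, basin_id: int | None) -> list[Basin]:
        return [b for b in self.basins if b.parent_id == basin_id]

    def leaves(self) -> list[Basin]:
        parents = {b.parent_id for b in self.basins if b.parent_id is not None}
        return [b for b in self.basins if b.id not in parents]

    def ancestors(self, basin_id: int) -> list[int]:
        """Chain of basin ids from ``basin_id`` up to (and including) the root."""
        chain = [basin_id]
        while self._by_id[chain[-1]].parent_id is not None:
            chain.append(self._by_id[chain[-1]].parent_id)
        return chain

    def validate(self) -> None:
        """Check structural invariants (nesting, saddle references)."""
        for b in self.basins:
            if b.parent_id is not None:
                parent = self._by_id[b.parent_id]
                child = {tuple(p) for p in np.round(b.grid_points, 9)}
                par = {tuple(p) for p in np.round(parent.grid_points, 9)}
                if not child <= par:
                    raise AssertionError(f"basin {b.id} is not nested in its parent")
                if b.birth_level > parent.birth_level + 1e-12:
                    raise AssertionError(f"basin {b.id} born above its parent")
        for s in self.saddles:
            if s.basin_a is not None or s.basin_b is not None:
                if s.basin_a == s.basin_b:
                    raise AssertionError("saddle must reference two distinct basins")
                for ref in (s.basin_a, s.basin_b):
                    if ref is not None and ref not in self._by_id:
                        raise AssertionError(f"saddle references unknown basin {ref}")

    def summary(self) -> str:
        lines = [
            f"Hierarchy ({self.method or 'unspecified method'})"
            + (f" for variant {self.variant_label!r}" if self.variant_label else ""),
            f"  basins: {len(self.basins)} ({len(self.leaves())} leaves)",
            f"  saddles: {len(self.saddles)}",
        ]
        if self.minima:
            lines.append(f"  local minima: {len(self.minima)}")
        for b in sorted(self.basins, key=lambda b: b.id):
            lines.append(
                f"  basin {b.id:3d} parent={str(b.parent_id):>4s} "
                f"birth_level={b.birth_level: .4f} n_grid={b.n_grid_points:6d} "
                f"deepest=({b.deepest_point[0]: .3f},{b.deepest_point[1]: .3f}) "
                f"E={b.deepest_energy: .4f}"
            )
        for s in self.saddles:
            lines.append(
                f"  saddle ({s.location[0]: .3f},{s.location[1]: .3f}) "
                f"E={s.energy: .4f} [{s.method}] joins {s.basin_a}<->{s.basin_b}"
            )
        return "\n".join(lines)


# -- serialization ------------------------------------------------------------

_FORMAT = "landscaper-hierarchy"


def hierarchy_to_dict(h: Hierarchy, include_grid_points: bool = True) -> dict:
    return {
        "format": _FORMAT,
        "version": 1,
        "variant_label": h.variant_label,
        "method": h.method,
        "basins": [
            {
                "id": b.id,
                "parent_id": b.parent_id,
                "birth_level": b.birth_level,
                "boundary": {
                    "vertices": np.asarray(b.boundary.vertices).tolist(),
                    "closed": b.boundary.closed,
                },
                "deepest_point": list(b.deepest_point),
                "deepest_energy": b.deepest_energy,
                "n_grid_points": b.n_grid_points,
                **(
                    {"grid_points": b.grid_points.tolist()}
                    if include_grid_points
                    else {}
                ),
            }
            for b in h.basins
        ],
        "saddles": [
            {
                "location": list(s.location),
                "energy": s.energy,
                "method": s.method,
                "basin_a": s.basin_a,
                "basin_b": s.basin_b,
                "hessian_eigenvalues": (
                    list(s.hessian_eigenvalues)
                    if s.hessian_eigenvalues is not None
                    else None
                ),
            }
            for s in h.saddles
        ],
        "minima": [
            {
                "location": list(m.location),
                "energy": m.energy,
                "cluster_size": m.cluster_size,
            }
            for m in h.minima
        ],
    }


def hierarchy_from_dict(d: dict) -> Hierarchy:
    if d.get("format") != _FORMAT:
        raise ValueError("not a landscaper hierarchy file")
    basins = []
    for bd in d["basins"]:
        boundary = BoundaryPolygon(
            np.asarray(bd["boundary"]["vertices"], dtype=float).reshape(-1, 2),
            closed=bd["boundary"]["closed"],
        )
        gp = np.asarray(bd.get("grid_points", []), dtype=float).reshape(-1, 2)
        basins.append(
            Basin(
                id=bd["id"],
                grid_points=gp,
                boundary=boundary,
                birth_level=bd["birth_level"],
                deepest_point=tuple(bd["deepest_point"]),
                deepest_energy=bd["deepest_energy"],
                parent_id=bd["parent_id"],
            )
        )
    saddles = [
        SaddlePoint(
            location=tuple(sd["location"]),
            energy=sd["energy"],
            method=sd["method"],
            basin_a=sd["basin_a"],
            basin_b=sd["basin_b"],
            hessian_eigenvalues=(
                tuple(sd["hessian_eigenvalues"])
                if sd.get("hessian_eigenvalues") is not None
                else None
            ),
        )
        for sd in d["saddles"]
    ]
    minima = [
        LocalMinimum(tuple(md["location"]), md["energy"], md["cluster_size"])
        for md in d.get("minima", [])
    ]
    return Hierarchy(
        basins, saddles, minima,
        variant_label=d.get("variant_label", ""), method=d.get("method", ""),
    )


def write_hierarchy(h: Hierarchy, path, include_grid_points: bool = True) -> None:
    """Serialize a hierarchy to JSON; round-trips losslessly (repr floats)."""
    payload = hierarchy_to_dict(h, include_grid_points=include_grid_points)
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_hierarchy(path) -> Hierarchy:
    with open(Path(path)) as fh:
        return hierarchy_from_dict(json.load(fh))
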