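"""Alpha-convex shapes and the regular grid laid over them.

The alpha-convex shape generalizes the convex hull: a Delaunay triangulation
of the point cloud is filtered by the circumradius criterion (keep triangles
whose circumscribed circle has radius at most ``1/alpha``) and the kept
triangles are unioned. In the large-radius limit (alpha -> 0) every triangle
survives and the shape degenerates to the convex hull; as the radius shrinks
the shape follows concavities and can develop holes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import MultiPolygon, Polygon


@dataclass
class BoundaryPolygon:
    """A closed (or degenerate open) polygonal boundary in PC space."""

    vertices: np.ndarray   # (k, 2), no closing duplicate
    closed: bool = True
    is_hole: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if self.closed and len(self.vertices) < 3:
            raise ValueError("a closed boundary polygon needs at least 3 vertices")
        if len(self.vertices) > 1:
            dup = np.all(self.vertices[1:] == self.vertices[:-1], axis=1)
            if dup.any():
                self.vertices = self.vertices[np.r_[True, ~dup]]

    def to_shapely(self) -> Polygon:
        return Polygon(self.vertices)


def _circumradius(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each Delaunay triangle; inf for degenerate ones."""
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    u, v = b - a, c - a
    area2 = np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[~np.isfinite(r)] = np.inf
    return r


def alpha_shape_geometry(points: np.ndarray, alpha: float):
    """Alpha-convex shape of a 2D point cloud as a shapely (Multi)Polygon."""
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("alpha shape needs at least 3 points")
    if alpha <= 0:
        raise ValueError("alpha must be strictly positive")
    try:
        tri = Delaunay(points)
    except Exception as exc:  # all collinear, or qhull degeneracy
        raise ValueError(f"cannot triangulate point cloud: {exc}") from exc
    radius = _circumradius(points, tri.simplices)
    keep = tri.simplices[radius <= 1.0 / alpha]
    if len(keep) == 0:
        raise ValueError(
            "no triangle satisfies the circumradius criterion; "
            "use a smaller alpha (larger ball radius 1/alpha)"
        )
    triangles = shapely.polygons(points[keep])
    geom = shapely.union_all(triangles)
    if geom.is_empty or geom.area == 0.0:
        raise ValueError("alpha shape is degenerate (zero area)")
    return geom


def geometry_to_polygons(geom) -> list[BoundaryPolygon]:
    """Flatten a shapely (Multi)Polygon into boundary rings (holes flagged)."""
    polys = list(geom.geoms) if isinstance(geom, MultiPolygon) else [geom]
    out: list[BoundaryPolygon] = []
    for poly in polys:
        out.append(BoundaryPolygon(np.asarray(poly.exterior.coords)[:-1], closed=True))
        for ring in poly.interiors:
            out.append(BoundaryPolygon(np.asarray(ring.coords)[:-1], closed=True, is_hole=True))
    return out


def compute_alpha_shape(samples, alpha: float) -> list[BoundaryPolygon]:
    """Alpha-convex shape of a sample cloud as closed boundary polygons.

    Accepts a :class:`~landscaper.samples.SampleSet` or an (n, 2) array.
    """
    points = getattr(samples, "points", samples)
    return geometry_to_polygons(alpha_shape_geometry(points, alpha))


def component_boundary(points: np.ndarray, alpha: float) -> BoundaryPolygon:
    """Boundary of one basin's grid points: alpha hull, with degenerate
    fallbacks (convex hull, then the bare point list) for tiny components."""
    points = np.asarray(points, dtype=float)
    if len(points) >= 3:
        try:
            geom = alpha_shape_geometry(points, alpha)
            polys = geometry_to_polygons(geom)
            # exterior ring of the largest polygon piece
            exteriors = [p for p in polys if not p.is_hole]
            areas = [p.to_shapely().area for p in exteriors]
            if len(exteriors) == 1:
                return exteriors[0]
            # multiple pieces: merge vertices of all exteriors (saddle
            # detection only needs the vertex set); keep the largest ring
            return exteriors[int(np.argmax(areas))]
        except ValueError:
            pass
    return BoundaryPolygon(points, closed=False)


@dataclass
class Grid:
    """Axis-aligned lattice at spacing ``delta1`` clipped to the alpha shape."""

    points: np.ndarray        # (g, 2) world coordinates
    spacing: float
    origin: tuple[float, float]   # world coordinates of lattice index (0, 0)
    lattice: np.ndarray       # (g, 2) integer lattice indices (ix, iy)
    shape: tuple[int, int]    # raster extent (nx, ny)
    _tree: cKDTree | None = None

    def __len__(self) -> int:
        return len(self.points)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree

    def subset(self, index: np.ndarray) -> "Grid":
        return Grid(self.points[index], self.spacing, self.origin,
                    self.lattice[index], self.shape)

    def raster_mask(self, index: np.ndarray | None = None) -> np.ndarray:
        """Boolean raster of shape ``self.shape`` marking the given points."""
        mask = np.zeros(self.shape, dtype=bool)
        lat = self.lattice if index is None else self.lattice[index]
        mask[lat[:, 0], lat[:, 1]] = True
        return mask


def build_grid(geom_or_polygons, delta1: float) -> Grid:
    """Lay a regular grid at spacing ``delta1`` over the alpha shape interior.

    Accepts a shapely geometry or a list of :class:`BoundaryPolygon`. The
    point-in-polygon test is boundary-inclusive.
    """
    if delta1 <= 0:
        raise ValueError("delta1 must be strictly positive")
    geom = geom_or_polygons
    if isinstance(geom, (list, tuple)):
        outer = shapely.union_all([p.to_shapely() for p in geom if not p.is_hole])
        holes = [p.to_shapely() for p in geom if p.is_hole]
        geom = outer.difference(shapely.union_all(holes)) if holes else outer
    minx, miny, maxx, maxy = geom.bounds
    ix0 = int(np.ceil(minx / delta1 - 1e-9))
    ix1 = int(np.floor(maxx / delta1 + 1e-9))
    iy0 = int(np.ceil(miny / delta1 - 1e-9))
    iy1 = int(np.floor(maxy / delta1 + 1e-9))
    if ix1 < ix0 or iy1 < iy0:
        raise ValueError("delta1 exceeds the boundary extent; the grid is empty")
    ix = np.arange(ix0, ix1 + 1)
    iy = np.arange(iy0, iy1 + 1)
    gx, gy = np.meshgrid(ix, iy, indexing="ij")
    lattice = np.column_stack([gx.ravel(), gy.ravel()])
    world = lattice * delta1
    inside = shapely.intersects_xy(geom, world[:, 0], world[:, 1])
    if not inside.any():
        raise ValueError("no grid point falls inside the boundary; reduce delta1")
    lattice = lattice[inside]
    world = world[inside]
    lattice = lattice - [ix0, iy0]
    origin = (ix0 * delta1, iy0 * delta1)
    shape = (ix1 - ix0 + 1, iy1 - iy0 + 1)
    return Grid(world, float(delta1), origin, lattice, shape)
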