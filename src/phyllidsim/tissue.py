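"""Polygonal cell tissue: data model, adjacency, distance fields, polarity.

The tissue is a conforming tiling of simple polygons (cells) over shared
vertices.  Convention: y is the longitudinal organ axis (base at y = 0, apex
toward +y), x is mediolateral.  Lengths are in model micrometres, time in
days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

# Vertex constraint codes
CONSTRAINT_NONE = 0
CONSTRAINT_LONGITUDINAL = 1  # y fixed (Dirichlet along the organ axis), x free
CONSTRAINT_FIXED = 2         # fully fixed rigid-mode anchor

TISSUE_TYPES = ("apical", "blade", "midrib", "attachment")
ZONES = ("attachment", "proliferative", "differentiation")

GLOBAL_AXIS = np.array([0.0, 1.0])  # fallback polarity: organ axis, base->apex


class TissueStructureError(ValueError):
    """Raised when the cell/vertex structure violates a tiling invariant."""


@dataclass
class Vertex:
    id: int
    pos: np.ndarray  # shape (2,)
    is_base: bool = False
    constraint: int = CONSTRAINT_NONE


@dataclass
class Cell:
    id: int
    boundary: list  # ordered vertex ids, counter-clockwise
    merophyte_id: int = 0  # 0 = apical lineage (not yet a merophyte)
    tissue_type: str = "blade"
    zone: str = "proliferative"
    polarity: np.ndarray | None = None
    k_par: float = 0.0
    k_per: float = 0.0
    area_threshold: float = math.inf
    t_diff: float | None = None
    parent_id: int | None = None
    interior_vertices: list = field(default_factory=list)


@dataclass
class Element:
    """Three-node membrane finite element owned by one cell."""

    vids: tuple  # (v0, v1, v2)
    cell_id: int
    rest: np.ndarray  # (3, 2) rest-configuration node coordinates


@dataclass
class DistanceField:
    """Per-cell shortest-path distances from a source cell set."""

    values: dict  # cell id -> distance (math.inf if disconnected)
    flavor: str   # "cell-count" | "euclidean-wall-weight"
    sources: tuple


def polygon_area(pts: np.ndarray) -> float:
    """Signed shoelace area of a ring given as an (n, 2) array (CCW > 0)."""
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_centroid(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-300:
        return pts.mean(axis=0)
    cx = ((x + np.roll(x, -1)) * cross).sum() / (6.0 * a)
    cy = ((y + np.roll(y, -1)) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


class Tissue:
    """Full simulation state: vertices, cells, elements, time and phase."""

    def __init__(self):
        self.vertices: dict[int, Vertex] = {}
        self.cells: dict[int, Cell] = {}
        self.elements: list[Element] = []
        self.apical_cell_id: int | None = None
        self.time: float = 0.0
        self.phase: int = 1
        self.apical_division_side: str = "left"
        self.midrib_assigned: bool = False
        self.lineage: list[tuple[int, int]] = []  # (child, parent)
        self._next_vertex_id = 0
        self._next_cell_id = 0
        self.next_merophyte_id = 1
        self._adjacency: nx.Graph | None = None

    # ---------------------------------------------------------------- ids
    def new_vertex(self, pos, is_base=False, constraint=CONSTRAINT_NONE) -> int:
        vid = self._next_vertex_id
        self._next_vertex_id += 1
        self.vertices[vid] = Vertex(vid, np.asarray(pos, dtype=float),
                                    is_base, constraint)
        return vid

    def new_cell(self, boundary, **kw) -> int:
        cid = self._next_cell_id
        self._next_cell_id += 1
        self.cells[cid] = Cell(cid, list(boundary), **kw)
        self.invalidate()
        return cid

    def invalidate(self):
        self._adjacency = None

    # ----------------------------------------------------------- geometry
    def ring_coords(self, cid: int) -> np.ndarray:
        cell = self.cells[cid]
        return np.array([self.vertices[v].pos for v in cell.boundary])

    def cell_area(self, cid: int) -> float:
        return polygon_area(self.ring_coords(cid))

    def cell_centroid(self, cid: int) -> np.ndarray:
        return polygon_centroid(self.ring_coords(cid))

    def total_area(self) -> float:
        return sum(self.cell_area(c) for c in self.cells)

    def bounds(self):
        pts = np.array([v.pos for v in self.vertices.values()])
        return pts.min(axis=0), pts.max(axis=0)

    # ---------------------------------------------------------- adjacency
    def wall_map(self) -> dict:
        """Map of undirected wall segment (vid pair) -> list of owning cells."""
        walls: dict[tuple[int, int], list[int]] = {}
        for cid, cell in self.cells.items():
            ring = cell.boundary
            n = len(ring)
            for i in range(n):
                a, b = ring[i], ring[(i + 1) % n]
                key = (a, b) if a < b else (b, a)
                walls.setdefault(key, []).append(cid)
        return walls

    def build_adjacency(self) -> nx.Graph:
        """Cell-adjacency graph; edge weight = total shared-wall length.

        Two cells are adjacent iff they share at least one wall segment
        (consecutive vertex pair in both rings).  A wall claimed by more than
        two cells is a non-manifold structural error.
        """
        if self._adjacency is not None:
            return self._adjacency
        g = nx.Graph()
        g.add_nodes_from(self.cells)
        for (a, b), owners in self.wall_map().items():
            if len(owners) > 2:
                raise TissueStructureError(
                    f"wall ({a},{b}) shared by {len(owners)} cells: {owners}")
            if len(owners) == 2:
                length = float(np.linalg.norm(
                    self.vertices[a].pos - self.vertices[b].pos))
                c0, c1 = owners
                if g.has_edge(c0, c1):
                    g[c0][c1]["weight"] += length
                else:
                    g.add_edge(c0, c1, weight=length)
        self._adjacency = g
        return g

    # ------------------------------------------------------ distance field
    def distance_field(self, source_cells, flavor="cell-count") -> DistanceField:
        """Single-source shortest-path distances on the adjacency graph.

        flavor "cell-count" uses unit edge weights; "euclidean-wall-weight"
        uses centroid-to-centroid Euclidean distance between adjacent cells.
        Disconnected cells get infinite distance.
        """
        sources = tuple(sorted(source_cells))
        if not sources:
            raise ValueError("source_cells must be non-empty")
        g = self.build_adjacency()
        if flavor == "cell-count":
            wg = g
            weight = None
        elif flavor == "euclidean-wall-weight":
            wg = nx.Graph()
            wg.add_nodes_from(g.nodes)
            cent = {c: self.cell_centroid(c) for c in self.cells}
            for a, b in g.edges:
                wg.add_edge(a, b,
                            weight=float(np.linalg.norm(cent[a] - cent[b])))
            weight = "weight"
        else:
            raise ValueError(f"unknown distance flavor {flavor!r}")
        dist = nx.multi_source_dijkstra_path_length(wg, set(sources),
                                                    weight=weight)
        values = {c: dist.get(c, math.inf) for c in self.cells}
        return DistanceField(values, flavor, sources)

    # ---------------------------------------------------------- polarity
    def polarity_field(self, apical_distance: DistanceField | None = None) -> dict:
        """Per-cell unit polarity from the apical-cell distance field.

        Polarity is the negative normalized gradient of the distance field
        from the apical cell, so it points from base toward apex.  The
        gradient is estimated per cell by a least-squares linear fit of the
        distance values of the cell and its neighbors at their centroids.
        Cells with a degenerate neighborhood fall back to the organ axis.
        """
        if apical_distance is None:
            if self.apical_cell_id is None:
                raise ValueError("tissue has no apical cell")
            apical_distance = self.distance_field(
                [self.apical_cell_id], flavor="euclidean-wall-weight")
        g = self.build_adjacency()
        cent = {c: self.cell_centroid(c) for c in self.cells}
        out = {}
        for cid in self.cells:
            ids = [cid] + sorted(g.neighbors(cid))
            pts = np.array([cent[i] for i in ids])
            d = np.array([apical_distance.values[i] for i in ids])
            grad = _lstsq_gradient(pts, d)
            if grad is None:
                out[cid] = GLOBAL_AXIS.copy()
            else:
                out[cid] = -grad / np.linalg.norm(grad)
        return out

    # ------------------------------------------------------------- checks
    def validate(self):
        """Assert structural invariants (simple positive rings, manifoldness)."""
        for cid, cell in self.cells.items():
            pts = self.ring_coords(cid)
            if len(pts) < 3:
                raise TissueStructureError(f"cell {cid}: ring too short")
            if polygon_area(pts) <= 0:
                raise TissueStructureError(f"cell {cid}: non-positive area")
            if not _ring_is_simple(pts):
                raise TissueStructureError(f"cell {cid}: self-intersecting ring")
            if not np.all(np.isfinite(pts)):
                raise TissueStructureError(f"cell {cid}: non-finite vertex")
        self.build_adjacency()  # raises on non-manifold walls

    def copy(self) -> "Tissue":
        t = Tissue()
        t.vertices = {i: Vertex(v.id, v.pos.copy(), v.is_base, v.constraint)
                      for i, v in self.vertices.items()}
        t.cells = {}
        for i, c in self.cells.items():
            t.cells[i] = Cell(
                c.id, list(c.boundary), c.merophyte_id, c.tissue_type, c.zone,
                None if c.polarity is None else c.polarity.copy(),
                c.k_par, c.k_per, c.area_threshold, c.t_diff, c.parent_id,
                list(c.interior_vertices))
        t.elements = [Element(e.vids, e.cell_id, e.rest.copy())
                      for e in self.elements]
        t.apical_cell_id = self.apical_cell_id
        t.time = self.time
        t.phase = self.phase
        t.apical_division_side = self.apical_division_side
        t.midrib_assigned = self.midrib_assigned
        t.lineage = list(self.lineage)
        t._next_vertex_id = self._next_vertex_id
        t._next_cell_id = self._next_cell_id
        t.next_merophyte_id = self.next_merophyte_id
        return t


def _lstsq_gradient(pts: np.ndarray, values: np.ndarray):
    """Gradient of a least-squares linear fit value ~ a + g.x; None if degenerate."""
    if len(pts) < 3 or not np.all(np.isfinite(values)):
        return None
    A = np.column_stack([np.ones(len(pts)), pts])
    sol, _, rank, _ = np.linalg.lstsq(A, values, rcond=None)
    if rank < 3:
        return None
    g = sol[1:3]
    if np.linalg.norm(g) < 1e-12:
        return None
    return g


def _ring_is_simple(pts: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    # allow repeated collinear points; shapely treats those as valid
    return Polygon(pts).is_valid


# ------------------------------------------------------------------ meshing

def triangle_aspect_ratio(p0, p1, p2) -> float:
    """2*inradius/circumradius-style quality in (0, 1]; 1 for equilateral."""
    a = np.linalg.norm(p1 - p0)
    b = np.linalg.norm(p2 - p1)
    c = np.linalg.norm(p0 - p2)
    s = 0.5 * (a + b + c)
    area = abs(polygon_area(np.array([p0, p1, p2])))
    if s <= 0 or a * b * c == 0:
        return 0.0
    # ratio of inradius to circumradius, normalized so equilateral -> 1
    r = area / s
    R = a * b * c / (4.0 * area) if area > 0 else math.inf
    return 0.0 if not math.isfinite(R) or R == 0 else 2.0 * r / R


def triangulate_polygon(pts: np.ndarray):
    """Triangulate a simple CCW polygon without crossing its boundary.

    Returns (extra_points, triangles): triangles index into the ring
    (0..n-1) and then into extra_points (n, n+1, ...).  Star-shaped polygons
    (with respect to their centroid) get a centroid fan, which keeps triangle
    aspect ratios reasonable even when boundary edges carry many collinear
    points; other polygons are ear-clipped.
    """
    n = len(pts)
    if n < 3:
        raise ValueError("polygon with fewer than 3 vertices")
    if n == 3:
        return [], [(0, 1, 2)]
    c = polygon_centroid(pts)
    # centroid fan is valid iff every fan triangle is CCW with nonzero area
    fan_ok = True
    min_cross = math.inf
    for i in range(n):
        p, q = pts[i], pts[(i + 1) % n]
        cross = (p[0] - c[0]) * (q[1] - c[1]) - (p[1] - c[1]) * (q[0] - c[0])
        min_cross = min(min_cross, cross)
    scale = max(1e-300, float(np.abs(pts - c).max()) ** 2)
    if min_cross / scale < 1e-12:
        fan_ok = False
    if fan_ok:
        tris = []
        for i in range(n):
            j = (i + 1) % n
            # skip degenerate slivers from repeated points
            if np.linalg.norm(pts[i] - pts[j]) > 0:
                tris.append((i, j, n))
        return [c], tris
    return [], _ear_clip(pts)


def _ear_clip(pts: np.ndarray):
    n = len(pts)
    idx = list(range(n))
    tris = []
    guard = 0
    while len(idx) > 3 and guard < 10 * n * n:
        guard += 1
        clipped = False
        m = len(idx)
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            p0, p1, p2 = pts[i0], pts[i1], pts[i2]
            cross = (p1[0] - p0[0]) * (p2[1] - p0[1]) - \
                    (p1[1] - p0[1]) * (p2[0] - p0[0])
            if cross <= 1e-14 * max(1.0, float(np.abs(pts).max()) ** 2):
                continue  # reflex or degenerate corner
            if any(_point_in_tri(pts[j], p0, p1, p2)
                   for j in idx if j not in (i0, i1, i2)):
                continue
            tris.append((i0, i1, i2))
            idx.pop(k)
            clipped = True
            break
        if not clipped:
            # last resort: drop an exactly-collinear corner
            for k in range(len(idx)):
                i0, i1, i2 = idx[(k - 1) % len(idx)], idx[k], idx[(k + 1) % len(idx)]
                p0, p1, p2 = pts[i0], pts[i1], pts[i2]
                cross = (p1[0] - p0[0]) * (p2[1] - p0[1]) - \
                        (p1[1] - p0[1]) * (p2[0] - p0[0])
                if abs(cross) <= 1e-12 * max(1.0, float(np.abs(pts).max()) ** 2):
                    idx.pop(k)
                    clipped = True
                    break
            if not clipped:
                raise ValueError("ear clipping failed on degenerate polygon")
    if len(idx) == 3:
        tris.append(tuple(idx))
    return tris


def _point_in_tri(p, a, b, c, eps=1e-12) -> bool:
    d1 = (p[0] - b[0]) * (a[1] - b[1]) - (a[0] - b[0]) * (p[1] - b[1])
    d2 = (p[0] - c[0]) * (b[1] - c[1]) - (b[0] - c[0]) * (p[1] - c[1])
    d3 = (p[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (p[1] - a[1])
    neg = (d1 < -eps) or (d2 < -eps) or (d3 < -eps)
    pos = (d1 > eps) or (d2 > eps) or (d3 > eps)
    return not (neg and pos)


def triangulate_cell(tissue: Tissue, cid: int):
    """(Re)build the finite elements of one cell, rest = current shape.

    Discards any previous elements and interior nodes of the cell.  Element
    triangles exactly tile the cell polygon and never cross its boundary.
    """
    cell = tissue.cells[cid]
    # drop old elements and interior nodes
    tissue.elements = [e for e in tissue.elements if e.cell_id != cid]
    for vid in cell.interior_vertices:
        tissue.vertices.pop(vid, None)
    cell.interior_vertices = []

    pts = tissue.ring_coords(cid)
    if polygon_area(pts) <= 0:
        raise ValueError(f"triangulation failed for cell {cid}: "
                         f"degenerate (non-positive area) polygon")
    try:
        extra, tris = triangulate_polygon(pts)
    except ValueError as exc:
        raise ValueError(f"triangulation failed for cell {cid}: {exc}") from exc
    ring_ids = list(cell.boundary)
    extra_ids = [tissue.new_vertex(p) for p in extra]
    cell.interior_vertices = extra_ids
    all_ids = ring_ids + extra_ids
    area = 0.0
    for tri in tris:
        vids = tuple(all_ids[i] for i in tri)
        coords = np.array([tissue.vertices[v].pos for v in vids])
        a = polygon_area(coords)
        if a <= 0:
            continue
        area += a
        tissue.elements.append(Element(vids, cid, coords.copy()))
    poly_area = polygon_area(pts)
    if abs(area - poly_area) > 1e-9 * max(1.0, abs(poly_area)):
        raise ValueError(
            f"triangulation of cell {cid} does not tile polygon: "
            f"{area} vs {poly_area}")


def retriangulate(tissue: Tissue, cell_ids):
    for cid in cell_ids:
        triangulate_cell(tissue, cid)
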