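"""Two-dimensional polygonal cell network (vertex model).

Cells are simple polygons tiling a connected region of the plane; adjacent
cells share straight walls and the vertices at their ends.  Mechanics act on
vertices: every wall exerts an elastic force ``k_S * (l - l_0)`` along its
axis on both endpoints, and every cell presses outward on each of its walls
with magnitude ``k_P / V`` (V = cell area), applied perpendicular to the wall
at both endpoints.  Vertex positions follow the overdamped law
``du_i/dt = k_T * F_i`` integrated by forward Euler until the largest
per-step displacement drops below a threshold.

Growth happens by division of the largest cell along a random line through
its area centroid; the network is then re-relaxed, so the tissue expands by
turgor pressure as cells halve and push their neighbourhood outward.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi

from .errors import DegenerateGeometry, DivisionRetry
from ._kernels import relax_kernel

__all__ = [
    "MechParams",
    "Wall",
    "CellNetwork",
    "initial_network",
    "elastic_wall_force",
    "pressure_magnitude",
]

_EPS_T = 1e-9  # division line parameter tolerance for "hits a vertex"


@dataclass(frozen=True)
class MechParams:
    """Mechanical constants of the vertex model.

    Defaults are the study conditions: mobility ``k_T`` = 0.5, wall elastic
    constant ``k_S`` = 1.0, wall rest length ``l_0`` = 0.3, turgor constant
    ``k_P`` = 1.0, division interval ``T`` = 50.0 (one division per
    simulation cycle).  The relaxation controls are numerical choices:
    explicit Euler with step ``relax_dt``, stopping when the maximum vertex
    displacement in a step falls below ``relax_tol``; a per-step displacement
    cap ``relax_max_step`` keeps the explicit scheme stable when a fresh
    division creates a transiently tiny, high-pressure cell.
    """

    k_T: float = 0.5
    k_S: float = 1.0
    l_0: float = 0.3
    k_P: float = 1.0
    T: float = 50.0
    relax_tol: float = 1e-4
    relax_dt: float = 0.05
    relax_max_iter: int = 10_000
    relax_max_step: float = 0.05

    def __post_init__(self) -> None:
        for name in ("k_T", "k_S", "l_0", "k_P", "T", "relax_tol",
                     "relax_dt", "relax_max_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"MechParams.{name} must be positive")
        if self.relax_max_iter < 1:
            raise ValueError("relax_max_iter must be >= 1")


@dataclass(frozen=True)
class Wall:
    """A straight wall between two vertices, bordering one or two cells."""

    id: int
    vertices: tuple[int, int]          # sorted endpoint vertex ids
    cells: tuple[int, ...]             # one (boundary) or two adjacent cells

    @property
    def is_boundary(self) -> bool:
        return len(self.cells) == 1


@dataclass
class RelaxInfo:
    """Outcome of the last mechanical relaxation."""

    iterations: int
    converged: bool
    max_displacement: float


def elastic_wall_force(pos_a, pos_b, mech: MechParams) -> np.ndarray:
    """Elastic force a wall exerts on its endpoint at ``pos_a``.

    Restores the wall toward rest length: directed toward the other endpoint
    when the wall is stretched (l > l_0), away when compressed.
    """
    pos_a = np.asarray(pos_a, float)
    d = np.asarray(pos_b, float) - pos_a
    l = float(np.hypot(*d))
    if l < 1e-12:
        raise DegenerateGeometry("zero-length wall")
    return mech.k_S * (l - mech.l_0) * d / l


def pressure_magnitude(area: float, mech: MechParams) -> float:
    """Turgor pressure magnitude ``k_P / V`` a cell of area V exerts on each
    of its walls."""
    if area <= 0:
        raise DegenerateGeometry("non-positive cell area")
    return mech.k_P / area


class CellNetwork:
    """Polygonal cell tiling with shared walls and vertices.

    Cells are stored as counter-clockwise vertex cycles; walls and the
    cell-cell adjacency are derived from the cycles (and cached until the
    topology changes), so adjacency symmetry and marginality are always
    recomputable from structure alone.
    """

    def __init__(self) -> None:
        self.vertices: dict[int, np.ndarray] = {}
        self.cells: dict[int, list[int]] = {}
        self.last_relax: RelaxInfo | None = None
        self._next_vertex_id = 0
        self._next_cell_id = 0
        self._next_wall_id = 0
        self._wall_id_map: dict[tuple[int, int], int] = {}
        self._walls_cache: dict[int, Wall] | None = None
        self._geom_cache = None

    # ---------------------------------------------------------------- basics

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def cell_ids(self) -> list[int]:
        return sorted(self.cells)

    def add_vertex(self, x: float, y: float) -> int:
        vid = self._next_vertex_id
        self._next_vertex_id += 1
        self.vertices[vid] = np.array([x, y], float)
        return vid

    def add_cell(self, vertex_cycle: list[int]) -> int:
        cid = self._next_cell_id
        self._next_cell_id += 1
        self.cells[cid] = list(vertex_cycle)
        self._invalidate()
        return cid

    def _invalidate(self) -> None:
        self._walls_cache = None
        self._geom_cache = None

    # ----------------------------------------------------------------- walls

    @property
    def walls(self) -> dict[int, Wall]:
        """Wall table derived from the cell cycles; ids persist across
        rebuilds for endpoint pairs that survive."""
        if self._walls_cache is None:
            adj: dict[tuple[int, int], list[int]] = {}
            for cid, cyc in self.cells.items():
                m = len(cyc)
                for k in range(m):
                    a, b = cyc[k], cyc[(k + 1) % m]
                    key = (a, b) if a < b else (b, a)
                    adj.setdefault(key, []).append(cid)
            walls: dict[int, Wall] = {}
            for key, cids in adj.items():
                if key not in self._wall_id_map:
                    self._wall_id_map[key] = self._next_wall_id
                    self._next_wall_id += 1
                wid = self._wall_id_map[key]
                walls[wid] = Wall(wid, key, tuple(sorted(cids)))
            self._walls_cache = walls
        return self._walls_cache

    def wall_length(self, wall_id: int) -> float:
        a, b = self.walls[wall_id].vertices
        return float(np.hypot(*(self.vertices[a] - self.vertices[b])))

    def cell_walls(self, cell_id: int) -> list[int]:
        """Wall ids of a cell, in cycle order."""
        cyc = self._cycle(cell_id)
        pair_to_id = {w.vertices: w.id for w in self.walls.values()}
        out = []
        m = len(cyc)
        for k in range(m):
            a, b = cyc[k], cyc[(k + 1) % m]
            out.append(pair_to_id[(a, b) if a < b else (b, a)])
        return out

    def _cycle(self, cell_id: int) -> list[int]:
        try:
            return self.cells[cell_id]
        except KeyError:
            raise KeyError(f"no cell with id {cell_id}") from None

    # -------------------------------------------------------------- geometry

    def cell_polygon(self, cell_id: int) -> np.ndarray:
        """(m, 2) vertex coordinates of the cell, in cycle order."""
        return np.array([self.vertices[v] for v in self._cycle(cell_id)])

    def cell_area(self, cell_id: int) -> float:
        """Shoelace area of the (counter-clockwise) cell polygon."""
        p = self.cell_polygon(cell_id)
        x, y = p[:, 0], p[:, 1]
        a = 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
        if a <= 0:
            raise DegenerateGeometry(
                f"cell {cell_id} has non-positive signed area {a}")
        return a

    def cell_centroid(self, cell_id: int) -> np.ndarray:
        """Area centroid (gravity centre) of the cell polygon."""
        p = self.cell_polygon(cell_id)
        q = np.roll(p, -1, axis=0)
        cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
        a = 0.5 * cross.sum()
        if abs(a) < 1e-300:
            return p.mean(axis=0)
        cx = ((p[:, 0] + q[:, 0]) * cross).sum() / (6 * a)
        cy = ((p[:, 1] + q[:, 1]) * cross).sum() / (6 * a)
        return np.array([cx, cy])

    def largest_cell(self) -> int:
        """Id of the maximum-area cell; ties go to the smallest id."""
        if not self.cells:
            raise ValueError("empty network")
        best_id, best_area = -1, -math.inf
        for cid in sorted(self.cells):
            a = self.cell_area(cid)
            if a > best_area:
                best_id, best_area = cid, a
        return best_id

    def network_centroid(self) -> np.ndarray:
        """Area-weighted centroid of the whole tiling."""
        tot, acc = 0.0, np.zeros(2)
        for cid in self.cells:
            a = self.cell_area(cid)
            acc += a * self.cell_centroid(cid)
            tot += a
        return acc / tot

    # ------------------------------------------------------------- adjacency

    def neighbors(self, cell_id: int) -> set[int]:
        """Cells sharing at least one wall with ``cell_id``."""
        self._cycle(cell_id)
        out: set[int] = set()
        for w in self.walls.values():
            if cell_id in w.cells:
                out.update(w.cells)
        out.discard(cell_id)
        return out

    def is_marginal(self, cell_id: int) -> bool:
        """True iff the cell has a wall on the network boundary."""
        self._cycle(cell_id)
        return any(cell_id in w.cells and w.is_boundary
                   for w in self.walls.values())

    def adjacency_edges(self) -> list[tuple[int, int]]:
        """Unordered cell-id pairs sharing a wall (each pair once)."""
        return sorted({w.cells for w in self.walls.values()
                       if len(w.cells) == 2})

    # -------------------------------------------------------------- division

    def divide_cell(self, cell_id: int, angle: float) -> tuple[int, int]:
        """Split a cell by the straight line through its area centroid at
        ``angle`` (radians).

        Two new vertices are inserted where the line crosses the cell outline
        (the neighbouring cells' cycles are updated to include them), the
        mother cell is replaced by two counter-clockwise daughters separated
        by a new straight wall, and the two daughter ids are returned.

        Raises :class:`DivisionRetry` when the line grazes an existing vertex
        or does not cross the outline in exactly two points (strongly
        non-convex cell), so the caller can redraw the angle.
        """
        cyc = self._cycle(cell_id)
        m = len(cyc)
        c = self.cell_centroid(cell_id)
        d = np.array([math.cos(angle), math.sin(angle)])
        hits: list[tuple[int, float, np.ndarray]] = []
        for k in range(m):
            A = self.vertices[cyc[k]]
            B = self.vertices[cyc[(k + 1) % m]]
            e = B - A
            denom = e[0] * d[1] - e[1] * d[0]
            if abs(denom) < 1e-14:
                continue
            t = -((A[0] - c[0]) * d[1] - (A[1] - c[1]) * d[0]) / denom
            if -_EPS_T < t < _EPS_T or 1 - _EPS_T < t < 1 + _EPS_T:
                raise DivisionRetry("division line passes through a vertex")
            if 0.0 < t < 1.0:
                hits.append((k, t, A + t * e))
        if len(hits) != 2:
            raise DivisionRetry(
                f"division line crosses the outline {len(hits)} times")
        (k1, _, p1), (k2, _, p2) = hits
        n1 = self.add_vertex(*p1)
        n2 = self.add_vertex(*p2)

        # insert the new vertex into the neighbour sharing each split edge
        for k, nv in ((k1, n1), (k2, n2)):
            a, b = cyc[k], cyc[(k + 1) % m]
            self._insert_in_neighbor(cell_id, a, b, nv)

        # daughter cycles (both counter-clockwise, new wall n1-n2 shared)
        def arc(i: int, j: int) -> list[int]:
            out, k = [], i
            while True:
                out.append(cyc[k])
                if k == j:
                    return out
                k = (k + 1) % m

        cyc_a = [n1] + arc((k1 + 1) % m, k2) + [n2]
        cyc_b = [n2] + arc((k2 + 1) % m, k1) + [n1]
        del self.cells[cell_id]
        ida = self.add_cell(cyc_a)
        idb = self.add_cell(cyc_b)
        return ida, idb

    def _insert_in_neighbor(self, cell_id: int, a: int, b: int,
                            new_vertex: int) -> None:
        key = (a, b) if a < b else (b, a)
        for cid, cyc in self.cells.items():
            if cid == cell_id:
                continue
            n = len(cyc)
            for i in range(n):
                p, q = cyc[i], cyc[(i + 1) % n]
                kk = (p, q) if p < q else (q, p)
                if kk == key:
                    cyc.insert(i + 1, new_vertex)
                    return

    # -------------------------------------------------------------- mechanics

    def vertex_force(self, vertex_id: int, mech: MechParams) -> np.ndarray:
        """Total force on a vertex: elastic pulls of its walls plus the
        turgor pressure of every cell adjacent to those walls.

        Pressure from a cell of area V acts with magnitude ``k_P / V``
        perpendicular to the wall, outward from the cell, on both wall
        endpoints (unweighted by wall length).
        """
        if vertex_id not in self.vertices:
            raise KeyError(f"no vertex with id {vertex_id}")
        F = np.zeros(2)
        areas = {}
        for w in self.walls.values():
            if vertex_id not in w.vertices:
                continue
            a, b = w.vertices
            other = b if a == vertex_id else a
            F += elastic_wall_force(self.vertices[vertex_id],
                                    self.vertices[other], mech)
            pa, pb = self.vertices[a], self.vertices[b]
            dw = pb - pa
            l = float(np.hypot(*dw))
            if l < 1e-12:
                raise DegenerateGeometry(f"zero-length wall {w.id}")
            nhat = np.array([dw[1], -dw[0]]) / l
            for cid in w.cells:
                if cid not in areas:
                    areas[cid] = self.cell_area(cid)
                # for a counter-clockwise cycle, the directed edge rotated
                # by -90 degrees points outward; exact for any cell shape
                cyc = self.cells[cid]
                forward = any(p == a and q == b
                              for p, q in zip(cyc, cyc[1:] + cyc[:1]))
                nh = nhat if forward else -nhat
                F += pressure_magnitude(areas[cid], mech) * nh
        return F

    def rigid_drift_forces(self, mech: MechParams) -> dict[int, np.ndarray]:
        """Rigid-body (translation + rotation) component of the force field.

        Unweighted per-wall pressure leaves a small net force and torque on
        the whole tissue that change no length or area; relaxation projects
        these zero modes out, so mechanical equilibrium means
        ``vertex_force(v) - rigid_drift_forces()[v]`` vanishes, not
        ``vertex_force(v)`` itself.
        """
        vids = sorted(self.vertices)
        F = np.array([self.vertex_force(v, mech) for v in vids])
        pos = np.array([self.vertices[v] for v in vids])
        F0 = F.mean(axis=0)
        r = pos - pos.mean(axis=0)
        Fc = F - F0
        omega = float((r[:, 0] * Fc[:, 1] - r[:, 1] * Fc[:, 0]).sum()
                      / (r * r).sum())
        rot = omega * np.column_stack([-r[:, 1], r[:, 0]])
        return {v: F0 + rot[i] for i, v in enumerate(vids)}

    def _compiled(self):
        """Flat array view of the topology for the numba kernels."""
        if self._geom_cache is None:
            vids = sorted(self.vertices)
            vindex = {v: i for i, v in enumerate(vids)}
            cids = self.cell_ids()
            cindex = {c: i for i, c in enumerate(cids)}
            walls = sorted(self.walls.values(), key=lambda w: w.id)
            wv1 = np.array([vindex[w.vertices[0]] for w in walls], np.int64)
            wv2 = np.array([vindex[w.vertices[1]] for w in walls], np.int64)
            # ss: +1 when the wall's (v1 -> v2) direction follows the cell's
            # counter-clockwise cycle, -1 otherwise; rotating the directed
            # edge by -90 degrees then gives the exact outward normal
            # regardless of cell shape
            forward = {}
            for cid in cids:
                cyc = self.cells[cid]
                for a, b in zip(cyc, cyc[1:] + cyc[:1]):
                    forward[(cid, a, b)] = True
            sw, sc, ss = [], [], []
            for i, w in enumerate(walls):
                a, b = w.vertices
                for cid in w.cells:
                    sw.append(i)
                    sc.append(cindex[cid])
                    ss.append(1.0 if (cid, a, b) in forward else -1.0)
            sw = np.array(sw, np.int64)
            sc = np.array(sc, np.int64)
            ss = np.array(ss, float)
            flat, off = [], [0]
            for cid in cids:
                flat.extend(vindex[v] for v in self.cells[cid])
                off.append(len(flat))
            self._geom_cache = (vids, cids, wv1, wv2, sw, sc, ss,
                                np.array(flat, np.int64),
                                np.array(off, np.int64))
        return self._geom_cache

    def positions_array(self):
        vids, *_ = self._compiled()
        return np.array([self.vertices[v] for v in vids])

    def relax(self, mech: MechParams) -> "CellNetwork":
        """Forward-Euler relaxation of all vertex positions toward mechanical
        equilibrium; stops when the largest per-step displacement is below
        ``mech.relax_tol`` or after ``mech.relax_max_iter`` steps (recorded in
        :attr:`last_relax`, non-convergence is not an error)."""
        vids, cids, wv1, wv2, sw, sc, ss, flat, off = self._compiled()
        pos = self.positions_array()
        niter, maxdisp = relax_kernel(
            pos, wv1, wv2, sw, sc, ss, flat, off,
            mech.k_T, mech.k_S, mech.l_0, mech.k_P,
            mech.relax_dt, mech.relax_tol, mech.relax_max_iter,
            mech.relax_max_step)
        for i, v in enumerate(vids):
            self.vertices[v] = pos[i].copy()
        self.last_relax = RelaxInfo(int(niter), maxdisp < mech.relax_tol,
                                    float(maxdisp))
        # orientation audit: relaxation must not fold any polygon
        for cid in cids:
            self.cell_area(cid)
        return self

    # ------------------------------------------------------------- integrity

    def validate(self) -> None:
        """Structure audit; raises ValueError on any violated invariant."""
        for vid, p in self.vertices.items():
            if not np.all(np.isfinite(p)):
                raise ValueError(f"vertex {vid} has non-finite position")
        used = set()
        for cid, cyc in self.cells.items():
            if len(cyc) < 3:
                raise ValueError(f"cell {cid} has fewer than 3 vertices")
            if len(set(cyc)) != len(cyc):
                raise ValueError(f"cell {cid} repeats a vertex")
            used.update(cyc)
            self.cell_area(cid)  # positive, CCW
            from shapely.geometry import Polygon
            if not Polygon(self.cell_polygon(cid)).is_valid:
                raise ValueError(f"cell {cid} is not a simple polygon")
        if used != set(self.vertices):
            raise ValueError("dangling vertices present")
        for w in self.walls.values():
            if not 1 <= len(w.cells) <= 2:
                raise ValueError(f"wall {w.id} borders {len(w.cells)} cells")
            if w.vertices[0] == w.vertices[1]:
                raise ValueError(f"wall {w.id} is a loop")
        # Euler characteristic of a connected planar subdivision
        V, E, C = len(self.vertices), len(self.walls), len(self.cells)
        if V - E + (C + 1) != 2:
            raise ValueError(
                f"Euler characteristic violated: V={V} E={E} F={C + 1}")

    # ------------------------------------------------------------------- io

    def to_json(self) -> str:
        doc = {
            "vertices": [{"id": v, "x": float(p[0]), "y": float(p[1])}
                         for v, p in sorted(self.vertices.items())],
            "walls": [{"id": w.id, "v1": w.vertices[0], "v2": w.vertices[1],
                       "cells": list(w.cells)}
                      for w in sorted(self.walls.values(), key=lambda w: w.id)],
            "cells": [{"id": c, "vertices": list(cyc),
                       "walls": self.cell_walls(c)}
                      for c, cyc in sorted(self.cells.items())],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CellNetwork":
        doc = json.loads(text)
        net = cls()
        for v in doc["vertices"]:
            net.vertices[v["id"]] = np.array([v["x"], v["y"]], float)
        net._next_vertex_id = 1 + max((v["id"] for v in doc["vertices"]),
                                      default=-1)
        for c in doc["cells"]:
            net.cells[c["id"]] = list(c["vertices"])
        net._next_cell_id = 1 + max((c["id"] for c in doc["cells"]),
                                    default=-1)
        for w in doc["walls"]:
            key = tuple(sorted((w["v1"], w["v2"])))
            net._wall_id_map[key] = w["id"]
        net._next_wall_id = 1 + max((w["id"] for w in doc["walls"]),
                                    default=-1)
        return net


# -------------------------------------------------------------- construction


def initial_network(n_cells: int, seed: int,
                    mech: MechParams | None = None) -> CellNetwork:
    """Seeded initial tissue of ``n_cells`` cells, mechanically relaxed.

    Cells are the Voronoi regions of points drawn uniformly in the unit
    disk; reflecting each point across the disk boundary (plus a far ghost
    ring) bounds the tiling so that boundary walls are genuine Voronoi
    ridges and all shared walls/vertices are exactly consistent.  A few
    Lloyd iterations (points moved to their cell centroids) regularize the
    tiling so no sliver cells reach the mechanical relaxation.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    mech = mech or MechParams()
    net = CellNetwork()
    if n_cells == 1:
        r = 0.6
        verts = [net.add_vertex(r * math.cos(a), r * math.sin(a))
                 for a in np.linspace(0, 2 * math.pi, 7)[:-1]]
        net.add_cell(verts)
        net.relax(mech)
        return net

    rng = np.random.default_rng(seed)
    pts = np.empty((n_cells, 2))
    for i in range(n_cells):
        while True:
            p = rng.uniform(-1, 1, 2)
            r = np.hypot(*p)
            if 0.05 < r < 0.95:
                # min spacing keeps the Voronoi construction non-degenerate
                if i == 0 or np.min(np.hypot(*(pts[:i] - p).T)) > 0.3 / math.sqrt(n_cells):
                    pts[i] = p
                    break

    vor = None
    for _ in range(4):  # Lloyd iterations, then one final tessellation
        radii = np.hypot(pts[:, 0], pts[:, 1])
        mirrors = pts / radii[:, None] * (2 - radii)[:, None]
        ring = 3.0 * np.column_stack(
            [np.cos(np.linspace(0, 2 * math.pi, 17)[:-1]),
             np.sin(np.linspace(0, 2 * math.pi, 17)[:-1])])
        vor = Voronoi(np.vstack([pts, mirrors, ring]))
        new_pts = np.empty_like(pts)
        for i in range(n_cells):
            region = vor.regions[vor.point_region[i]]
            if -1 in region or len(region) < 3:
                raise RuntimeError("unbounded Voronoi region in initial tiling")
            poly = vor.vertices[sorted(
                region, key=lambda vi: math.atan2(
                    vor.vertices[vi][1] - pts[i, 1],
                    vor.vertices[vi][0] - pts[i, 0]))]
            x, y = poly[:, 0], poly[:, 1]
            cross = x * np.roll(y, -1) - np.roll(x, -1) * y
            a = 0.5 * cross.sum()
            new_pts[i, 0] = ((x + np.roll(x, -1)) * cross).sum() / (6 * a)
            new_pts[i, 1] = ((y + np.roll(y, -1)) * cross).sum() / (6 * a)
        # keep centroids inside the sampling annulus of the disk
        r = np.hypot(new_pts[:, 0], new_pts[:, 1])
        clip = np.clip(r, 0.05, 0.95)
        pts = new_pts * (clip / np.maximum(r, 1e-12))[:, None]
    vmap: dict[int, int] = {}
    for i in range(n_cells):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise RuntimeError("unbounded Voronoi region in initial tiling")
        for vi in region:
            if vi not in vmap:
                vmap[vi] = net.add_vertex(*vor.vertices[vi])
        # Voronoi cells are convex, so sorting by angle around the
        # generating point yields the simple counter-clockwise cycle
        # (scipy does not guarantee any vertex order within a region)
        region = sorted(region, key=lambda vi: math.atan2(
            vor.vertices[vi][1] - pts[i, 1], vor.vertices[vi][0] - pts[i, 0]))
        net.add_cell([vmap[vi] for vi in region])
    net.validate()
    net.relax(mech)
    return net
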