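"""Finite-volume discretization of an allocated landscape.

The square extent is covered by a uniform Cartesian grid of cells; each
cell belongs to the polygon containing its centre.  Hedge-labelled edges
are discretized into 1D control volumes (cell-centred along each segment)
that form a network: segments sharing an endpoint are coupled through a
junction condition (value continuity, flux balance), so predator diffusion
applies continuously across hedge junctions.

Two graph Laplacians are assembled: one on all interior faces (pest — no
edge is a barrier) and one with the faces crossed by hedges removed
(predator — a hedge interrupts direct field-to-field movement; transfer
through the hedge happens via the migration exchange).  Both are exactly
mass-conservative with reflecting exterior boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from shapely import STRtree
from shapely.geometry import Point, box

from .landscape import LandscapeAllocation, Tessellation

__all__ = ["Mesh", "build_mesh"]


@dataclass
class Mesh:
    """Coupled 2D-grid / 1D-hedge-network finite-volume mesh."""

    extent: float
    nx: int
    h: float
    cell_polygon: np.ndarray  # (n_cells,) polygon index per cell
    crop_cell: np.ndarray  # (n_cells,) bool (majority crop cover)
    crop_polygon: np.ndarray  # (n_polygons,) bool
    poly_cells: list  # list of int arrays, cells per polygon (by centre)
    cell_crop_frac: np.ndarray  # (n_cells,) crop area fraction of the cell
    poly_weights: sp.csr_matrix  # (n_polygons, n_cells) cell-polygon areas
    lap2d_pest: sp.csr_matrix  # du/dt = D * lap2d @ u (1/h^2 included)
    lap2d_pred: sp.csr_matrix
    # 1D hedge network
    hnode_pos: np.ndarray  # (n_h, 2)
    hnode_len: np.ndarray  # (n_h,) control length (km)
    hnode_edge: np.ndarray  # (n_h,) tessellation edge index
    lap1d: sp.csr_matrix  # dv/dt = D1v * lap1d @ v
    # interface exchange bookkeeping: one entry per (hedge node, bordering cell)
    if_node: np.ndarray
    if_cell: np.ndarray
    if_cell2: np.ndarray  # next cell outward along the normal (trace extrapolation)
    if_nsides: np.ndarray  # sides of the node's segment that found a cell

    @property
    def n_cells(self) -> int:
        return self.nx * self.nx

    @property
    def n_hedge_nodes(self) -> int:
        return len(self.hnode_len)

    @property
    def cell_area(self) -> float:
        return self.h * self.h

    def cell_centroids(self) -> np.ndarray:
        idx = np.arange(self.n_cells)
        i, j = idx % self.nx, idx // self.nx
        return np.column_stack(((i + 0.5) * self.h, (j + 0.5) * self.h))

    def polygon_areas(self) -> np.ndarray:
        if not hasattr(self, "_areas"):
            self._areas = np.asarray(self.poly_weights.sum(axis=1)).ravel()
        return self._areas

    def polygon_means(self, values: np.ndarray) -> np.ndarray:
        """Area-weighted mean of a cell field over every polygon."""
        areas = self.polygon_areas()
        out = self.poly_weights @ values
        np.divide(out, areas, out=out, where=areas > 0)
        return out

    def polygon_mean(self, values: np.ndarray, i: int) -> float:
        return float(self.polygon_means(values)[i])


def _grid_faces(nx: int) -> np.ndarray:
    """Interior faces of an nx*nx grid as (cell_a, cell_b) index pairs."""
    idx = np.arange(nx * nx).reshape(nx, nx)  # idx[j, i] with j = y row
    vert = np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
    horiz = np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()])
    return np.vstack([vert, horiz])


def _graph_laplacian(faces: np.ndarray, n: int, scale: float) -> sp.csr_matrix:
    """Symmetric conservative Laplacian from unit-conductance faces."""
    if len(faces) == 0:
        return sp.csr_matrix((n, n))
    a, b = faces[:, 0], faces[:, 1]
    rows = np.concatenate([a, b, a, b])
    cols = np.concatenate([b, a, a, b])
    data = np.concatenate(
        [np.ones(len(a)), np.ones(len(a)), -np.ones(len(a)), -np.ones(len(a))]
    )
    return sp.csr_matrix((data * scale, (rows, cols)), shape=(n, n))


def build_mesh(
    tess: Tessellation, alloc: LandscapeAllocation, resolution: float
) -> Mesh:
    """Discretize a landscape at a target cell diameter (km)."""
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    for i, p in enumerate(tess.polygons):
        if p.area <= 0 or not p.is_valid:
            raise ValueError(f"degenerate polygon {i} (area {p.area})")

    extent = tess.extent
    nx = max(2, int(round(extent / resolution)))
    h = extent / nx
    n_cells = nx * nx

    idx = np.arange(n_cells)
    ci, cj = idx % nx, idx // nx
    centers = np.column_stack(((ci + 0.5) * h, (cj + 0.5) * h))

    tree = STRtree(tess.polygons)
    cell_polygon = np.empty(n_cells, dtype=int)
    pts = [Point(x, y) for x, y in centers]
    hits = tree.query(pts, predicate="within")
    cell_polygon[:] = -1
    cell_polygon[hits[0]] = hits[1]
    missing = np.flatnonzero(cell_polygon < 0)
    for k in missing:  # centre exactly on a border: take nearest polygon
        cell_polygon[k] = tree.nearest(pts[k])

    crop_polygon = np.asarray(alloc.crop_label, dtype=bool)
    poly_cells = [
        np.flatnonzero(cell_polygon == i) for i in range(tess.n_polygons)
    ]

    # exact cell-polygon intersection areas: field means and the
    # crop/non-crop reaction blend are then O(h^2) accurate at borders
    poly_weights = _intersection_weights(tess, nx, h, cell_polygon)
    crop_area = np.asarray(
        poly_weights[np.flatnonzero(crop_polygon)].sum(axis=0)
    ).ravel()
    cell_crop_frac = np.clip(crop_area / (h * h), 0.0, 1.0)
    crop_cell = cell_crop_frac > 0.5

    # --- 2D Laplacians ----------------------------------------------------
    faces = _grid_faces(nx)
    blocked = _blocked_faces(tess, alloc, nx, h)
    lap2d_pest = _graph_laplacian(faces, n_cells, 1.0 / h**2)
    if blocked:
        keep = np.array(
            [tuple(f) not in blocked for f in np.sort(faces, axis=1)], dtype=bool
        )
        faces_pred = faces[keep]
    else:
        faces_pred = faces
    lap2d_pred = _graph_laplacian(faces_pred, n_cells, 1.0 / h**2)

    # --- 1D hedge network -------------------------------------------------
    (hnode_pos, hnode_len, hnode_edge, lap1d) = _hedge_network(tess, alloc, h)

    # --- hedge <-> field interface map ------------------------------------
    if_node, if_cell, if_cell2, if_nsides = _interface_map(
        tess, hnode_pos, hnode_edge, nx, h
    )

    return Mesh(
        extent=extent,
        nx=nx,
        h=h,
        cell_polygon=cell_polygon,
        crop_cell=crop_cell,
        crop_polygon=crop_polygon,
        poly_cells=poly_cells,
        cell_crop_frac=cell_crop_frac,
        poly_weights=poly_weights,
        lap2d_pest=lap2d_pest,
        lap2d_pred=lap2d_pred,
        hnode_pos=hnode_pos,
        hnode_len=hnode_len,
        hnode_edge=hnode_edge,
        lap1d=lap1d,
        if_node=if_node,
        if_cell=if_cell,
        if_cell2=if_cell2,
        if_nsides=if_nsides,
    )


def _intersection_weights(
    tess: Tessellation, nx: int, h: float, cell_polygon: np.ndarray
) -> sp.csr_matrix:
    """Sparse (n_polygons, n_cells) matrix of cell-polygon overlap areas."""
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    cell_area = h * h
    for i, poly in enumerate(tess.polygons):
        minx, miny, maxx, maxy = poly.bounds
        i0, i1 = max(0, int(minx // h)), min(nx - 1, int(np.ceil(maxx / h)) )
        j0, j1 = max(0, int(miny // h)), min(nx - 1, int(np.ceil(maxy / h)) )
        for j in range(j0, j1 + 1):
            for ic in range(i0, i1 + 1):
                c = j * nx + ic
                x0, y0 = ic * h, j * h
                cell = box(x0, y0, x0 + h, y0 + h)
                if poly.contains(cell):
                    a = cell_area
                else:
                    a = poly.intersection(cell).area
                if a > 1e-12 * cell_area:
                    rows.append(i)
                    cols.append(c)
                    data.append(a)
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(tess.n_polygons, nx * nx)
    )


def _segment_normal(p0, p1) -> np.ndarray:
    d = np.array([p1[0] - p0[0], p1[1] - p0[1]])
    n = np.array([-d[1], d[0]])
    return n / np.linalg.norm(n)


def _blocked_faces(
    tess: Tessellation, alloc: LandscapeAllocation, nx: int, h: float
) -> set[tuple[int, int]]:
    """Grid faces crossed by hedge segments (predator barriers).

    Hedge segments are sampled at half-cell spacing; each sample probes a
    half-cell on either side of the segment and, when the probes land in
    4-neighbouring cells, the face between them is blocked.  A face is only
    blocked where the hedge actually overlaps it, so short hedges leave the
    rest of the border permeable.
    """
    blocked: set[tuple[int, int]] = set()

    def cell_of(x: float, y: float) -> int | None:
        i, j = int(x // h), int(y // h)
        if 0 <= i < nx and 0 <= j < nx:
            return j * nx + i
        return None

    for k, edge in enumerate(tess.edges):
        if not alloc.hedge_label[k]:
            continue
        (x0, y0), (x1, y1) = edge.coords[0], edge.coords[-1]
        length = edge.length
        nrm = _segment_normal((x0, y0), (x1, y1))
        n_samp = max(2, int(np.ceil(length / (h / 2))) + 1)
        for t in np.linspace(0.0, 1.0, n_samp):
            qx, qy = x0 + t * (x1 - x0), y0 + t * (y1 - y0)
            a = cell_of(qx + 0.5 * h * nrm[0], qy + 0.5 * h * nrm[1])
            b = cell_of(qx - 0.5 * h * nrm[0], qy - 0.5 * h * nrm[1])
            if a is None or b is None or a == b:
                continue
            ia, ja, ib, jb = a % nx, a // nx, b % nx, b // nx
            if abs(ia - ib) + abs(ja - jb) == 1:
                blocked.add((min(a, b), max(a, b)))
    return blocked


def _hedge_network(tess: Tessellation, alloc: LandscapeAllocation, h: float):
    """Cell-centred 1D control volumes along hedges + junction coupling."""
    hnode_pos: list[tuple[float, float]] = []
    hnode_len: list[float] = []
    hnode_edge: list[int] = []
    # terminal node bookkeeping per rounded endpoint for junction coupling
    endpoint_terms: dict[tuple[float, float], list[tuple[int, float]]] = {}
    chain_pairs: list[tuple[int, int, float]] = []  # (i, j, distance)

    for k, edge in enumerate(tess.edges):
        if not alloc.hedge_label[k]:
            continue
        (x0, y0), (x1, y1) = edge.coords[0], edge.coords[-1]
        length = edge.length
        m = max(1, int(round(length / h)))
        d = length / m
        base = len(hnode_pos)
        for s in range(m):
            t = (s + 0.5) / m
            hnode_pos.append((x0 + t * (x1 - x0), y0 + t * (y1 - y0)))
            hnode_len.append(d)
            hnode_edge.append(k)
            if s > 0:
                chain_pairs.append((base + s - 1, base + s, d))
        key0 = (round(x0, 9), round(y0, 9))
        key1 = (round(x1, 9), round(y1, 9))
        endpoint_terms.setdefault(key0, []).append((base, d / 2))
        endpoint_terms.setdefault(key1, []).append((base + m - 1, d / 2))

    n_h = len(hnode_pos)
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []

    def add_conductance(i: int, j: int, c: float) -> None:
        # flux between control volumes i, j with conductance c; the change
        # of the per-length density divides by the control length
        li, lj = hnode_len[i], hnode_len[j]
        rows.extend([i, i, j, j])
        cols.extend([j, i, i, j])
        data.extend([c / li, -c / li, c / lj, -c / lj])

    for i, j, d in chain_pairs:
        add_conductance(i, j, 1.0 / d)
    for _, terms in endpoint_terms.items():
        if len(terms) < 2:
            continue  # dead end: reflecting
        # junction value eliminated under flux balance -> star of
        # pairwise conductances g_i g_j / sum(g)
        g = [1.0 / a for _, a in terms]
        gtot = sum(g)
        for a in range(len(terms)):
            for b in range(a + 1, len(terms)):
                add_conductance(terms[a][0], terms[b][0], g[a] * g[b] / gtot)

    lap1d = (
        sp.csr_matrix((data, (rows, cols)), shape=(n_h, n_h))
        if n_h
        else sp.csr_matrix((0, 0))
    )
    return (
        np.array(hnode_pos).reshape(n_h, 2),
        np.array(hnode_len),
        np.array(hnode_edge, dtype=int),
        lap1d,
    )


def _interface_map(tess, hnode_pos, hnode_edge, nx: int, h: float):
    """Bordering 2D cell (and the next cell outward) per hedge node side.

    The second cell allows a linear extrapolation of the predator density
    to the hedge line, which removes the leading O(h) bias of reading the
    strip-cell average in the migration exchange.
    """
    if_node: list[int] = []
    if_cell: list[int] = []
    if_cell2: list[int] = []
    nsides = np.zeros(len(hnode_pos), dtype=int)

    def cell_of(x: float, y: float) -> int | None:
        i, j = int(x // h), int(y // h)
        if 0 <= i < nx and 0 <= j < nx:
            return j * nx + i
        return None

    for n, (px, py) in enumerate(hnode_pos):
        edge = tess.edges[hnode_edge[n]]
        nrm = _segment_normal(edge.coords[0], edge.coords[-1])
        found: list[tuple[int, int]] = []
        for sgn in (1.0, -1.0):
            c = cell_of(px + sgn * 0.5 * h * nrm[0], py + sgn * 0.5 * h * nrm[1])
            if c is None or any(c == f[0] for f in found):
                continue
            c2 = cell_of(px + sgn * 1.5 * h * nrm[0], py + sgn * 1.5 * h * nrm[1])
            found.append((c, c2 if c2 is not None else c))
        nsides[n] = len(found)
        for c, c2 in found:
            if_node.append(n)
            if_cell.append(c)
            if_cell2.append(c2)

    return (
        np.array(if_node, dtype=int),
        np.array(if_cell, dtype=int),
        np.array(if_cell2, dtype=int),
        nsides,
    )
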