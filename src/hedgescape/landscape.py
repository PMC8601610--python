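"""Stochastic agricultural landscape model.

A landscape is a planar T-tessellation of a square extent: polygons are
fields, line-segment edges are field borders.  Land cover is allocated by
thresholding a pair of correlated Gaussian random fields (GRFs) with
exponential correlation, one field evaluated at polygon representative
points (crop / non-crop) and one at edge representative points (hedge /
no-hedge).  The correlation range ``phi`` controls spatial aggregation of
the allocation; ``rho`` couples the crop field to the hedge field so that
crops and hedges can cluster together or avoid each other.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, Polygon, box, mapping, shape

__all__ = [
    "Tessellation",
    "GRFConfig",
    "LandscapeAllocation",
    "LandscapeMetrics",
    "build_tessellation_fixture",
    "simulate_grf",
    "correlate_fields",
    "allocate",
    "compute_metrics",
    "tessellation_to_geojson",
    "tessellation_from_geojson",
]

_ROUND = 9  # coordinate rounding for vertex identity


def _key(x: float, y: float) -> tuple[float, float]:
    return (round(x, _ROUND), round(y, _ROUND))


@dataclass
class Tessellation:
    """Planar polygon/edge mosaic serving as the spatial support.

    Parameters
    ----------
    polygons : list of shapely.Polygon
        Simple polygons partitioning the square ``[0, extent]^2``.
    edges : list of shapely.LineString
        Straight border segments; every edge bounds one polygon (on the
        landscape exterior) or two (interior borders).
    edge_polygons : list of tuple of int
        Indices of the polygon(s) each edge borders.
    extent : float
        Side length of the square landscape (km).
    """

    polygons: list[Polygon]
    edges: list[LineString]
    edge_polygons: list[tuple[int, ...]]
    extent: float

    @property
    def n_polygons(self) -> int:
        return len(self.polygons)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def polygon_adjacency(self) -> set[tuple[int, int]]:
        """Symmetric set of polygon index pairs sharing an edge."""
        pairs: set[tuple[int, int]] = set()
        for polys in self.edge_polygons:
            if len(polys) == 2:
                i, j = polys
                pairs.add((i, j))
                pairs.add((j, i))
        return pairs

    def edge_graph(self) -> nx.Graph:
        """Graph of edges connected at shared endpoints."""
        g = nx.Graph()
        endpoint_map: dict[tuple[float, float], list[int]] = {}
        for k, e in enumerate(self.edges):
            g.add_node(k)
            (x0, y0), (x1, y1) = e.coords[0], e.coords[-1]
            for p in (_key(x0, y0), _key(x1, y1)):
                endpoint_map.setdefault(p, []).append(k)
        for _, members in endpoint_map.items():
            for a in members:
                for b in members:
                    if a < b:
                        g.add_edge(a, b)
        return g

    def neighbours(self, i: int) -> list[int]:
        return sorted({j for (a, j) in self.polygon_adjacency if a == i})

    def polygon_edges(self, i: int) -> list[int]:
        return [k for k, polys in enumerate(self.edge_polygons) if i in polys]

    def validate(self, rtol: float = 1e-8) -> None:
        total = sum(p.area for p in self.polygons)
        if not math.isclose(total, self.extent**2, rel_tol=1e-6):
            raise ValueError(
                f"polygons do not partition the extent: total area {total:.6f} "
                f"!= {self.extent**2:.6f}"
            )
        for k, polys in enumerate(self.edge_polygons):
            if len(polys) not in (1, 2):
                raise ValueError(f"edge {k} borders {len(polys)} polygons")


@dataclass
class GRFConfig:
    """Parameters of the landscape allocation model.

    ``phi`` is the exponential correlation range (km) shared by both GRFs;
    ``rho`` the cross-correlation between the hedge field and the crop
    field; ``p_crop`` / ``p_hedge`` the target allocation proportions by
    element count.
    """

    phi: float = 2.8
    rho: float = 0.5
    p_crop: float = 0.5
    p_hedge: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [-1, 1], got {self.rho}")
        for name in ("p_crop", "p_hedge"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class LandscapeAllocation:
    """Crop/hedge labels plus the GRF draws that produced them."""

    crop_label: np.ndarray  # bool per polygon
    hedge_label: np.ndarray  # bool per edge
    w_crop: np.ndarray  # GRF value per polygon
    w_hedge: np.ndarray  # GRF value per edge
    config: GRFConfig

    @property
    def n_crop(self) -> int:
        return int(self.crop_label.sum())

    @property
    def n_hedge(self) -> int:
        return int(self.hedge_label.sum())


@dataclass
class LandscapeMetrics:
    """Per-polygon and landscape-level descriptors used as covariates."""

    area: np.ndarray
    perimeter: np.ndarray
    n_adjacent_crop: np.ndarray
    n_adjacent_hedges: np.ndarray
    p_crop_realized: float
    p_hedge_realized: float
    crop_hedge_interface: float
    crop_aggregation: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "area": self.area,
                "perimeter": self.perimeter,
                "adj_crop": self.n_adjacent_crop,
                "adj_hedges": self.n_adjacent_hedges,
            }
        )


# ---------------------------------------------------------------------------
# tessellation fixture generator


def build_tessellation_fixture(
    extent: float, n_target_polygons: int, seed: int | None = None
) -> Tessellation:
    """Generate a synthetic T-tessellation by recursive rectangle splitting.

    Starting from the full square, rectangles are split one at a time:
    the rectangle to split is drawn with probability proportional to its
    area, the cut is perpendicular to its longer side at a uniformly
    jittered position.  Every interior vertex is a T-junction.  The result
    has exactly ``n_target_polygons`` polygons.

    This is a synthetic stand-in for a digitised field mosaic; real
    geometries can be loaded with :func:`tessellation_from_geojson`.
    """
    if extent <= 0:
        raise ValueError(f"extent must be positive, got {extent}")
    if n_target_polygons < 1:
        raise ValueError(f"n_target_polygons must be >= 1, got {n_target_polygons}")
    rng = np.random.default_rng(seed)
    rects: list[tuple[float, float, float, float]] = [(0.0, 0.0, extent, extent)]
    while len(rects) < n_target_polygons:
        areas = np.array([(x1 - x0) * (y1 - y0) for x0, y0, x1, y1 in rects])
        i = rng.choice(len(rects), p=areas / areas.sum())
        x0, y0, x1, y1 = rects.pop(i)
        frac = rng.uniform(0.3, 0.7)
        if (x1 - x0) >= (y1 - y0):  # cut vertically
            c = x0 + frac * (x1 - x0)
            rects += [(x0, y0, c, y1), (c, y0, x1, y1)]
        else:
            c = y0 + frac * (y1 - y0)
            rects += [(x0, y0, x1, c), (x0, c, x1, y1)]
    return _tessellation_from_rects(rects, extent)


def _tessellation_from_rects(
    rects: Sequence[tuple[float, float, float, float]], extent: float
) -> Tessellation:
    # Corner points subdivide the sides of neighbouring rectangles, which
    # is what makes the junctions T-shaped.
    corners: set[tuple[float, float]] = set()
    for x0, y0, x1, y1 in rects:
        corners |= {_key(x0, y0), _key(x0, y1), _key(x1, y0), _key(x1, y1)}

    xs_on: dict[float, list[float]] = {}
    ys_on: dict[float, list[float]] = {}
    for cx, cy in corners:
        xs_on.setdefault(cx, []).append(cy)  # points on vertical line x=cx
        ys_on.setdefault(cy, []).append(cx)

    seg_set: dict[tuple, None] = {}
    for x0, y0, x1, y1 in rects:
        kx0, ky0, kx1, ky1 = (round(v, _ROUND) for v in (x0, y0, x1, y1))
        for a, lo, hi, vertical in (
            (kx0, ky0, ky1, True),
            (kx1, ky0, ky1, True),
            (ky0, kx0, kx1, False),
            (ky1, kx0, kx1, False),
        ):
            pts = sorted(
                {lo, hi}
                | {t for t in (xs_on if vertical else ys_on).get(a, []) if lo < t < hi}
            )
            for lo_t, hi_t in zip(pts[:-1], pts[1:]):
                seg = (a, lo_t, a, hi_t) if vertical else (lo_t, a, hi_t, a)
                seg_set.setdefault(seg, None)

    segs = sorted(seg_set)
    rect_arr = np.array(rects)
    eps = 1e-7 * extent

    def containing(px: float, py: float) -> int | None:
        hit = np.flatnonzero(
            (rect_arr[:, 0] - eps <= px)
            & (px <= rect_arr[:, 2] + eps)
            & (rect_arr[:, 1] - eps <= py)
            & (py <= rect_arr[:, 3] + eps)
        )
        # point sits strictly inside exactly one rectangle
        for i in hit:
            x0, y0, x1, y1 = rect_arr[i]
            if x0 < px < x1 and y0 < py < y1:
                return int(i)
        return None

    edges: list[LineString] = []
    edge_polygons: list[tuple[int, ...]] = []
    for sx0, sy0, sx1, sy1 in segs:
        mx, my = (sx0 + sx1) / 2, (sy0 + sy1) / 2
        if sx0 == sx1:  # vertical: probe left/right
            cand = (containing(mx - eps * 10, my), containing(mx + eps * 10, my))
        else:
            cand = (containing(mx, my - eps * 10), containing(mx, my + eps * 10))
        polys = tuple(sorted({c for c in cand if c is not None}))
        if not polys:
            continue
        edges.append(LineString([(sx0, sy0), (sx1, sy1)]))
        edge_polygons.append(polys)

    polygons = [box(x0, y0, x1, y1) for x0, y0, x1, y1 in rects]
    return Tessellation(polygons, edges, edge_polygons, float(extent))


# ---------------------------------------------------------------------------
# Gaussian random fields


def simulate_grf(
    points: np.ndarray, phi: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw a zero-mean GRF with exponential correlation at given points.

    The covariance is ``Sigma_ij = exp(-|x_i - x_j| / phi)``; ``phi = 0``
    is the independence limit (identity covariance).  A diagonal jitter of
    1e-10 is added before the Cholesky factorisation.
    """
    if phi < 0:
        raise ValueError(f"phi must be >= 0, got {phi}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if phi == 0:
        return rng.standard_normal(n)
    cov = np.exp(-cdist(pts, pts) / phi)
    cov[np.diag_indices_from(cov)] += 1e-10
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:  # pragma: no cover - pathological input
        raise np.linalg.LinAlgError(
            f"GRF covariance not positive definite after jitter "
            f"(n={n}, phi={phi}); are the points distinct?"
        ) from err
    return chol @ rng.standard_normal(n)


def correlate_fields(
    w_hedge: np.ndarray, w_indep: np.ndarray, rho: float
) -> np.ndarray:
    """Blend an independent GRF with the hedge GRF at correlation ``rho``.

    Returns ``rho * W_h + sqrt(1 - rho^2) * W_tilde`` so the output has
    unit marginal variance and correlation ``rho`` with ``w_hedge``.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [-1, 1], got {rho}")
    w_hedge = np.asarray(w_hedge, dtype=float)
    w_indep = np.asarray(w_indep, dtype=float)
    if w_hedge.shape != w_indep.shape:
        raise ValueError("field shapes differ")
    return rho * w_hedge + math.sqrt(1.0 - rho**2) * w_indep


def _top_k_mask(values: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k largest values; ties broken by element index."""
    n = len(values)
    order = np.lexsort((np.arange(n), -values))
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask


def allocate(tess: Tessellation, config: GRFConfig) -> LandscapeAllocation:
    """Allocate crop polygons and hedge edges by GRF quantile thresholding.

    Both GRFs are drawn jointly on the pooled set of polygon centroids and
    edge midpoints so their cross-correlation is spatially coherent.  The
    ``round(p * count)`` elements with the highest field values receive the
    label, which pins the realised proportions to the targets exactly.
    """
    poly_pts = np.array([[p.centroid.x, p.centroid.y] for p in tess.polygons])
    edge_pts = np.array([[e.centroid.x, e.centroid.y] for e in tess.edges])
    pts = np.vstack([poly_pts, edge_pts])
    rng = np.random.default_rng(config.seed)
    w_h = simulate_grf(pts, config.phi, rng)
    w_t = simulate_grf(pts, config.phi, rng)
    w_c = correlate_fields(w_h, w_t, config.rho)

    n_poly, n_edge = tess.n_polygons, tess.n_edges
    w_crop = w_c[:n_poly]
    w_hedge = w_h[n_poly:]
    n_crop = int(math.floor(config.p_crop * n_poly + 0.5))
    n_hedge = int(math.floor(config.p_hedge * n_edge + 0.5))
    return LandscapeAllocation(
        crop_label=_top_k_mask(w_crop, n_crop),
        hedge_label=_top_k_mask(w_hedge, n_hedge),
        w_crop=w_crop,
        w_hedge=w_hedge,
        config=config,
    )


# ---------------------------------------------------------------------------
# descriptors


def compute_metrics(tess: Tessellation, alloc: LandscapeAllocation) -> LandscapeMetrics:
    """Geometry and neighbourhood descriptors of an allocated landscape."""
    n = tess.n_polygons
    area = np.array([p.area for p in tess.polygons])
    perimeter = np.array([p.length for p in tess.polygons])
    adj_crop = np.zeros(n, dtype=int)
    adj_hedge = np.zeros(n, dtype=int)
    for k, polys in enumerate(tess.edge_polygons):
        hedge = bool(alloc.hedge_label[k])
        for i in polys:
            if hedge:
                adj_hedge[i] += 1
    # adjacent *fields* that are crop (count each neighbour once)
    neigh: dict[int, set[int]] = {i: set() for i in range(n)}
    for polys in tess.edge_polygons:
        if len(polys) == 2:
            i, j = polys
            neigh[i].add(j)
            neigh[j].add(i)
    for i in range(n):
        adj_crop[i] = sum(1 for j in neigh[i] if alloc.crop_label[j])

    interface = 0.0
    for k, polys in enumerate(tess.edge_polygons):
        if alloc.hedge_label[k] and any(alloc.crop_label[i] for i in polys):
            interface += tess.edges[k].length

    pairs = {(i, j) for (i, j) in tess.polygon_adjacency if i < j}
    with_crop = [
        (i, j) for (i, j) in pairs if alloc.crop_label[i] or alloc.crop_label[j]
    ]
    both = sum(1 for (i, j) in with_crop if alloc.crop_label[i] and alloc.crop_label[j])
    aggregation = both / len(with_crop) if with_crop else float("nan")

    return LandscapeMetrics(
        area=area,
        perimeter=perimeter,
        n_adjacent_crop=adj_crop,
        n_adjacent_hedges=adj_hedge,
        p_crop_realized=alloc.n_crop / n,
        p_hedge_realized=alloc.n_hedge / tess.n_edges,
        crop_hedge_interface=interface,
        crop_aggregation=aggregation,
    )


# ---------------------------------------------------------------------------
# GeoJSON I/O


def tessellation_to_geojson(
    tess: Tessellation, alloc: LandscapeAllocation | None = None
) -> dict:
    """Serialize a tessellation (and optional allocation) as GeoJSON."""
    features = []
    for i, poly in enumerate(tess.polygons):
        props = {"id": i, "kind": "polygon"}
        if alloc is not None:
            props["crop"] = bool(alloc.crop_label[i])
            props["grf"] = float(alloc.w_crop[i])
        features.append(
            {"type": "Feature", "geometry": mapping(poly), "properties": props}
        )
    for k, edge in enumerate(tess.edges):
        props = {"id": k, "kind": "edge", "polygons": list(tess.edge_polygons[k])}
        if alloc is not None:
            props["hedge"] = bool(alloc.hedge_label[k])
            props["grf"] = float(alloc.w_hedge[k])
        features.append(
            {"type": "Feature", "geometry": mapping(edge), "properties": props}
        )
    return {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"extent": tess.extent},
    }


def tessellation_from_geojson(
    obj: dict | str,
) -> tuple[Tessellation, LandscapeAllocation | None]:
    """Load a tessellation (and allocation if labels are present)."""
    if isinstance(obj, str):
        with open(obj) as fh:
            obj = json.load(fh)
    polys: list[tuple[int, Polygon, dict]] = []
    edges: list[tuple[int, LineString, dict]] = []
    for feat in obj["features"]:
        geom = shape(feat["geometry"])
        props = feat.get("properties", {})
        if props.get("kind") == "polygon" or geom.geom_type == "Polygon":
            polys.append((props["id"], geom, props))
        else:
            edges.append((props["id"], geom, props))
    polys.sort(key=lambda t: t[0])
    edges.sort(key=lambda t: t[0])
    tess = Tessellation(
        polygons=[p for _, p, _ in polys],
        edges=[e for _, e, _ in edges],
        edge_polygons=[tuple(props["polygons"]) for _, _, props in edges],
        extent=float(obj.get("properties", {}).get("extent", 0.0)),
    )
    if polys and "crop" in polys[0][2]:
        alloc = LandscapeAllocation(
            crop_label=np.array([p["crop"] for _, _, p in polys], dtype=bool),
            hedge_label=np.array([p["hedge"] for _, _, p in edges], dtype=bool),
            w_crop=np.array([p.get("grf", np.nan) for _, _, p in polys]),
            w_hedge=np.array([p.get("grf", np.nan) for _, _, p in edges]),
            config=GRFConfig(),
        )
        return tess, alloc
    return tess, None
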