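"""Landscape surfaces of genetic/chemical distance and diversity.

The cartography follows the connectivity-network approach: a Delaunay
triangulation links sampling sites, mean inter-individual distances are
assigned to the midpoint of each triangulation edge (optionally after
removing the linear trend on geographic distance), and an inverse
distance-weighted (IDW, weight 1/d^a with a = 2 by default) interpolation
spreads the midpoint values over a regular grid. Diversity or variability
surfaces interpolate values attached directly to geographic-group
barycenters instead of edge midpoints.

All planar geometry (triangulation, IDW) is computed on an equirectangular
projection about the mean latitude; great-circle distances are used only
as the regression predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .datatypes import DistanceMatrix, Surface

EARTH_RADIUS_KM = 6371.0
_COINCIDENCE_EPS = 1e-9  # degrees: grid node takes a coincident point's value
_JITTER = 1e-6           # degrees: applied to duplicate site coordinates


def haversine_km(
    lon1: np.ndarray | float, lat1: np.ndarray | float,
    lon2: np.ndarray | float, lat2: np.ndarray | float,
) -> np.ndarray | float:
    """Great-circle distance on a 6371-km sphere."""
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    h = (
        np.sin((phi2 - phi1) / 2) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _project(lon: np.ndarray, lat: np.ndarray, lat0: float) -> np.ndarray:
    """Equirectangular projection (degree units, x scaled by cos lat0)."""
    return np.column_stack([np.asarray(lon) * np.cos(np.radians(lat0)), lat])


@dataclass
class ConnectivityNetwork:
    """Delaunay triangulation of sampling sites with edge midpoints."""

    site_ids: list[str]
    coords: np.ndarray                     # (n, 2) lon/lat
    edges: list[tuple[str, str]]
    midpoints: np.ndarray                  # (n_edges, 2) lon/lat

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)


def build_connectivity(site_coords: dict[str, tuple[float, float]]) -> ConnectivityNetwork:
    """Delaunay triangulation of the site set.

    Duplicate coordinates are jittered by ~1e-6 degrees with a warning so
    the triangulation stays well defined.
    """
    site_ids = sorted(site_coords)
    coords = np.array([site_coords[s] for s in site_ids], dtype=float)
    if len(site_ids) < 3:
        raise ValueError("Delaunay triangulation needs >= 3 sites")
    seen: dict[tuple[float, float], int] = {}
    rng = np.random.default_rng(0)
    jittered = 0
    for i, xy in enumerate(map(tuple, coords)):
        if xy in seen:
            coords[i] += rng.uniform(-_JITTER, _JITTER, 2)
            jittered += 1
        else:
            seen[xy] = i
    if jittered:
        warnings.warn(f"jittered {jittered} duplicate site coordinates", stacklevel=2)
    lat0 = float(coords[:, 1].mean())
    planar = _project(coords[:, 0], coords[:, 1], lat0)
    try:
        tri = Delaunay(planar)
    except Exception as exc:  # QhullError on collinear input
        raise ValueError(f"degenerate site geometry: {exc}") from exc
    if tri.simplices.size == 0:
        raise ValueError("all sites collinear; no triangulation")
    edge_set: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            i, j = sorted((simplex[a], simplex[b]))
            edge_set.add((i, j))
    edges = sorted((site_ids[i], site_ids[j]) for i, j in edge_set)
    index = {s: i for i, s in enumerate(site_ids)}
    midpoints = np.array(
        [(coords[index[a]] + coords[index[b]]) / 2.0 for a, b in edges]
    )
    return ConnectivityNetwork(site_ids, coords, edges, midpoints)


def edge_midpoint_values(
    net: ConnectivityNetwork,
    dm: DistanceMatrix,
    sample_site_map: dict[str, str],
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]]]:
    """Mean inter-individual distance per triangulation edge.

    Returns (midpoint lon/lat, values, kept edges). The value at an edge's
    midpoint is the mean distance over all sample pairs spanning the edge's
    two sites; edges without any defined cross-pair are dropped with a
    warning.
    """
    by_site: dict[str, list[int]] = {}
    for i, label in enumerate(dm.labels):
        site = sample_site_map.get(label)
        if site is not None:
            by_site.setdefault(site, []).append(i)
    points, values, kept = [], [], []
    dropped = 0
    for (a, b), mid in zip(net.edges, net.midpoints):
        ia, ib = by_site.get(a, []), by_site.get(b, [])
        if not ia or not ib:
            dropped += 1
            continue
        block = dm.values[np.ix_(ia, ib)]
        finite = np.isfinite(block)
        if not finite.any():
            dropped += 1
            continue
        points.append(mid)
        values.append(float(block[finite].mean()))
        kept.append((a, b))
    if dropped:
        warnings.warn(f"dropped {dropped} edges without cross-site pairs", stacklevel=2)
    if not points:
        raise ValueError("no edge carries a defined inter-individual distance")
    return np.array(points), np.array(values), kept


def residualize(
    values: np.ndarray,
    edges: list[tuple[str, str]],
    site_coords: dict[str, tuple[float, float]],
) -> np.ndarray:
    """Residuals of midpoint values on great-circle inter-site distance (OLS).

    With a constant predictor the values are passed through unchanged with
    a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("residualization needs >= 3 points")
    km = np.array(
        [
            haversine_km(*site_coords[a], *site_coords[b])
            for a, b in edges
        ]
    )
    if np.ptp(km) < 1e-12:
        warnings.warn("zero variance in geographic distance; passing values through",
                      stacklevel=2)
        return values.copy()
    slope, intercept = np.polyfit(km, values, 1)
    return values - (slope * km + intercept)


@dataclass
class InterpolationConfig:
    """IDW settings: exponent a, grid width in columns, bounding-box margin
    (fraction of the span) and convex-hull masking."""

    a: float = 2.0
    n_cols: int = 150
    margin: float = 0.05
    mask_hull: bool = True
    use_residuals: bool = True

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("distance-weighting exponent must be positive")
        if self.n_cols < 2:
            raise ValueError("grid needs >= 2 columns")


def _grid(bbox: tuple[float, float, float, float], cfg: InterpolationConfig):
    lon_min, lat_min, lon_max, lat_max = bbox
    # degenerate spans (single point / collinear) get a half-degree pad
    if lon_max - lon_min < 1e-9:
        lon_min, lon_max = lon_min - 0.5, lon_max + 0.5
    if lat_max - lat_min < 1e-9:
        lat_min, lat_max = lat_min - 0.5, lat_max + 0.5
    span_lon = lon_max - lon_min
    span_lat = lat_max - lat_min
    lon_min -= cfg.margin * span_lon
    lon_max += cfg.margin * span_lon
    lat_min -= cfg.margin * span_lat
    lat_max += cfg.margin * span_lat
    cell = (lon_max - lon_min) / cfg.n_cols
    n_rows = max(int(np.ceil((lat_max - lat_min) / cell)), 2)
    return (lon_min, lat_min), cell, n_rows


def idw_surface(
    points: np.ndarray,
    values: np.ndarray,
    cfg: InterpolationConfig | None = None,
    bbox: tuple[float, float, float, float] | None = None,
    hull_points: np.ndarray | None = None,
) -> Surface:
    """Inverse distance-weighted surface over a regular lon/lat grid.

    Grid value = sum(w_i v_i)/sum(w_i) with w_i = 1/d_i^a in projected
    planar coordinates. A node coinciding with a data point takes that
    point's value exactly. Cells outside the convex hull of ``hull_points``
    (default: the data points) are masked when ``cfg.mask_hull``.
    """
    cfg = cfg or InterpolationConfig()
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if points.size == 0:
        raise ValueError("empty point set")
    if bbox is None:
        bbox = (
            points[:, 0].min(), points[:, 1].min(),
            points[:, 0].max(), points[:, 1].max(),
        )
    origin, cell, n_rows = _grid(bbox, cfg)
    lon = origin[0] + (np.arange(cfg.n_cols) + 0.5) * cell
    lat = origin[1] + (np.arange(n_rows) + 0.5) * cell
    glon, glat = np.meshgrid(lon, lat)
    lat0 = float(points[:, 1].mean())
    planar_pts = _project(points[:, 0], points[:, 1], lat0)
    planar_grid = _project(glon.ravel(), glat.ravel(), lat0)

    d = np.sqrt(
        ((planar_grid[:, None, :] - planar_pts[None, :, :]) ** 2).sum(axis=2)
    )
    coincident = d < _COINCIDENCE_EPS
    with np.errstate(divide="ignore"):
        w = 1.0 / np.maximum(d, _COINCIDENCE_EPS) ** cfg.a
    est = (w * values[None, :]).sum(axis=1) / w.sum(axis=1)
    hit = coincident.any(axis=1)
    if hit.any():
        first = np.argmax(coincident[hit], axis=1)
        est[hit] = values[first]
    grid = est.reshape(n_rows, cfg.n_cols)

    mask = np.zeros_like(grid, dtype=bool)
    if cfg.mask_hull:
        hull_src = points if hull_points is None else np.asarray(hull_points, float)
        if len(hull_src) >= 3:
            try:
                tri = Delaunay(_project(hull_src[:, 0], hull_src[:, 1], lat0))
                inside = tri.find_simplex(planar_grid) >= 0
                mask = ~inside.reshape(n_rows, cfg.n_cols)
            except Exception:
                warnings.warn("degenerate hull; surface left unmasked", stacklevel=2)
    return Surface(origin=origin, cellsize=cell, values=grid, mask=mask)


def distance_surface(
    net: ConnectivityNetwork,
    dm: DistanceMatrix,
    sample_site_map: dict[str, str],
    site_coords: dict[str, tuple[float, float]],
    cfg: InterpolationConfig | None = None,
    bbox: tuple[float, float, float, float] | None = None,
) -> tuple[Surface, np.ndarray, np.ndarray]:
    """End-to-end distance cartography: midpoints, optional residualization,
    IDW. Returns (surface, midpoints, midpoint values actually interpolated)."""
    cfg = cfg or InterpolationConfig()
    points, raw, kept = edge_midpoint_values(net, dm, sample_site_map)
    values = residualize(raw, kept, site_coords) if cfg.use_residuals else raw
    surface = idw_surface(points, values, cfg, bbox=bbox, hull_points=net.coords)
    return surface, points, values


def diversity_surface(
    site_values: dict[str, float],
    barycenters: dict[str, tuple[float, float]],
    cfg: InterpolationConfig | None = None,
    bbox: tuple[float, float, float, float] | None = None,
) -> Surface:
    """IDW surface of per-group diversity/variability values placed at group
    barycenters. Groups with undefined (NaN) values are excluded with a
    warning."""
    cfg = cfg or InterpolationConfig()
    points, values = [], []
    for group, value in sorted(site_values.items()):
        if group not in barycenters:
            raise KeyError(f"no barycenter for group {group!r}")
        if not np.isfinite(value):
            warnings.warn(f"group {group!r} has undefined value; excluded", stacklevel=2)
            continue
        points.append(barycenters[group])
        values.append(value)
    if not points:
        raise ValueError("no group carries a finite value")
    return idw_surface(np.array(points), np.array(values), cfg, bbox=bbox)


def nearest_neighbour_values(points: np.ndarray, values: np.ndarray,
                             probes: np.ndarray) -> np.ndarray:
    """Voronoi (nearest data point) values at probe locations; the a -> inf
    limit of IDW, used as an independent check."""
    tree = cKDTree(points)
    _, idx = tree.query(probes)
    return np.asarray(values)[idx]
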