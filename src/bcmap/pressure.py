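"""Distance- and area-based landscape pressure index.

Three pressure maps, each scoring every habitat patch on a relative 0-4
scale: (1) proximity to agricultural land, (2) proximity to urban areas, and
(3) the proportion of modified (agricultural + urban) land in the linked
coastal drainage basin. Their sum is the cumulative impact value (0-12);
values of 6 and above (half the maximum or more) mark higher-level pressure.

Distance classes (upper bound inclusive): ≤100 m → 4, ≤400 m → 3,
≤1000 m → 2, ≤5000 m → 1, beyond → 0. Proportion classes (lower bound
inclusive): ≥80% → 4, ≥60% → 3, ≥40% → 2, ≥20% → 1, below → 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.ops import unary_union

from .grid import GridRaster, require_boolean
from .habitats import HabitatPatch

__all__ = [
    "DistanceClassTable",
    "ProportionClassTable",
    "PressureScore",
    "DrainageBasin",
    "HIGH_PRESSURE_THRESHOLD",
    "classify_distance",
    "classify_proportion",
    "patch_stressor_distances",
    "agricultural_pressure",
    "urban_pressure",
    "urban_pressure_rings",
    "basin_modified_proportion",
    "basin_pressure",
    "cumulative_pressure",
    "score_patches",
]

HIGH_PRESSURE_THRESHOLD = 6.0


@dataclass(frozen=True)
class DistanceClassTable:
    """Distance thresholds (m) and the pressure value at or below each."""

    breaks: tuple[float, ...] = (100.0, 400.0, 1000.0, 5000.0)
    values: tuple[int, ...] = (4, 3, 2, 1)
    beyond: int = 0

    def __post_init__(self) -> None:
        if list(self.breaks) != sorted(self.breaks) or len(set(self.breaks)) != len(self.breaks):
            raise ValueError("distance breaks must be strictly increasing")
        if list(self.values) != sorted(self.values, reverse=True):
            raise ValueError("distance class values must be strictly decreasing")


@dataclass(frozen=True)
class ProportionClassTable:
    """Percent thresholds and the pressure value at or above each."""

    breaks: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0)
    values: tuple[int, ...] = (1, 2, 3, 4)
    below: int = 0

    def __post_init__(self) -> None:
        if list(self.breaks) != sorted(self.breaks) or len(set(self.breaks)) != len(self.breaks):
            raise ValueError("proportion breaks must be strictly increasing")


@dataclass(frozen=True)
class DrainageBasin:
    """Coastal drainage basin with its modified-land proportion and pressure value."""

    id: str
    polygon: shapely.Geometry
    modified_proportion: float  # percent of basin area that is agriculture + urban
    v_basin: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.modified_proportion <= 100.0:
            raise ValueError(
                f"modified_proportion must lie in [0, 100], got {self.modified_proportion}"
            )


@dataclass(frozen=True)
class PressureScore:
    """Per-patch pressure components, cumulative impact and high-pressure flag."""

    patch_id: str
    v_agri: float
    v_urban: float
    v_basin: float
    basin_excluded: bool = False
    high_threshold: float = HIGH_PRESSURE_THRESHOLD

    def __post_init__(self) -> None:
        for name in ("v_agri", "v_urban", "v_basin"):
            v = getattr(self, name)
            if not 0.0 <= v <= 4.0:
                raise ValueError(f"{name} must lie in [0, 4], got {v}")

    @property
    def cumulative(self) -> float:
        return self.v_agri + self.v_urban + self.v_basin

    @property
    def high_pressure(self) -> bool:
        # the 6-12 band is inclusive at 6 (half the maximal value)
        return self.cumulative >= self.high_threshold


def classify_distance(d, table: DistanceClassTable = DistanceClassTable()):
    """Pressure value for a nearest-stressor distance (m); upper bounds inclusive."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distances must be non-negative")
    out = np.full(d_arr.shape, table.beyond, dtype=int)
    # outermost threshold first, so the innermost class a distance fits wins
    for brk, val in sorted(zip(table.breaks, table.values), reverse=True):
        out[d_arr <= brk] = val
    return out if out.ndim else int(out)


def classify_proportion(p, table: ProportionClassTable = ProportionClassTable()):
    """Pressure value for a modified-land proportion (%); lower bounds inclusive."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 100)):
        raise ValueError("proportions must lie in [0, 100]")
    out = np.full(p_arr.shape, table.below, dtype=int)
    for brk, val in sorted(zip(table.breaks, table.values)):
        out[p_arr >= brk] = val
    return out if out.ndim else int(out)


def _stressor_distance_grid(mask: GridRaster) -> np.ndarray:
    """Exact Euclidean centre-to-centre distance (m) to the nearest True cell."""
    require_boolean(mask, "stressor mask")
    if not mask.data.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask.data) * mask.cell_size


def patch_stressor_distances(patches: list[HabitatPatch], stressor) -> np.ndarray:
    """Nearest distance (m) from each patch to a stressor layer.

    ``stressor`` is either a boolean GridRaster (distances between cell
    centres, exact via the Euclidean distance transform) or an iterable of
    shapely geometries (distance from patch cell centres to the geometry).
    ``inf`` where the stressor layer is empty.
    """
    if isinstance(stressor, GridRaster):
        dist = _stressor_distance_grid(stressor)
        return np.array(
            [dist[p.rows, p.cols].min() if p.n_cells else np.inf for p in patches]
        )
    geoms = [g for g in stressor if not g.is_empty]
    if not geoms:
        return np.full(len(patches), np.inf)
    merged = unary_union(geoms)
    out = np.empty(len(patches))
    for i, patch in enumerate(patches):
        x, y = patch.cell_centers()
        out[i] = shapely.distance(merged, shapely.points(x, y)).min()
    return out


def _classify_distances(dists: np.ndarray, table: DistanceClassTable) -> np.ndarray:
    finite = np.isfinite(dists)
    out = np.full(dists.shape, table.beyond, dtype=int)
    if finite.any():
        out[finite] = np.asarray(classify_distance(dists[finite], table))
    return out


def agricultural_pressure(
    patches: list[HabitatPatch],
    agriculture,
    table: DistanceClassTable = DistanceClassTable(),
) -> np.ndarray:
    """Pressure value from the nearest distance to agricultural land, per patch."""
    return _classify_distances(patch_stressor_distances(patches, agriculture), table)


def urban_pressure(
    patches: list[HabitatPatch],
    urban,
    table: DistanceClassTable = DistanceClassTable(),
) -> np.ndarray:
    """Pressure value from the nearest distance to urban areas, per patch."""
    return _classify_distances(patch_stressor_distances(patches, urban), table)


def urban_pressure_rings(
    patches: list[HabitatPatch],
    urban_geoms,
    table: DistanceClassTable = DistanceClassTable(),
) -> np.ndarray:
    """Buffer-ring construction of the urban pressure map.

    Concentric buffer zones are drawn around the urban areas at the class
    thresholds; a patch takes the value of the innermost zone it touches.
    Equivalent by construction to nearest-distance classification; both
    routes are kept so the equivalence can be tested.
    """
    geoms = [g for g in urban_geoms if not g.is_empty]
    out = np.full(len(patches), table.beyond, dtype=int)
    if not geoms:
        return out
    merged = unary_union(geoms)
    patch_points = []
    for patch in patches:
        x, y = patch.cell_centers()
        patch_points.append(shapely.points(x, y))
    for brk, val in sorted(zip(table.breaks, table.values), reverse=True):
        # high arc resolution keeps the polygonal buffer within ~1e-5 x radius
        # of the true offset curve, so ring membership matches distance
        # classification away from exact floating-point boundaries
        zone = merged.buffer(brk, quad_segs=256)
        shapely.prepare(zone)
        for i, pts in enumerate(patch_points):
            if shapely.intersects(zone, pts).any():
                out[i] = val
    return out


def basin_modified_proportion(
    basin_polygon: shapely.Geometry,
    landcover: GridRaster,
    modified_codes=(3, 4),  # agriculture, urban
) -> float:
    """Percent of the basin's cells whose land cover is agricultural or urban."""
    minx, miny, maxx, maxy = basin_polygon.bounds
    r0, c0 = landcover.cell_of(minx, miny)
    r1, c1 = landcover.cell_of(maxx, maxy)
    r0, c0 = max(int(r0), 0), max(int(c0), 0)
    r1 = min(int(r1) + 1, landcover.n_rows)
    c1 = min(int(c1) + 1, landcover.n_cols)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    x, y = landcover.cell_center(rr.ravel(), cc.ravel())
    inside = shapely.contains_xy(basin_polygon, x, y)
    n_inside = int(np.count_nonzero(inside))
    if n_inside == 0:
        raise ValueError("basin has zero area on the land-cover grid")
    codes = landcover.data[rr.ravel()[inside], cc.ravel()[inside]]
    n_modified = int(np.count_nonzero(np.isin(codes, modified_codes)))
    return 100.0 * n_modified / n_inside


def basin_pressure(
    patches: list[HabitatPatch],
    basins: list[DrainageBasin],
    link_radius: float = 500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Basin-linked pressure value per patch.

    A patch inside one basin takes that basin's value; a patch spanning
    several basins takes the unrounded mean of their values; a patch outside
    every basin but within ``link_radius`` of one takes the nearest basin's
    value; patches farther than that are excluded from this pressure map
    (value contribution 0, flagged).

    Returns ``(v_basin, excluded)`` arrays.
    """
    n = len(patches)
    v = np.zeros(n)
    excluded = np.ones(n, dtype=bool)
    if not basins:
        return v, excluded
    prepared = [shapely.prepared.prep(b.polygon) for b in basins]
    for i, patch in enumerate(patches):
        x, y = patch.cell_centers()
        member_values = [
            b.v_basin
            for b, _ in zip(basins, prepared)
            if shapely.contains_xy(b.polygon, x, y).any()
        ]
        if member_values:
            v[i] = float(np.mean(member_values))
            excluded[i] = False
            continue
        pts = shapely.points(x, y)
        dists = np.array([shapely.distance(b.polygon, pts).min() for b in basins])
        j = int(np.argmin(dists))
        if dists[j] <= link_radius:
            v[i] = float(basins[j].v_basin)
            excluded[i] = False
    return v, excluded


def cumulative_pressure(
    v_agri: float,
    v_urban: float,
    v_basin: float,
    patch_id: str = "",
    basin_excluded: bool = False,
    high_threshold: float = HIGH_PRESSURE_THRESHOLD,
) -> PressureScore:
    """Combine the three component values into a cumulative impact score."""
    return PressureScore(
        patch_id=patch_id,
        v_agri=float(v_agri),
        v_urban=float(v_urban),
        v_basin=float(v_basin),
        basin_excluded=basin_excluded,
        high_threshold=high_threshold,
    )


def score_patches(
    patches: list[HabitatPatch],
    agriculture,
    urban,
    basins: list[DrainageBasin],
    link_radius: float = 500.0,
    distance_table: DistanceClassTable = DistanceClassTable(),
    high_threshold: float = HIGH_PRESSURE_THRESHOLD,
) -> list[PressureScore]:
    """Run all three pressure maps over a patch list and combine them."""
    v_agri = agricultural_pressure(patches, agriculture, distance_table)
    v_urban = urban_pressure(patches, urban, distance_table)
    v_basin, excluded = basin_pressure(patches, basins, link_radius)
    return [
        cumulative_pressure(a, u, b, patch_id=p.id, basin_excluded=bool(e),
                            high_threshold=high_threshold)
        for p, a, u, b, e in zip(patches, v_agri, v_urban, v_basin, excluded)
    ]
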