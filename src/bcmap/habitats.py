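"""Compile the four blue-carbon habitat classes and split them into patches.

Sources: a national-style land-cover raster supplies the wetland classes, a
protected-area habitat inventory (vector, quality-controlled) takes
precedence where the two disagree; the submerged classes come from a 5-year
satellite SAV layer filtered for persistence and split into seagrass versus
other rooted macrophytes using a modelled seagrass distribution plus
per-region classification rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union

from .coastal import connectivity_structure
from .grid import GridRaster, require_boolean, require_same_grid

__all__ = [
    "LANDCOVER_CODES",
    "HABITAT_CODES",
    "HABITAT_NAMES",
    "HABITAT_REALMS",
    "REGION_RULES",
    "HabitatPatch",
    "merge_wetland_raster",
    "merge_wetland_layers",
    "filter_sav_persistence",
    "classify_sav",
    "patchify",
    "assign_subbasins",
]

# Land-cover class codes (national land-cover style raster).
LANDCOVER_CODES = {
    "other": 0,
    "open_wetland": 1,
    "forested_wetland": 2,
    "agriculture": 3,
    "urban": 4,
    "lake": 5,
    "road": 6,
}

# Blue-carbon habitat class codes (0 = unlabeled).
HABITAT_CODES = {
    "seagrass": 1,
    "other_rooted_macrophytes": 2,
    "open_wetland": 3,
    "forested_wetland": 4,
}
HABITAT_NAMES = {v: k for k, v in HABITAT_CODES.items()}
HABITAT_REALMS = {
    "seagrass": "submerged",
    "other_rooted_macrophytes": "submerged",
    "open_wetland": "land",
    "forested_wetland": "land",
}

# Regional SAV classification rules: in the rule's region every retained SAV
# cell is classified seagrass / other, or by overlap with the modelled
# potential seagrass distribution.
REGION_RULES = {"all_other": 0, "model_overlap": 1, "all_seagrass": 2}


@dataclass
class HabitatPatch:
    """One contiguous mapped habitat unit (a connected set of raster cells)."""

    id: str
    habitat_class: str
    rows: np.ndarray
    cols: np.ndarray
    raster: GridRaster = field(repr=False)
    subbasin: str | None = None

    @property
    def realm(self) -> str:
        return HABITAT_REALMS[self.habitat_class]

    @property
    def n_cells(self) -> int:
        return len(self.rows)

    @property
    def area_km2(self) -> float:
        return self.n_cells * self.raster.cell_area_km2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return self.raster.cell_center(self.rows, self.cols)

    @property
    def geometry(self) -> shapely.Geometry:
        """Patch footprint as the union of its cell squares."""
        cs = self.raster.cell_size
        x0, y0 = self.raster.x0, self.raster.y0
        boxes = [
            box(x0 + c * cs, y0 + r * cs, x0 + (c + 1) * cs, y0 + (r + 1) * cs)
            for r, c in zip(self.rows, self.cols)
        ]
        return unary_union(boxes)

    def subset(self, keep: np.ndarray) -> "HabitatPatch":
        return HabitatPatch(
            id=self.id,
            habitat_class=self.habitat_class,
            rows=self.rows[keep],
            cols=self.cols[keep],
            raster=self.raster,
            subbasin=self.subbasin,
        )


def _burn_polygons(class_raster: np.ndarray, grid: GridRaster, polygons) -> None:
    """Burn (geometry, habitat_class) pairs into a habitat-code array, in place."""
    rows, cols = np.nonzero(np.ones_like(class_raster, dtype=bool))
    # evaluate membership only inside each polygon's bounding box for speed
    for geom, habitat_class in polygons:
        if habitat_class not in HABITAT_CODES:
            raise ValueError(f"unknown habitat class in vector source: {habitat_class!r}")
        minx, miny, maxx, maxy = geom.bounds
        r0, c0 = grid.cell_of(minx, miny)
        r1, c1 = grid.cell_of(maxx, maxy)
        r0, c0 = max(int(r0), 0), max(int(c0), 0)
        r1 = min(int(r1) + 1, grid.n_rows)
        c1 = min(int(c1) + 1, grid.n_cols)
        if r1 <= r0 or c1 <= c0:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        x, y = grid.cell_center(rr.ravel(), cc.ravel())
        inside = shapely.contains_xy(geom, x, y)
        class_raster[rr.ravel()[inside], cc.ravel()[inside]] = HABITAT_CODES[habitat_class]


def merge_wetland_raster(
    primary_landcover: GridRaster,
    protected_area_habitats=(),
) -> GridRaster:
    """Merged wetland habitat-code raster (open/forested wetland only).

    The raster land-cover source and the vector inventory are unioned per
    class; where they disagree on the class at a cell, the vector source wins
    (it is the quality-controlled baseline inventory inside protected areas).
    """
    lc = np.asarray(primary_landcover.data)
    known = np.isin(lc, list(LANDCOVER_CODES.values()))
    if not known.all():
        bad = sorted(np.unique(lc[~known]).tolist())
        raise ValueError(f"unknown land-cover class codes: {bad}")
    out = np.zeros(lc.shape, dtype=np.int16)
    out[lc == LANDCOVER_CODES["open_wetland"]] = HABITAT_CODES["open_wetland"]
    out[lc == LANDCOVER_CODES["forested_wetland"]] = HABITAT_CODES["forested_wetland"]
    wetland_polys = []
    for geom, habitat_class in protected_area_habitats:
        if habitat_class not in ("open_wetland", "forested_wetland"):
            raise ValueError(f"unknown habitat class in vector source: {habitat_class!r}")
        wetland_polys.append((geom, habitat_class))
    _burn_polygons(out, primary_landcover, wetland_polys)
    return primary_landcover.with_data(out)


def merge_wetland_layers(
    primary_landcover: GridRaster,
    protected_area_habitats=(),
    connectivity: int = 4,
) -> list[HabitatPatch]:
    """Merged wetland sources, patchified into contiguous habitat units."""
    return patchify(merge_wetland_raster(primary_landcover, protected_area_habitats),
                    connectivity=connectivity)


def filter_sav_persistence(sav_year_count: GridRaster, min_years: int = 4) -> GridRaster:
    """Retain SAV cells detected in at least ``min_years`` of the 5 observation years."""
    counts = np.asarray(sav_year_count.data)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.array_equal(counts, counts.astype(int)):
            raise ValueError("SAV year counts must be integers in 0..5")
        counts = counts.astype(int)
    if counts.min() < 0 or counts.max() > 5:
        raise ValueError(
            f"SAV year counts must lie in 0..5, got range "
            f"[{counts.min()}, {counts.max()}]"
        )
    if not 1 <= min_years <= 5:
        raise ValueError(f"min_years must lie in 1..5, got {min_years}")
    return sav_year_count.with_data(counts >= min_years)


def classify_sav(
    sav_mask: GridRaster,
    seagrass_model: GridRaster,
    region_rules: GridRaster,
) -> GridRaster:
    """Split retained SAV cells into seagrass vs. other rooted macrophytes.

    Under the ``model_overlap`` rule a SAV cell is seagrass iff the modelled
    potential seagrass distribution covers it; under ``all_seagrass`` /
    ``all_other`` every SAV cell in the region takes that class. Cells
    without SAV stay unlabeled (0).
    """
    require_boolean(sav_mask, "sav_mask")
    require_boolean(seagrass_model, "seagrass_model")
    require_same_grid(sav_mask, seagrass_model, region_rules)
    rules = np.asarray(region_rules.data)
    valid = np.isin(rules, list(REGION_RULES.values()))
    if not valid[sav_mask.data].all():
        bad = sorted(np.unique(rules[sav_mask.data & ~valid]).tolist())
        raise ValueError(f"missing/unknown region rule tags under SAV cells: {bad}")
    out = np.zeros(sav_mask.shape, dtype=np.int16)
    sav = sav_mask.data
    seagrass = (
        (rules == REGION_RULES["all_seagrass"])
        | ((rules == REGION_RULES["model_overlap"]) & seagrass_model.data)
    )
    out[sav & seagrass] = HABITAT_CODES["seagrass"]
    out[sav & ~seagrass] = HABITAT_CODES["other_rooted_macrophytes"]
    return sav_mask.with_data(out)


def patchify(class_raster: GridRaster, connectivity: int = 4) -> list[HabitatPatch]:
    """One patch per connected component per habitat class.

    The sum of patch areas per class equals the labeled cell count times the
    cell area, exactly.
    """
    data = np.asarray(class_raster.data)
    structure = connectivity_structure(connectivity)
    patches: list[HabitatPatch] = []
    for code in sorted(HABITAT_NAMES):
        name = HABITAT_NAMES[code]
        labels, n = ndimage.label(data == code, structure=structure)
        for k in range(1, n + 1):
            rows, cols = np.nonzero(labels == k)
            patches.append(
                HabitatPatch(
                    id=f"{name}_{k:03d}",
                    habitat_class=name,
                    rows=rows,
                    cols=cols,
                    raster=class_raster,
                )
            )
    return patches


def assign_subbasins(patches: list[HabitatPatch], basins) -> None:
    """Label each patch with the basin holding the majority of its cells.

    Patches outside every basin get the nearest basin's label. Modifies the
    patches in place.
    """
    if not basins:
        return
    for patch in patches:
        x, y = patch.cell_centers()
        counts = {
            basin.id: int(np.count_nonzero(shapely.contains_xy(basin.polygon, x, y)))
            for basin in basins
        }
        best = max(counts, key=lambda b: counts[b])
        if counts[best] > 0:
            patch.subbasin = best
        else:
            pts = shapely.points(x, y)
            dists = [min(basin.polygon.distance(p) for p in pts) for basin in basins]
            patch.subbasin = basins[int(np.argmin(dists))].id
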