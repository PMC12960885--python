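"""Coastal analysis domain: low-lying land adjacent to the sea plus the
satellite-feasible submerged area.

The land part of the domain is every cell at or below an elevation threshold
(default 2 m) that is hydrologically reachable from the sea through a
connected path of such cells; man-made barrier cells (roads) block the path
and lake cells are not marine connections. The submerged part is the
feasibility mask of the satellite-derived vegetation layer, taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import GridRaster, require_boolean, require_same_grid

__all__ = [
    "CoastalDomain",
    "delimit_coastal_land",
    "submerged_domain",
    "clip_to_domain",
    "connectivity_structure",
]


def connectivity_structure(connectivity: int) -> np.ndarray:
    """Binary structure for 4- (edge-sharing) or 8-connectivity."""
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


@dataclass(frozen=True)
class CoastalDomain:
    """Delimited coastal analysis domain (land fringe + submerged feasibility)."""

    land_mask: GridRaster
    submerged_mask: GridRaster
    elevation_threshold: float = 2.0

    def __post_init__(self) -> None:
        require_boolean(self.land_mask, "land_mask")
        require_boolean(self.submerged_mask, "submerged_mask")
        require_same_grid(self.land_mask, self.submerged_mask)

    @property
    def land_area_km2(self) -> float:
        return self.land_mask.area_km2()

    @property
    def submerged_area_km2(self) -> float:
        return self.submerged_mask.area_km2()

    @property
    def combined_area_km2(self) -> float:
        return self.land_area_km2 + self.submerged_area_km2

    @property
    def combined_mask(self) -> GridRaster:
        return self.land_mask.with_data(self.land_mask.data | self.submerged_mask.data)


def delimit_coastal_land(
    elevation: GridRaster,
    sea_mask: GridRaster,
    barriers: GridRaster | None = None,
    lakes: GridRaster | None = None,
    threshold: float = 2.0,
    connectivity: int = 4,
) -> GridRaster:
    """Land cells at or below ``threshold`` elevation that are reachable from the sea.

    Reachability is a flood fill seeded at sea cells over the set
    {sea} ∪ {land with elevation ≤ threshold}; barrier and lake cells are
    removed from the traversable set, so a road severs the area behind it and
    a lake can neither belong to the domain nor act as a conduit. Ties at
    exactly the threshold elevation are included ("2 m or less").
    """
    if threshold <= 0:
        raise ValueError(f"elevation threshold must be positive, got {threshold}")
    require_boolean(sea_mask, "sea_mask")
    rasters = [elevation, sea_mask]
    for extra, name in ((barriers, "barriers"), (lakes, "lakes")):
        if extra is not None:
            require_boolean(extra, name)
            rasters.append(extra)
    require_same_grid(*rasters)

    sea = sea_mask.data
    candidate = (np.asarray(elevation.data, dtype=float) <= threshold) & ~sea
    if barriers is not None:
        candidate &= ~barriers.data
    if lakes is not None:
        candidate &= ~lakes.data

    traversable = candidate | sea
    labels, n = ndimage.label(traversable, structure=connectivity_structure(connectivity))
    if n == 0:
        return sea_mask.with_data(np.zeros_like(sea))
    sea_labels = np.unique(labels[sea])
    sea_labels = sea_labels[sea_labels > 0]
    reachable = np.isin(labels, sea_labels)
    return sea_mask.with_data(candidate & reachable)


def submerged_domain(feasibility_mask: GridRaster) -> GridRaster:
    """Validated pass-through of the submerged feasibility layer."""
    require_boolean(feasibility_mask, "feasibility_mask")
    return feasibility_mask.with_data(feasibility_mask.data.copy())


def clip_to_domain(layer, domain: CoastalDomain):
    """Restrict a raster (or list of cell-based patches) to the combined domain.

    Raster layers are masked (False/0 outside); habitat patches lose the cells
    that fall outside, and patches left empty are dropped. The clipped area
    never exceeds the input area; an empty domain yields an empty result.
    """
    mask = domain.combined_mask.data
    if isinstance(layer, GridRaster):
        require_same_grid(layer, domain.land_mask)
        if layer.data.dtype == np.bool_:
            return layer.with_data(layer.data & mask)
        return layer.with_data(np.where(mask, layer.data, 0))
    clipped = []
    for patch in layer:
        keep = mask[patch.rows, patch.cols]
        if keep.any():
            clipped.append(patch.subset(keep))
    return clipped
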