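"""Synthetic coastal landscapes with known ground truth.

Every downstream stage (coastal delimitation, habitat compilation, pressure
index, protection overlay, quality control) is testable against scenes whose
true coastal mask, habitat classes, per-patch stressor distance classes,
basin pressure values and protection splits are fixed at construction time.

Scene anatomy (planar metres, row 0 = south, col 0 = west):

* a wiggly north-south coastline separates sea (west) from land (east);
  elevation ramps linearly inland, so the coastal fringe (elevation <= 2 m)
  is an analytically known strip along the shore;
* one optional headland bulge carries a coastal road that severs the fringe
  behind it (a known, constructed cell set), and small lakes sit inside the
  fringe between habitat bands;
* habitat patches are random connected blobs (seeded region growing), one
  per horizontal band: wetland classes on the fringe, SAV classes hugging
  the shoreline on the sea side;
* per patch, urban and agricultural stressor blocks are placed due east at
  the midpoint of the requested distance class, then every patch's nearest
  distance to every stressor type is re-verified exactly (configuration
  error on violation) -- so the requested classes are guaranteed;
* drainage basins are horizontal land bands whose modified-land proportion
  is topped up to a target by painting far-field agricultural cells;
* protected-area rectangles cover whole patches, lowest cumulative pressure
  first, until a target share of habitat area is protected;
* the 5-year SAV layer draws per-cell year counts Binomial(5, p) inside
  true SAV and Binomial(5, q) commission noise elsewhere in the feasibility
  strip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union

from .grid import GridRaster
from .habitats import (
    HABITAT_CODES,
    HABITAT_NAMES,
    HABITAT_REALMS,
    LANDCOVER_CODES,
    REGION_RULES,
    HabitatPatch,
)
from .pressure import (
    DistanceClassTable,
    DrainageBasin,
    HIGH_PRESSURE_THRESHOLD,
    classify_distance,
    classify_proportion,
)
from .qc import FieldPoint

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "TruthRecord",
    "SyntheticScene",
    "generate_landscape",
    "generate_field_points",
    "recovery_config",
]

# midpoint of each distance-class interval, metres (class 0 = no stressor)
DISTANCE_TARGETS = {4: 50.0, 3: 250.0, 2: 700.0, 1: 2500.0}
_CLASS_INTERVALS = {4: (0.0, 100.0), 3: (100.0, 400.0), 2: (400.0, 1000.0),
                    1: (1000.0, 5000.0), 0: (5000.0, math.inf)}

_SAV_CLASSES = ("seagrass", "other_rooted_macrophytes")
_WETLAND_CLASSES = ("open_wetland", "forested_wetland")


class ConfigurationError(ValueError):
    """The requested scene layout is infeasible on the requested grid."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic coastal scene."""

    seed: int = 0
    grid_width: int = 450
    grid_height: int = 768
    cell_size: float = 10.0
    sea_fraction: float = 0.35
    coastal_relief: float = 15.0  # max elevation (m) at the inland edge
    n_patches_per_class: int = 2
    patch_classes: tuple[str, ...] | None = None  # per-band override
    patch_cells: int = 120
    sav_detection_prob: float = 0.97
    sav_false_prob: float = 0.15
    stressor_layout: tuple[tuple[int, int], ...] | None = None  # (urban, agri) per patch
    n_basins: int = 4
    basin_modified_props: tuple[float, ...] = (10.0, 30.0, 50.0, 70.0)
    n_protected: int = 3
    protected_cover_target: float = 0.31
    n_field_points: int = 80
    gps_noise_sd: float = 10.0
    road_barrier: bool = True
    n_lakes: int = 2
    coast_amplitude_cells: int = 8

    def __post_init__(self) -> None:
        for name in ("sea_fraction", "sav_detection_prob", "sav_false_prob",
                     "protected_cover_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if self.grid_width < 40 or self.grid_height < 40:
            raise ConfigurationError("grid must be at least 40x40 cells")
        if self.coastal_relief <= 2.0:
            raise ConfigurationError("coastal_relief must exceed the 2 m fringe threshold")
        if self.patch_cells < 1:
            raise ConfigurationError("patch_cells must be positive")
        if self.n_field_points < 0:
            raise ConfigurationError("n_field_points must be non-negative")
        if len(self.basin_modified_props) != self.n_basins:
            raise ConfigurationError(
                "basin_modified_props must list one proportion per basin"
            )
        for cls in self.resolved_patch_classes():
            if cls not in HABITAT_CODES:
                raise ConfigurationError(f"unknown habitat class {cls!r}")
        layout = self.resolved_stressor_layout()
        if len(layout) != len(self.resolved_patch_classes()):
            raise ConfigurationError("stressor_layout must assign one entry per patch")
        for u, a in layout:
            if u not in _CLASS_INTERVALS or a not in _CLASS_INTERVALS:
                raise ConfigurationError(f"distance classes must lie in 0..4, got {(u, a)}")

    # -- derived layout -----------------------------------------------------
    def resolved_patch_classes(self) -> tuple[str, ...]:
        """Habitat class per band, south to north.

        SAV classes go to the coast-compatible latitude bands: seagrass in
        the southernmost bands, other rooted macrophytes in the northernmost
        (mirroring the latitudinal classification rule); wetlands fill the
        middle.
        """
        if self.patch_classes is not None:
            return tuple(self.patch_classes)
        n = self.n_patches_per_class
        wetlands = []
        for i in range(n):
            wetlands += ["open_wetland", "forested_wetland"]
        return tuple(["seagrass"] * n + wetlands + ["other_rooted_macrophytes"] * n)

    def resolved_stressor_layout(self) -> tuple[tuple[int, int], ...]:
        if self.stressor_layout is not None:
            return tuple(tuple(entry) for entry in self.stressor_layout)
        cycle = [(4, 4), (3, 2), (2, 3), (2, 2)]
        n = len(self.resolved_patch_classes())
        return tuple(cycle[i % len(cycle)] for i in range(n))


@dataclass
class TruthRecord:
    """Ground truth fixed at scene construction."""

    true_coastal_mask: GridRaster
    true_habitat_class: GridRaster
    patch_table: pd.DataFrame  # per-patch classes, distance classes, v_basin, flags
    true_high_pressure_fraction: dict[str, float]
    true_protected_fraction: dict[str, float]


@dataclass
class SyntheticScene:
    """A complete generated landscape bundle plus its ground-truth record."""

    config: SimulationConfig
    elevation: GridRaster
    sea_mask: GridRaster
    landcover: GridRaster
    sav_year_count: GridRaster
    seagrass_model: GridRaster
    feasibility_mask: GridRaster
    region_rules: GridRaster
    basins: list[DrainageBasin]
    protected: list[shapely.Geometry]
    protected_habitat_polys: list[tuple[shapely.Geometry, str]]
    urban_polygons: list[shapely.Geometry]
    field_points: list[FieldPoint]
    truth: TruthRecord

    @property
    def cell_size(self) -> float:
        return self.config.cell_size

    def habitat_cell_count(self) -> int:
        return int(np.count_nonzero(self.truth.true_habitat_class.data))


# ---------------------------------------------------------------------------
# generation helpers
# ---------------------------------------------------------------------------

def _grow_blob(
    rng: np.random.Generator,
    allowed: np.ndarray,
    seed_cell: tuple[int, int],
    n_cells: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random region growing to exactly ``n_cells`` 4-connected cells."""
    n_rows, n_cols = allowed.shape
    if not allowed[seed_cell]:
        raise ConfigurationError(f"blob seed {seed_cell} falls outside its allowed region")
    in_blob = {seed_cell}
    frontier = [seed_cell]
    while len(in_blob) < n_cells:
        if not frontier:
            raise ConfigurationError(
                f"allowed region exhausted while growing a {n_cells}-cell patch"
            )
        idx = int(rng.integers(len(frontier)))
        r, c = frontier[idx]
        neighbours = [
            (rr, cc)
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
            if 0 <= rr < n_rows and 0 <= cc < n_cols
            and allowed[rr, cc] and (rr, cc) not in in_blob
        ]
        if not neighbours:
            frontier.pop(idx)
            continue
        nxt = neighbours[int(rng.integers(len(neighbours)))]
        in_blob.add(nxt)
        frontier.append(nxt)
    cells = sorted(in_blob)
    rows = np.array([r for r, _ in cells])
    cols = np.array([c for _, c in cells])
    return rows, cols


def _min_distance_cells(rows_a, cols_a, rows_b, cols_b, cell_size: float) -> float:
    """Brute-force minimum centre-to-centre distance between two cell sets (m)."""
    dr = rows_a[:, None] - rows_b[None, :]
    dc = cols_a[:, None] - cols_b[None, :]
    return float(np.sqrt(dr * dr + dc * dc).min() * cell_size)


def generate_landscape(config: SimulationConfig) -> SyntheticScene:
    """Build a complete synthetic scene; deterministic for a fixed config."""
    rng = np.random.default_rng(config.seed)
    W, H, cs = config.grid_width, config.grid_height, config.cell_size
    patch_classes = config.resolved_patch_classes()
    layout = config.resolved_stressor_layout()
    n_patches = len(patch_classes)
    if n_patches == 0:
        raise ConfigurationError("at least one habitat patch is required")
    band = H // n_patches
    if band < 42:
        raise ConfigurationError(
            f"grid height {H} is too small for {n_patches} patch bands (need >= 42 rows each)"
        )

    # -- coastline and elevation -------------------------------------------
    rows_idx = np.arange(H)
    if config.sea_fraction == 0.0:
        coast_x = np.zeros(H, dtype=int)
    else:
        base = int(round(config.sea_fraction * W))
        amp = config.coast_amplitude_cells
        wiggle = amp * np.sin(2 * np.pi * rows_idx / (H / 2.3))
        coast_x = np.clip(np.round(base + wiggle).astype(int), 1, W - 10)

    # headland bulge carrying the severing road
    bulge_rows = np.zeros(H, dtype=bool)
    road_mask = np.zeros((H, W), dtype=bool)
    severed = np.zeros((H, W), dtype=bool)
    bulge_width = 20
    if config.road_barrier and config.sea_fraction > 0.0 and n_patches >= 2:
        rb = (n_patches // 2) * band - 8
        rb2 = rb + 14
        if rb >= 1 and rb2 <= H - 2:
            bulge_rows[rb : rb2 + 1] = True
            coast_x[bulge_rows] += bulge_width

    col_idx = np.arange(W)
    sea = col_idx[None, :] < coast_x[:, None]
    K = W - coast_x.min()
    k_land = col_idx[None, :] - coast_x[:, None] + 1  # 1 at the first land column
    elevation = np.where(sea, -2.0, config.coastal_relief * k_land / K)
    f_cols = int(math.floor(2.0 * K / config.coastal_relief))  # fringe width, cells
    fringe = (~sea) & (k_land <= f_cols)

    if config.road_barrier and bulge_rows.any():
        adj = max(coast_x[np.flatnonzero(bulge_rows)[0] - 1],
                  coast_x[np.flatnonzero(bulge_rows)[-1] + 1])
        x_road = adj + f_cols
        if x_road >= W:
            raise ConfigurationError("grid too narrow for the coastal road headland")
        road_mask[bulge_rows, x_road] = True
        severed[bulge_rows, x_road + 1 :] = fringe[bulge_rows, x_road + 1 :]

    # lakes inside the fringe, on band boundaries away from the bulge
    lake_mask = np.zeros((H, W), dtype=bool)
    if config.n_lakes > 0 and config.sea_fraction > 0.0 and n_patches >= 2:
        boundaries = [k for k in range(1, n_patches) if k != n_patches // 2]
        for k in boundaries[: config.n_lakes]:
            r0 = k * band - 3
            rows_l = slice(max(r0, 0), min(r0 + 6, H))
            for r in range(rows_l.start, rows_l.stop):
                c0 = coast_x[r] + 4
                lake_mask[r, c0 : min(c0 + 8, W)] = True
        lake_mask &= fringe & ~road_mask & ~severed

    allowed_fringe = fringe & ~road_mask & ~lake_mask & ~severed
    if config.sea_fraction > 0.0:
        true_coastal = allowed_fringe.copy()
    else:
        true_coastal = np.zeros((H, W), dtype=bool)  # no sea, no coast

    # -- regions and feasibility -------------------------------------------
    region = np.zeros((H, W), dtype=np.int16)
    t1, t2 = H // 3, 2 * H // 3
    region[:t1] = REGION_RULES["all_seagrass"]
    region[t1:t2] = REGION_RULES["model_overlap"]
    region[t2:] = REGION_RULES["all_other"]

    f_sav = 40  # feasibility strip width (cells) seaward of the coast
    k_sea = coast_x[:, None] - col_idx[None, :]
    feasibility = sea & (k_sea <= f_sav)

    # -- habitat patches -----------------------------------------------------
    occupied = np.zeros((H, W), dtype=bool)
    habitat = np.zeros((H, W), dtype=np.int16)
    patch_cells_list: list[tuple[np.ndarray, np.ndarray]] = []
    model_mask = np.zeros((H, W), dtype=bool)
    sav_hug = 20  # SAV blobs grow within this many cells of the shore

    for i, cls in enumerate(patch_classes):
        center = i * band + band // 2
        lo, hi = center - 12, center + 12
        if not (i * band <= lo and hi < (i + 1) * band):
            raise ConfigurationError("patch band too narrow for the 25-row patch window")
        window = np.zeros((H, W), dtype=bool)
        window[lo : hi + 1] = True
        if HABITAT_REALMS[cls] == "land":
            allowed = allowed_fringe & window & ~occupied
            seed_col = coast_x[center] + 2 if config.sea_fraction > 0 else 2
        else:
            if config.sea_fraction == 0.0:
                raise ConfigurationError(f"cannot place submerged habitat {cls!r} without sea")
            if coast_x.min() <= sav_hug + 1:
                raise ConfigurationError("sea strip too narrow for SAV habitat blobs")
            allowed = sea & (k_sea <= sav_hug) & window & ~occupied
            seed_col = coast_x[center] - 2
            rules_here = region[center, seed_col]
            if cls == "seagrass" and rules_here == REGION_RULES["all_other"]:
                raise ConfigurationError(
                    f"patch {i}: seagrass requested in an all-other region band"
                )
            if cls == "other_rooted_macrophytes" and rules_here == REGION_RULES["all_seagrass"]:
                raise ConfigurationError(
                    f"patch {i}: other rooted macrophytes requested in an all-seagrass band"
                )
        rows_p, cols_p = _grow_blob(rng, allowed, (center, seed_col), config.patch_cells)
        # SAV bands must not straddle a region-rule boundary
        if HABITAT_REALMS[cls] == "submerged":
            if len(np.unique(region[rows_p, cols_p])) != 1:
                raise ConfigurationError(f"patch {i} straddles a region-rule boundary")
            if region[rows_p[0], cols_p[0]] == REGION_RULES["model_overlap"] and cls == "seagrass":
                r0, r1 = rows_p.min() - 1, rows_p.max() + 2
                c0, c1 = cols_p.min() - 1, cols_p.max() + 2
                model_mask[max(r0, 0) : r1, max(c0, 0) : c1] = True
        habitat[rows_p, cols_p] = HABITAT_CODES[cls]
        occupied[rows_p, cols_p] = True
        patch_cells_list.append((rows_p, cols_p))

    # -- land cover ---------------------------------------------------------
    landcover = np.zeros((H, W), dtype=np.int16)
    landcover[lake_mask] = LANDCOVER_CODES["lake"]
    landcover[road_mask] = LANDCOVER_CODES["road"]
    landcover[habitat == HABITAT_CODES["open_wetland"]] = LANDCOVER_CODES["open_wetland"]
    landcover[habitat == HABITAT_CODES["forested_wetland"]] = LANDCOVER_CODES["forested_wetland"]

    # -- stressor placement --------------------------------------------------
    urban_boxes: list[tuple[int, int, int, int]] = []  # (r0, r1, c0, c1) inclusive
    blocked = occupied | lake_mask | road_mask | sea
    for i, (cls_u, cls_a) in enumerate(layout):
        rows_p, cols_p = patch_cells_list[i]
        x_e = int(cols_p.max())
        y_e = int(rows_p[cols_p == x_e].max())
        for cls, code, row_offset in (
            (cls_u, LANDCOVER_CODES["urban"], 0),
            (cls_a, LANDCOVER_CODES["agriculture"], 6),
        ):
            if cls == 0:
                continue
            d_cells = int(round(DISTANCE_TARGETS[cls] / cs))
            lo_m, hi_m = _CLASS_INTERVALS[cls]
            placed = False
            for shift in range(0, max(2, int(hi_m / cs) - d_cells)):
                x_a = x_e + d_cells + shift
                r0, r1 = y_e + row_offset - 2, y_e + row_offset + 2
                c0, c1 = x_a, x_a + 4
                if c1 >= W or r0 < 0 or r1 >= H:
                    raise ConfigurationError(
                        f"patch {i}: distance class {cls} exceeds the grid extent"
                    )
                block = blocked[r0 : r1 + 1, c0 : c1 + 1]
                on_sea = sea[r0 : r1 + 1, c0 : c1 + 1]
                if block.any() or on_sea.any():
                    continue
                rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                                     indexing="ij")
                d = _min_distance_cells(rows_p, cols_p, rr.ravel(), cc.ravel(), cs)
                if not (lo_m < d <= hi_m):
                    continue
                landcover[r0 : r1 + 1, c0 : c1 + 1] = code
                blocked[r0 : r1 + 1, c0 : c1 + 1] = True
                if code == LANDCOVER_CODES["urban"]:
                    urban_boxes.append((r0, r1, c0, c1))
                placed = True
                break
            if not placed:
                raise ConfigurationError(
                    f"patch {i}: no feasible position for distance class {cls}"
                )

    # -- drainage basins -----------------------------------------------------
    # Top-up agriculture is painted only east of a safety margin so it cannot
    # undercut any patch's assigned agricultural distance class.
    max_patch_col = max(int(cols_p.max()) for _, cols_p in patch_cells_list)
    agri_lo = max(_CLASS_INTERVALS[a][0] for _, a in layout) if layout else 0.0
    safe_col = max_patch_col + int(math.ceil(agri_lo / cs)) + 1

    basins: list[DrainageBasin] = []
    basin_of_patch = np.full(n_patches, -1)
    if config.n_basins > 0:
        bb = H // config.n_basins
        modified_codes = (LANDCOVER_CODES["agriculture"], LANDCOVER_CODES["urban"])
        for j in range(config.n_basins):
            r_lo = j * bb
            r_hi = H if j == config.n_basins - 1 else (j + 1) * bb
            strips = [
                box(coast_x[r] * cs, r * cs, W * cs, (r + 1) * cs)
                for r in range(r_lo, r_hi)
            ]
            polygon = unary_union(strips)
            in_basin = np.zeros((H, W), dtype=bool)
            in_basin[r_lo:r_hi] = ~sea[r_lo:r_hi]
            n_cells = int(in_basin.sum())
            if n_cells == 0:
                raise ConfigurationError(f"basin {j} has no land cells")
            existing = int(np.isin(landcover, modified_codes)[in_basin].sum())
            target = int(round(config.basin_modified_props[j] / 100.0 * n_cells))
            deficit = max(0, target - existing)
            if deficit:
                paintable = in_basin & ~blocked & (landcover == 0) & ~severed
                paintable[:, : min(safe_col, W)] = False
                paint_rows, paint_cols = np.nonzero(paintable)
                order = np.lexsort((paint_rows, -paint_cols))  # far-east columns first
                if deficit > len(order):
                    raise ConfigurationError(
                        f"basin {j}: cannot reach {config.basin_modified_props[j]}% modified land"
                    )
                sel = order[:deficit]
                landcover[paint_rows[sel], paint_cols[sel]] = LANDCOVER_CODES["agriculture"]
                blocked[paint_rows[sel], paint_cols[sel]] = True
            achieved = 100.0 * max(target, existing) / n_cells
            basins.append(
                DrainageBasin(
                    id=f"basin_{j}",
                    polygon=polygon,
                    modified_proportion=achieved,
                    v_basin=int(classify_proportion(achieved)),
                )
            )
        for i in range(n_patches):
            center = i * band + band // 2
            basin_of_patch[i] = min(center // bb, config.n_basins - 1)

    # -- exact placement-contract verification -------------------------------
    for code_name, idx in (("urban", 0), ("agriculture", 1)):
        mask = landcover == LANDCOVER_CODES[code_name]
        dist = (
            ndimage.distance_transform_edt(~mask) * cs if mask.any()
            else np.full((H, W), np.inf)
        )
        for i, assignment in enumerate(layout):
            cls = assignment[idx]
            rows_p, cols_p = patch_cells_list[i]
            d = float(dist[rows_p, cols_p].min())
            lo_m, hi_m = _CLASS_INTERVALS[cls]
            if not (lo_m < d <= hi_m or (cls == 0 and math.isinf(d))):
                raise ConfigurationError(
                    f"patch {i}: nearest {code_name} distance {d:.0f} m falls outside "
                    f"requested class {cls} ({lo_m:.0f}-{hi_m:.0f} m); "
                    "layout is infeasible on this grid"
                )

    # -- per-patch truth table -----------------------------------------------
    records = []
    counters: dict[str, int] = {}
    for i, cls in enumerate(patch_classes):
        counters[cls] = counters.get(cls, 0) + 1
        u_cls, a_cls = layout[i]
        v_basin = basins[basin_of_patch[i]].v_basin if basins else 0.0
        cumulative = u_cls + a_cls + v_basin
        records.append(
            {
                "patch_id": f"{cls}_{counters[cls]:03d}",
                "habitat_class": cls,
                "band": i,
                "urban_class": u_cls,
                "agri_class": a_cls,
                "v_basin": float(v_basin),
                "basin_id": f"basin_{basin_of_patch[i]}" if basins else "",
                "cumulative": float(cumulative),
                "high_pressure": bool(cumulative >= HIGH_PRESSURE_THRESHOLD),
                "n_cells": len(patch_cells_list[i][0]),
            }
        )
    patch_table = pd.DataFrame.from_records(records)

    # -- protected areas (lowest pressure first, whole patches) --------------
    protected_geoms: list[shapely.Geometry] = []
    protected_flags = np.zeros(n_patches, dtype=bool)
    if config.n_protected > 0 and config.protected_cover_target > 0 and n_patches > 0:
        total_cells = int(patch_table["n_cells"].sum())
        order = patch_table.sort_values(["cumulative", "band"]).index.to_numpy()
        covered = 0
        for i in order:
            if len(protected_geoms) >= config.n_protected:
                break
            if covered >= config.protected_cover_target * total_cells:
                break
            rows_p, cols_p = patch_cells_list[i]
            r0, r1 = rows_p.min() - 2, rows_p.max() + 3
            c0, c1 = cols_p.min() - 2, cols_p.max() + 3
            protected_geoms.append(box(c0 * cs, r0 * cs, c1 * cs, r1 * cs))
            protected_flags[i] = True
            covered += len(rows_p)
    patch_table["protected"] = protected_flags

    # NNK-style vector wetland inventory: exact footprints of protected wetland patches
    protected_habitat_polys = []
    for i, cls in enumerate(patch_classes):
        if protected_flags[i] and HABITAT_REALMS[cls] == "land":
            rows_p, cols_p = patch_cells_list[i]
            cell_boxes = [
                box(c * cs, r * cs, (c + 1) * cs, (r + 1) * cs)
                for r, c in zip(rows_p, cols_p)
            ]
            protected_habitat_polys.append((unary_union(cell_boxes), cls))

    # -- truth fractions ------------------------------------------------------
    def _fractions(flag_col: str) -> dict[str, float]:
        out: dict[str, float] = {}
        total = patch_table["n_cells"].sum()
        for cls in HABITAT_CODES:
            sub = patch_table[patch_table["habitat_class"] == cls]
            if len(sub):
                out[cls] = float(
                    sub.loc[sub[flag_col], "n_cells"].sum() / sub["n_cells"].sum()
                )
        out["all"] = float(
            patch_table.loc[patch_table[flag_col], "n_cells"].sum() / total
        ) if total else 0.0
        return out

    # -- SAV year counts ------------------------------------------------------
    sav_true = np.isin(habitat, [HABITAT_CODES[c] for c in _SAV_CLASSES])
    counts = np.zeros((H, W), dtype=np.int16)
    if sav_true.any():
        counts[sav_true] = rng.binomial(5, config.sav_detection_prob, int(sav_true.sum()))
    commission = feasibility & ~sav_true
    if commission.any() and config.sav_false_prob > 0:
        counts[commission] = rng.binomial(5, config.sav_false_prob, int(commission.sum()))

    grid_kwargs = dict(cell_size=cs, x0=0.0, y0=0.0)
    truth = TruthRecord(
        true_coastal_mask=GridRaster(true_coastal, **grid_kwargs),
        true_habitat_class=GridRaster(habitat, **grid_kwargs),
        patch_table=patch_table,
        true_high_pressure_fraction=_fractions("high_pressure"),
        true_protected_fraction=_fractions("protected"),
    )
    scene = SyntheticScene(
        config=config,
        elevation=GridRaster(elevation, **grid_kwargs),
        sea_mask=GridRaster(sea, **grid_kwargs),
        landcover=GridRaster(landcover, **grid_kwargs),
        sav_year_count=GridRaster(counts, **grid_kwargs),
        seagrass_model=GridRaster(model_mask, **grid_kwargs),
        feasibility_mask=GridRaster(feasibility, **grid_kwargs),
        region_rules=GridRaster(region, **grid_kwargs),
        basins=basins,
        protected=protected_geoms,
        protected_habitat_polys=protected_habitat_polys,
        urban_polygons=[
            box(c0 * cs, r0 * cs, (c1 + 1) * cs, (r1 + 1) * cs)
            for r0, r1, c0, c1 in urban_boxes
        ],
        field_points=[],
        truth=truth,
    )
    scene.field_points = generate_field_points(
        scene, config.n_field_points, config.gps_noise_sd, rng=rng
    )
    return scene


def generate_field_points(
    scene: SyntheticScene,
    n: int,
    gps_noise_sd: float,
    rng: np.random.Generator | None = None,
) -> list[FieldPoint]:
    """Ground-truthed survey points with isotropic Gaussian positional noise.

    Each point records the true habitat class of the cell it was sampled
    from; its coordinate is the cell centre displaced by N(0, sd²) in x and y.
    """
    if n < 0:
        raise ValueError(f"number of field points must be non-negative, got {n}")
    habitat = scene.truth.true_habitat_class.data
    rows, cols = np.nonzero(habitat)
    if n > 0 and len(rows) == 0:
        raise ValueError("scene has no habitat cells to sample field points from")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([scene.config.seed, 20260920]))
    if n == 0:
        return []
    sel = rng.choice(len(rows), size=n, replace=True)
    x, y = scene.truth.true_habitat_class.cell_center(rows[sel], cols[sel])
    noise = rng.normal(0.0, gps_noise_sd, size=(n, 2)) if gps_noise_sd > 0 else np.zeros((n, 2))
    return [
        FieldPoint(
            x=float(xi + dx),
            y=float(yi + dy),
            observed_class=HABITAT_NAMES[int(habitat[r, c])],
            source="synthetic_survey",
        )
        for xi, yi, (dx, dy), r, c in zip(x, y, noise, rows[sel], cols[sel])
    ]


def recovery_config(high_fraction: float, seed: int = 0) -> SimulationConfig:
    """Four equal-size patches whose true high-pressure area fraction is exact.

    ``high_fraction`` must be a multiple of 0.25. High patches get urban and
    agricultural stressors in the innermost distance class (4 + 4 = 8 >= 6);
    low patches get both in the 400-1000 m class (2 + 2 = 4 < 6); basin
    modified proportions stay below 20% so the basin component is 0. SAV
    detection is perfect and commission-free so the compiled map equals the
    constructed one.
    """
    n_high = round(high_fraction * 4)
    if not math.isclose(n_high / 4, high_fraction):
        raise ValueError("high_fraction must be a multiple of 0.25")
    layout = tuple([(4, 4)] * n_high + [(2, 2)] * (4 - n_high))
    return SimulationConfig(
        seed=seed,
        grid_width=360,
        grid_height=384,
        patch_classes=("seagrass", "open_wetland", "other_rooted_macrophytes",
                       "forested_wetland"),
        stressor_layout=layout,
        sav_detection_prob=1.0,
        sav_false_prob=0.0,
        n_basins=2,
        basin_modified_props=(0.0, 0.0),
        n_protected=2,
        protected_cover_target=0.3,
        n_field_points=40,
        gps_noise_sd=0.0,
        n_lakes=1,
    )
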