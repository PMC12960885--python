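"""End-to-end orchestration: simulate (or load) a scene, delimit the coast,
compile habitats, score pressure, overlay protection and run quality control.

Every numeric constant of the analysis lives on :class:`PipelineConfig` with
the standard default (2 m elevation limit, 100/400/1000/5000 m distance
classes, 20/40/60/80 % proportion classes, high-pressure threshold 6, 500 m
basin link radius, 30 m QC radius, 4-of-5-year SAV persistence); every run is
fully deterministic under a fixed config, and re-running writes byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace as dataclasses_replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coastal import CoastalDomain, clip_to_domain, delimit_coastal_land, submerged_domain
from .grid import GridRaster
from .habitats import (
    HABITAT_CODES,
    LANDCOVER_CODES,
    HabitatPatch,
    assign_subbasins,
    classify_sav,
    filter_sav_persistence,
    merge_wetland_raster,
    patchify,
)
from .io import write_ascii_grid, write_geojson
from .pressure import (
    DistanceClassTable,
    HIGH_PRESSURE_THRESHOLD,
    ProportionClassTable,
    PressureScore,
    score_patches,
)
from .protection import (
    TTestResult,
    compare_pressure_inside_outside,
    compute_percent,
    overlay_protection,
    summarize_areas,
)
from .qc import QCReport, SAVReference, match_points, select_persistence_threshold
from .synthetic import SimulationConfig, SyntheticScene, generate_landscape

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "compute_percent"]


@dataclass(frozen=True)
class PipelineConfig:
    """All paths/constants of one pipeline run (defaults = standard analysis)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    elevation_threshold: float = 2.0
    connectivity: int = 4
    distance_table: DistanceClassTable = field(default_factory=DistanceClassTable)
    proportion_table: ProportionClassTable = field(default_factory=ProportionClassTable)
    high_pressure_threshold: float = HIGH_PRESSURE_THRESHOLD
    link_radius_m: float = 500.0
    qc_max_dist_m: float = 30.0
    sav_min_years: int = 4
    n_sav_reference: int = 2000
    ttest_unit: str = "stratum"
    out_dir: str | None = None

    def digest(self) -> str:
        # exclude the output path: the digest identifies the analysis, not where it lands
        payload = repr(dataclasses_replace(self, out_dir=None)).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything one run computed, plus provenance."""

    config: PipelineConfig
    scene: SyntheticScene
    domain: CoastalDomain
    patches: list[HabitatPatch]
    scores: list[PressureScore]
    protection: pd.DataFrame
    summary: pd.DataFrame
    qc_report: QCReport
    sav_best_k: int | None
    sav_threshold_table: pd.DataFrame | None
    ttest: TTestResult | None
    high_pressure_fraction: dict[str, float]
    provenance: dict

    def scores_frame(self) -> pd.DataFrame:
        prot = dict(zip(self.protection["patch_id"], self.protection["protected_area_km2"]))
        rows = []
        for patch, score in zip(self.patches, self.scores):
            rows.append(
                {
                    "patch_id": patch.id,
                    "habitat_class": patch.habitat_class,
                    "realm": patch.realm,
                    "subbasin": patch.subbasin,
                    "n_cells": patch.n_cells,
                    "area_km2": patch.area_km2,
                    "v_agri": score.v_agri,
                    "v_urban": score.v_urban,
                    "v_basin": score.v_basin,
                    "cumulative": score.cumulative,
                    "high_pressure": score.high_pressure,
                    "basin_excluded": score.basin_excluded,
                    "protected_area_km2": prot.get(patch.id, 0.0),
                }
            )
        return pd.DataFrame.from_records(rows)


def _sample_sav_references(scene: SyntheticScene, n: int, seed: int) -> list[SAVReference]:
    """Presence/absence reference points drawn from the scene's ground truth."""
    habitat = scene.truth.true_habitat_class.data
    sav_codes = [HABITAT_CODES["seagrass"], HABITAT_CODES["other_rooted_macrophytes"]]
    present = np.isin(habitat, sav_codes)
    absent = scene.feasibility_mask.data & ~present
    if not present.any() or not absent.any():
        return []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1129]))
    refs = []
    for mask, flag in ((present, True), (absent, False)):
        rows, cols = np.nonzero(mask)
        sel = rng.choice(len(rows), size=min(n // 2, len(rows)), replace=False)
        x, y = scene.feasibility_mask.cell_center(rows[sel], cols[sel])
        refs += [SAVReference(float(xi), float(yi), flag) for xi, yi in zip(x, y)]
    return refs


def _high_pressure_fractions(
    patches: list[HabitatPatch], scores: list[PressureScore]
) -> dict[str, float]:
    frame = pd.DataFrame(
        {
            "habitat_class": [p.habitat_class for p in patches],
            "area": [p.area_km2 for p in patches],
            "high": [s.high_pressure for s in scores],
        }
    )
    out = {}
    for cls, sub in frame.groupby("habitat_class"):
        out[str(cls)] = float(sub.loc[sub["high"], "area"].sum() / sub["area"].sum())
    total = frame["area"].sum()
    out["all"] = float(frame.loc[frame["high"], "area"].sum() / total) if total else 0.0
    return out


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run the full analysis on a (simulated) scene and optionally write outputs."""
    scene = generate_landscape(config.simulation)
    lc = scene.landcover

    barriers = lc.with_data(lc.data == LANDCOVER_CODES["road"])
    lakes = lc.with_data(lc.data == LANDCOVER_CODES["lake"])
    land = delimit_coastal_land(
        scene.elevation,
        scene.sea_mask,
        barriers=barriers,
        lakes=lakes,
        threshold=config.elevation_threshold,
        connectivity=config.connectivity,
    )
    domain = CoastalDomain(
        land_mask=land,
        submerged_mask=submerged_domain(scene.feasibility_mask),
        elevation_threshold=config.elevation_threshold,
    )

    wetland = merge_wetland_raster(lc, scene.protected_habitat_polys)
    wetland = clip_to_domain(wetland, domain)
    sav_mask = filter_sav_persistence(scene.sav_year_count, min_years=config.sav_min_years)
    sav_class = clip_to_domain(
        classify_sav(sav_mask, scene.seagrass_model, scene.region_rules), domain
    )
    combined = lc.with_data(
        np.where(wetland.data > 0, wetland.data, sav_class.data).astype(np.int16)
    )
    patches = patchify(combined, connectivity=config.connectivity)
    assign_subbasins(patches, scene.basins)

    agri = lc.with_data(lc.data == LANDCOVER_CODES["agriculture"])
    urban = lc.with_data(lc.data == LANDCOVER_CODES["urban"])
    scores = score_patches(
        patches,
        agri,
        urban,
        scene.basins,
        link_radius=config.link_radius_m,
        distance_table=config.distance_table,
        high_threshold=config.high_pressure_threshold,
    )
    protection = overlay_protection(patches, scene.protected)
    summary = summarize_areas(patches, scores, domain, protection)
    qc_report = match_points(
        scene.field_points, patches, max_dist=config.qc_max_dist_m
    )

    refs = _sample_sav_references(scene, config.n_sav_reference, config.simulation.seed)
    if refs and any(r.present for r in refs) and any(not r.present for r in refs):
        sav_best_k, sav_table = select_persistence_threshold(scene.sav_year_count, refs)
    else:
        sav_best_k, sav_table = None, None

    try:
        ttest = compare_pressure_inside_outside(
            patches, scores, protection, unit=config.ttest_unit
        )
    except ValueError:
        ttest = None

    result = PipelineResult(
        config=config,
        scene=scene,
        domain=domain,
        patches=patches,
        scores=scores,
        protection=protection,
        summary=summary,
        qc_report=qc_report,
        sav_best_k=sav_best_k,
        sav_threshold_table=sav_table,
        ttest=ttest,
        high_pressure_fraction=_high_pressure_fractions(patches, scores),
        provenance={
            "package": "bcmap",
            "version": __version__,
            "config_digest": config.digest(),
            "seed": config.simulation.seed,
            "coastal_land_area_km2": domain.land_area_km2,
            "submerged_area_km2": domain.submerged_area_km2,
            "n_patches": len(patches),
        },
    )
    if config.out_dir is not None:
        write_outputs(result, config.out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write tables, masks and vector layers; deterministic byte-identical files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(out / "area_summary.csv", index=False)
    result.scores_frame().to_csv(out / "pressure_scores.csv", index=False)
    result.qc_report.points.to_csv(out / "qc_points.csv", index=False)
    qc_summary = {
        "n_points": result.qc_report.n_points,
        "n_correct": result.qc_report.n_correct,
        "accuracy_pct": result.qc_report.accuracy_pct,
        "max_dist_m": result.qc_report.max_dist,
        "sav_best_persistence_k": result.sav_best_k,
    }
    with open(out / "qc_summary.json", "w") as fh:
        json.dump(qc_summary, fh, indent=2)
    if result.sav_threshold_table is not None:
        result.sav_threshold_table.to_csv(out / "sav_threshold.csv", index=False)
    if result.ttest is not None:
        with open(out / "ttest.json", "w") as fh:
            json.dump(asdict(result.ttest), fh, indent=2)
    with open(out / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2)
    write_ascii_grid(result.domain.land_mask, out / "coastal_land_mask.asc")
    write_geojson(
        [b.polygon for b in result.scene.basins],
        out / "basins.geojson",
        [
            {"id": b.id, "modified_proportion": b.modified_proportion, "v_basin": b.v_basin}
            for b in result.scene.basins
        ],
    )
    write_geojson(result.scene.protected, out / "protected.geojson")
    return out
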