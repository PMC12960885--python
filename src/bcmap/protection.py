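"""Protected-area overlay, area accounting and inside/outside pressure comparison."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.ops import unary_union

from .coastal import CoastalDomain
from .habitats import HABITAT_CODES, HabitatPatch
from .pressure import PressureScore

__all__ = [
    "TTestResult",
    "overlay_protection",
    "summarize_areas",
    "compare_pressure_inside_outside",
    "compute_percent",
]


@dataclass(frozen=True)
class TTestResult:
    """Classical two-sample Student's t test (pooled variance), two-sided."""

    df: int
    t: float
    p: float
    unit: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p}")


def compute_percent(part: float, whole: float) -> int:
    """Integer percentage, rounded half away from zero (printed-table convention)."""
    if whole <= 0:
        raise ValueError(f"whole must be positive, got {whole}")
    if part < 0:
        raise ValueError(f"part must be non-negative, got {part}")
    ratio = 100.0 * part / whole
    return int(np.floor(ratio + 0.5))


def overlay_protection(
    patches: list[HabitatPatch],
    protected,
) -> pd.DataFrame:
    """Per-patch split of area into protected and unprotected parts (km²).

    Membership is evaluated per cell centre, so the split is exact at cell
    resolution and protected + unprotected equals the patch area.
    """
    geoms = [g for g in protected if not g.is_empty]
    merged = unary_union(geoms) if geoms else None
    records = []
    for patch in patches:
        if merged is None:
            n_prot = 0
        else:
            x, y = patch.cell_centers()
            n_prot = int(np.count_nonzero(shapely.contains_xy(merged, x, y)))
        cell_area = patch.raster.cell_area_km2
        records.append(
            {
                "patch_id": patch.id,
                "habitat_class": patch.habitat_class,
                "protected_area_km2": n_prot * cell_area,
                "unprotected_area_km2": (patch.n_cells - n_prot) * cell_area,
                "protected_share": n_prot / patch.n_cells if patch.n_cells else 0.0,
            }
        )
    return pd.DataFrame.from_records(
        records, columns=["patch_id", "habitat_class", "protected_area_km2",
                          "unprotected_area_km2", "protected_share"]
    )


def summarize_areas(
    patches: list[HabitatPatch],
    scores: list[PressureScore],
    domain: CoastalDomain,
    protection: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Area accounting per habitat class × subbasin, with "all" rollups.

    ``area_pct_of_coastal`` is relative to the delimited coastal area;
    ``high_pressure_pct`` and ``protected_pct`` are relative to the row's own
    habitat area. Percentages are integers, rounded half away from zero.
    """
    coastal_area = domain.combined_area_km2
    if coastal_area <= 0:
        raise ValueError("delimited coastal area is zero; nothing to summarise against")
    if len(scores) != len(patches):
        raise ValueError("every patch needs exactly one pressure score")
    score_by_id = {s.patch_id: s for s in scores}
    prot_by_id = (
        dict(zip(protection["patch_id"], protection["protected_area_km2"]))
        if protection is not None
        else {}
    )

    rows = []
    for patch in patches:
        s = score_by_id[patch.id]
        rows.append(
            {
                "habitat_class": patch.habitat_class,
                "subbasin": patch.subbasin if patch.subbasin is not None else "unassigned",
                "area_km2": patch.area_km2,
                "high_area_km2": patch.area_km2 if s.high_pressure else 0.0,
                "protected_area_km2": prot_by_id.get(patch.id, 0.0),
            }
        )
    per_patch = pd.DataFrame.from_records(rows)

    def _aggregate(frame: pd.DataFrame, habitat_class: str, subbasin: str) -> dict:
        total = frame["area_km2"].sum()
        high = frame["high_area_km2"].sum()
        prot = frame["protected_area_km2"].sum()
        return {
            "habitat_class": habitat_class,
            "subbasin": subbasin,
            "total_area_km2": total,
            "area_pct_of_coastal": compute_percent(total, coastal_area),
            "high_pressure_area_km2": high,
            "high_pressure_pct": compute_percent(high, total) if total > 0 else 0,
            "protected_area_km2": prot,
            "protected_pct": compute_percent(prot, total) if total > 0 else 0,
        }

    out = []
    classes = [c for c in HABITAT_CODES if (per_patch["habitat_class"] == c).any()]
    subbasins = sorted(per_patch["subbasin"].unique())
    for habitat_class in classes + ["all"]:
        class_frame = (
            per_patch if habitat_class == "all"
            else per_patch[per_patch["habitat_class"] == habitat_class]
        )
        for subbasin in subbasins + ["all"]:
            frame = (
                class_frame if subbasin == "all"
                else class_frame[class_frame["subbasin"] == subbasin]
            )
            if frame.empty:
                continue
            out.append(_aggregate(frame, habitat_class, subbasin))
    return pd.DataFrame.from_records(out)


def compare_pressure_inside_outside(
    patches: list[HabitatPatch],
    scores: list[PressureScore],
    protection: pd.DataFrame,
    unit: str = "stratum",
) -> TTestResult:
    """Student's t test of cumulative pressure inside vs. outside protection.

    A patch counts as "inside" when more than half its area is protected.
    With ``unit="stratum"`` the observations are the mean cumulative values
    per habitat-class × subbasin × protection cell; with ``unit="patch"``
    each patch is one observation. Inside is the first group, so lower
    pressure inside protection gives a negative t.
    """
    if unit not in ("patch", "stratum"):
        raise ValueError(f"unit must be 'patch' or 'stratum', got {unit!r}")
    share = dict(zip(protection["patch_id"], protection["protected_share"]))
    score_by_id = {s.patch_id: s for s in scores}
    frame = pd.DataFrame.from_records(
        [
            {
                "habitat_class": p.habitat_class,
                "subbasin": p.subbasin if p.subbasin is not None else "unassigned",
                "inside": share.get(p.id, 0.0) > 0.5,
                "cumulative": score_by_id[p.id].cumulative,
            }
            for p in patches
        ]
    )
    if unit == "stratum":
        frame = (
            frame.groupby(["habitat_class", "subbasin", "inside"], as_index=False)["cumulative"]
            .mean()
        )
    inside = frame.loc[frame["inside"], "cumulative"].to_numpy()
    outside = frame.loc[~frame["inside"], "cumulative"].to_numpy()
    if len(inside) < 2 or len(outside) < 2:
        raise ValueError(
            "need at least two observations per group "
            f"(inside: {len(inside)}, outside: {len(outside)})"
        )
    df = len(inside) + len(outside) - 2
    pooled_var = (
        ((len(inside) - 1) * inside.var(ddof=1) + (len(outside) - 1) * outside.var(ddof=1)) / df
    )
    if pooled_var == 0.0:
        if inside.mean() == outside.mean():
            return TTestResult(df=df, t=0.0, p=1.0, unit=unit)
        t = -np.inf if inside.mean() < outside.mean() else np.inf
        return TTestResult(df=df, t=float(t), p=0.0, unit=unit)
    with warnings.catch_warnings():
        # near-identical groups trigger a scipy precision warning; the
        # degenerate exactly-identical case is already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(inside, outside, equal_var=True)
    return TTestResult(df=df, t=float(res.statistic), p=float(res.pvalue), unit=unit)
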