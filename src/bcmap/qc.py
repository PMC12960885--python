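"""Field-point quality control of the compiled habitat map.

A sampled field site is correctly mapped when the nearest mapped patch of
its observed habitat class lies within an accepted-error radius (default
30 m, inclusive — GPS plus map uncertainty); farther away counts as
incorrect. A second check selects the SAV multi-year persistence threshold
that best agrees with presence/absence reference points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.ops import unary_union

from .grid import GridRaster
from .habitats import HabitatPatch

__all__ = [
    "FieldPoint",
    "SAVReference",
    "QCReport",
    "match_points",
    "sav_agreement",
    "select_persistence_threshold",
]


@dataclass(frozen=True)
class FieldPoint:
    """Ground-truthed survey point with its observed habitat class."""

    x: float
    y: float
    observed_class: str
    source: str = "field_survey"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"field point coordinates must be finite: ({self.x}, {self.y})")


@dataclass(frozen=True)
class SAVReference:
    """Presence/absence reference point for the SAV layer."""

    x: float
    y: float
    present: bool


@dataclass
class QCReport:
    """Per-point verdicts plus per-class and overall accuracy."""

    points: pd.DataFrame
    max_dist: float

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_correct(self) -> int:
        return int(self.points["correct"].sum()) if self.n_points else 0

    @property
    def accuracy_pct(self) -> float | None:
        if self.n_points == 0:
            return None
        return 100.0 * self.n_correct / self.n_points

    def per_class(self) -> pd.DataFrame:
        if self.n_points == 0:
            return pd.DataFrame(columns=["observed_class", "n_points", "n_correct", "accuracy_pct"])
        grouped = self.points.groupby("observed_class")["correct"].agg(["count", "sum"])
        return pd.DataFrame(
            {
                "observed_class": grouped.index,
                "n_points": grouped["count"].to_numpy(),
                "n_correct": grouped["sum"].astype(int).to_numpy(),
                "accuracy_pct": (100.0 * grouped["sum"] / grouped["count"]).to_numpy(),
            }
        ).reset_index(drop=True)


def match_points(
    points: list[FieldPoint],
    patches: list[HabitatPatch],
    max_dist: float = 30.0,
    class_aware: bool = True,
) -> QCReport:
    """Match each field point to the nearest patch of its observed class.

    Distance is measured to the patch footprint (zero inside a patch). With
    ``class_aware=False`` the nearest patch of any class is used and the
    verdict additionally requires the class to match (sensitivity mode).
    """
    records = []
    # cache merged geometries per class
    class_geoms: dict[str, object] = {}
    patch_geoms = [(p, p.geometry) for p in patches]
    for pt in points:
        best_id, best_dist = None, np.inf
        candidates = (
            [(p, g) for p, g in patch_geoms if p.habitat_class == pt.observed_class]
            if class_aware
            else patch_geoms
        )
        point = shapely.Point(pt.x, pt.y)
        for patch, geom in candidates:
            d = point.distance(geom)
            if d < best_dist:
                best_id, best_dist = patch, d
        if best_id is None:
            correct = False
            matched, dist = "", np.inf
        else:
            dist = best_dist
            matched = best_id.id
            correct = dist <= max_dist
            if not class_aware:
                correct = correct and best_id.habitat_class == pt.observed_class
        records.append(
            {
                "x": pt.x,
                "y": pt.y,
                "observed_class": pt.observed_class,
                "matched_patch": matched,
                "distance_m": dist,
                "correct": correct,
            }
        )
    frame = pd.DataFrame.from_records(
        records, columns=["x", "y", "observed_class", "matched_patch", "distance_m", "correct"]
    )
    return QCReport(points=frame, max_dist=max_dist)


def sav_agreement(mask: GridRaster, references: list[SAVReference]) -> float:
    """Balanced accuracy of a SAV presence mask against reference points.

    Mean of the true-positive and true-negative rates. A class absent from
    the references contributes a vacuous rate of 1.0 (no point of that class
    can be misclassified), so an empty mask scored against all-present
    references gives 0.5.
    """
    if not references:
        raise ValueError("no reference points")
    xs = np.array([r.x for r in references])
    ys = np.array([r.y for r in references])
    present = np.array([r.present for r in references])
    rows, cols = mask.cell_of(xs, ys)
    inside = (rows >= 0) & (rows < mask.n_rows) & (cols >= 0) & (cols < mask.n_cols)
    predicted = np.zeros(len(references), dtype=bool)
    predicted[inside] = mask.data[rows[inside], cols[inside]].astype(bool)
    rates = []
    for cls in (True, False):
        sel = present == cls
        if sel.any():
            rates.append(np.mean(predicted[sel] == cls))
        else:
            rates.append(1.0)
    return float(np.mean(rates))


def select_persistence_threshold(
    sav_year_count: GridRaster,
    references: list[SAVReference],
    candidate_k=range(1, 6),
) -> tuple[int, pd.DataFrame]:
    """Pick the persistence threshold k whose mask best agrees with the references.

    Agreement is balanced accuracy of ``count >= k`` against presence/absence;
    ties go to the larger (stricter) k. References must include both classes.
    """
    from .habitats import filter_sav_persistence

    present = [r.present for r in references]
    if not references or all(present) or not any(present):
        raise ValueError(
            "references must include both SAV-present and SAV-absent points; "
            "agreement is undefined otherwise"
        )
    rows = []
    for k in candidate_k:
        mask = filter_sav_persistence(sav_year_count, min_years=k)
        rows.append({"k": int(k), "agreement": sav_agreement(mask, references)})
    table = pd.DataFrame.from_records(rows)
    best = table.loc[table["agreement"] == table["agreement"].max(), "k"].max()
    return int(best), table
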