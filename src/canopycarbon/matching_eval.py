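"""Match delineated crowns to field-measured stems and score the delineation.

A field tree is "inside" an ITC when its stem position falls in the crown
polygon (boundary included).  An ITC containing exactly one tree is paired
with it; when several trees fall inside, the tree whose measured height is
closest to the ITC height wins (ties: larger DBH, then smaller tree id).
Accuracy is summarized by the detection rate (DET), omission error
(OE = 100 - DET), commission error (CE, spurious crowns) and the accuracy
index AI = 100 - (OE + CE), overall and by stem-diameter class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point

DEFAULT_DBH_BREAKS = (10, 20, 30, 40, 50, 60, 70, 80)


@dataclass
class FieldTree:
    """A ground-measured stem."""

    id: int
    x: float
    y: float
    species: str
    dbh_cm: float
    height_m: float
    plot_id: int | None = None
    agb_kg: float | None = None
    carbon_kg: float | None = None

    def __post_init__(self) -> None:
        if self.dbh_cm <= 0 or self.height_m <= 0:
            raise ValueError(f"tree {self.id}: DBH and height must be positive")


@dataclass
class Plot:
    """A fixed-radius circular plot or an angle-count (Bitterlich) sample point."""

    id: int
    x: float
    y: float
    radius_m: float | None = None
    basal_area_factor: float | None = None
    trees: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.radius_m is None) == (self.basal_area_factor is None):
            raise ValueError("exactly one of radius_m / basal_area_factor must be set")


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]          # (itc id, field tree id)
    unmatched_field_trees: list[int]
    unmatched_itcs: list[int]
    height_pairs: list[tuple[float, float]] = field(default_factory=list)  # (itc H, field H)


@dataclass
class DelineationMetrics:
    det_pct: float
    oe_pct: float
    ce_pct: float
    ai_pct: float
    per_class: pd.DataFrame | None = None


def bitterlich_included(dbh_cm: float, distance_m: float, baf: float) -> bool:
    """Angle-count inclusion: a stem is tallied iff dbh_cm >= 100*sqrt(BAF)*dist/50."""
    return dbh_cm >= 100.0 * np.sqrt(baf) * distance_m / 50.0


def match_itcs(itcs, trees: list[FieldTree]) -> MatchResult:
    """Pair each ITC with at most one field tree (height-proximity rule)."""
    from shapely.strtree import STRtree

    pairs: list[tuple[int, int]] = []
    height_pairs: list[tuple[float, float]] = []
    matched_tree_ids: set[int] = set()
    unmatched_itcs: list[int] = []
    stems = STRtree([Point(t.x, t.y) for t in trees]) if trees else None
    for itc in itcs:
        cand_idx = stems.query(itc.polygon, predicate="covers") if stems else []
        inside = [trees[i] for i in sorted(cand_idx)
                  if trees[i].id not in matched_tree_ids]
        if not inside:
            unmatched_itcs.append(itc.id)
            continue
        best = min(inside, key=lambda t: (abs(t.height_m - itc.height), -t.dbh_cm, t.id))
        pairs.append((itc.id, best.id))
        height_pairs.append((itc.height, best.height_m))
        matched_tree_ids.add(best.id)
    unmatched_trees = [t.id for t in trees if t.id not in matched_tree_ids]
    return MatchResult(pairs, unmatched_trees, unmatched_itcs, height_pairs)


def _dbh_class(dbh: float, breaks) -> int:
    return int(np.searchsorted(np.asarray(breaks, dtype=float), dbh, side="right"))


def delineation_metrics(match: MatchResult, trees: list[FieldTree], itcs,
                        dbh_breaks=DEFAULT_DBH_BREAKS) -> DelineationMetrics:
    """DET/OE/CE/AI overall and per DBH class.

    DET = 100 * matched trees / field trees; OE = 100 - DET;
    CE = 100 * unmatched ITCs / delineated ITCs; AI = 100 - (OE + CE).
    Per-class rows bin field trees by measured DBH; an unmatched ITC is
    attributed to the class of its own estimated DBH (where available).
    """
    n_trees = len(trees)
    if n_trees == 0:
        raise ValueError("delineation metrics undefined with zero field trees")
    n_matched = len(match.pairs)
    det = 100.0 * n_matched / n_trees
    oe = 100.0 - det
    n_itcs = len(list(itcs))
    ce = 100.0 * len(match.unmatched_itcs) / n_itcs if n_itcs else 0.0
    ai = 100.0 - (oe + ce)

    matched_tree_ids = {tid for _, tid in match.pairs}
    unmatched_itc_ids = set(match.unmatched_itcs)
    n_classes = len(dbh_breaks) + 1
    rows = []
    itc_by_id = {itc.id: itc for itc in itcs}
    for k in range(n_classes):
        in_class = [t for t in trees if _dbh_class(t.dbh_cm, dbh_breaks) == k]
        n_f = len(in_class)
        n_m = sum(1 for t in in_class if t.id in matched_tree_ids)
        spurious = sum(
            1 for iid in unmatched_itc_ids
            if itc_by_id[iid].dbh_cm is not None
            and _dbh_class(itc_by_id[iid].dbh_cm, dbh_breaks) == k)
        det_k = 100.0 * n_m / n_f if n_f else np.nan
        n_itc_k = sum(
            1 for itc in itcs
            if itc.dbh_cm is not None and _dbh_class(itc.dbh_cm, dbh_breaks) == k)
        ce_k = 100.0 * spurious / n_itc_k if n_itc_k else np.nan
        rows.append({"dbh_class": k, "n_field": n_f, "n_matched": n_m,
                     "det_pct": det_k, "oe_pct": 100.0 - det_k if n_f else np.nan,
                     "n_itcs": n_itc_k, "ce_pct": ce_k})
    return DelineationMetrics(det, oe, ce, ai, pd.DataFrame(rows))


def accuracy_index(det_pct: float, ce_pct: float) -> float:
    """AI = 100 - (OE + CE) with OE = 100 - DET."""
    return 100.0 - ((100.0 - det_pct) + ce_pct)


def biomass_detection_by_class(match: MatchResult, trees: list[FieldTree], itcs,
                               dbh_breaks=DEFAULT_DBH_BREAKS) -> pd.DataFrame:
    """Per DBH class: field AGB, matched-tree AGB, ARS-detected AGB, detected %."""
    matched_tree_ids = {tid for _, tid in match.pairs}
    n_classes = len(dbh_breaks) + 1
    rows = []
    for k in range(n_classes):
        in_class = [t for t in trees if _dbh_class(t.dbh_cm, dbh_breaks) == k]
        field_agb = sum(t.agb_kg or 0.0 for t in in_class)
        matched_agb = sum(t.agb_kg or 0.0 for t in in_class if t.id in matched_tree_ids)
        ars_agb = sum(
            itc.agb_kg or 0.0 for itc in itcs
            if itc.dbh_cm is not None and _dbh_class(itc.dbh_cm, dbh_breaks) == k)
        pct = 100.0 * matched_agb / field_agb if field_agb > 0 else np.nan
        rows.append({"dbh_class": k, "field_agb_kg": field_agb,
                     "matched_agb_kg": matched_agb, "ars_agb_kg": ars_agb,
                     "detected_pct": pct})
    return pd.DataFrame(rows)


def height_agreement(match: MatchResult) -> tuple[float, float, float]:
    """(RMSE m, OLS R^2, mean relative bias %) of ITC vs field heights."""
    if len(match.height_pairs) < 2:
        raise ValueError("need at least 2 matched pairs for height agreement")
    ars = np.array([h for h, _ in match.height_pairs])
    fld = np.array([h for _, h in match.height_pairs])
    rmse = float(np.sqrt(np.mean((ars - fld) ** 2)))
    ss_res = np.sum((fld - ars) ** 2)
    ss_tot = np.sum((fld - fld.mean()) ** 2)
    if ss_tot == 0:
        r2 = 1.0 if ss_res == 0 else 0.0
    else:
        # R^2 of the OLS fit of field on ARS heights
        slope, intercept = np.polyfit(ars, fld, 1)
        pred = slope * ars + intercept
        r2 = float(1 - np.sum((fld - pred) ** 2) / ss_tot)
    bias = float(100.0 * np.mean((ars - fld) / fld))
    return rmse, r2, bias
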