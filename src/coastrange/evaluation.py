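"""Scoring reconstructions: confusion statistics, TSS, area and cell fates."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import UndefinedRateError
from .grid import CoastlineGrid
from .occupancy import OccupancyHistory, dedupe_records


@dataclass
class EvaluationReport:
    """Confusion counts and the derived sensitivity/specificity/TSS."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    tss: float | None
    scope: str = "pooled"
    n_records: int = 0

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int,
                    scope: str = "pooled", strict: bool = True) -> "EvaluationReport":
        sens = tp / (tp + fn) if (tp + fn) > 0 else None
        spec = tn / (tn + fp) if (tn + fp) > 0 else None
        if strict:
            if sens is None:
                raise UndefinedRateError("sensitivity undefined: no presence records")
            if spec is None:
                raise UndefinedRateError("specificity undefined: no absence records")
        tss = sens + spec - 1.0 if (sens is not None and spec is not None) else None
        return cls(tp, fp, tn, fn, sens, spec, tss,
                   scope=scope, n_records=tp + fp + tn + fn)


def _counts(occ: OccupancyHistory, records: pd.DataFrame):
    rec = dedupe_records(records)
    ci = rec["cell_id"].to_numpy(dtype=int)
    yi = np.array([occ.year_index(int(y)) for y in rec["year"]])
    if (ci < 0).any() or (ci >= occ.n_cells).any():
        raise ValueError("record cell outside occupancy grid")
    pred = occ.values[ci, yi].astype(int)
    obs = rec["presence"].to_numpy(dtype=int)
    return rec, pred, obs


def confusion_stats(
    occ: OccupancyHistory,
    records: pd.DataFrame,
    strict: bool = True,
) -> EvaluationReport:
    """Pooled record-vs-occupancy agreement over all years.

    ``strict`` raises :class:`UndefinedRateError` when either class is
    absent; otherwise the affected rate is reported as ``None``.
    """
    _, pred, obs = _counts(occ, records)
    tp = int(((pred == 1) & (obs == 1)).sum())
    fp = int(((pred == 1) & (obs == 0)).sum())
    tn = int(((pred == 0) & (obs == 0)).sum())
    fn = int(((pred == 0) & (obs == 1)).sum())
    return EvaluationReport.from_counts(tp, fp, tn, fn, scope="pooled", strict=strict)


def yearly_accuracy(
    occ: OccupancyHistory,
    records: pd.DataFrame,
) -> dict[int, EvaluationReport]:
    """One report per year holding at least one record; undefined rates are None."""
    rec = dedupe_records(records)
    out: dict[int, EvaluationReport] = {}
    for year, sub in rec.groupby("year"):
        rep = confusion_stats(occ, sub, strict=False)
        rep.scope = f"year:{year}"
        out[int(year)] = rep
    return out


def area_series(
    occ: OccupancyHistory,
    grid: CoastlineGrid,
    reference_year: int | None = None,
) -> pd.DataFrame:
    """Occupied area per year (km^2) and percent change vs a reference year."""
    counts = occ.values.sum(axis=0)
    area = counts * grid.cell_area
    ref_year = occ.first_year if reference_year is None else reference_year
    ref = area[occ.year_index(ref_year)]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(ref > 0, 100.0 * (area - ref) / ref, np.nan)
    return pd.DataFrame(
        {"year": occ.years, "n_cells": counts.astype(int), "area_km2": area,
         "pct_change": pct}
    )


class CellFate(str, Enum):
    NEVER_PRESENT = "never_present"
    PERSISTENCE = "persistence"
    EXTINCTION = "extinction"
    EXTINCTION_THEN_RECOLONIZATION = "extinction_then_recolonization"


def classify_fate(series: np.ndarray) -> CellFate:
    """Fate of one cell over a period of yearly presences.

    never_present: no presence; extinction: present at some point, absent in
    the final year; extinction_then_recolonization: an internal absence gap
    between presences but present in the final year; persistence: present in
    the final year with no gap since first presence.
    """
    s = np.asarray(series, dtype=int)
    if s.size == 0:
        raise ValueError("empty period")
    present = np.flatnonzero(s == 1)
    if present.size == 0:
        return CellFate.NEVER_PRESENT
    if s[-1] == 0:
        return CellFate.EXTINCTION
    gap = (s[present[0] : present[-1] + 1] == 0).any()
    return (
        CellFate.EXTINCTION_THEN_RECOLONIZATION if gap else CellFate.PERSISTENCE
    )


def transition_map(
    occ: OccupancyHistory,
    period: tuple[int, int],
) -> pd.DataFrame:
    """Classify every cell's fate within [first, last] (inclusive) years."""
    y0, y1 = period
    if y1 < y0:
        raise ValueError("empty period")
    i0, i1 = occ.year_index(y0), occ.year_index(y1)
    block = occ.values[:, i0 : i1 + 1]
    fates = [classify_fate(row).value for row in block]
    return pd.DataFrame(
        {"cell_id": np.arange(occ.n_cells), "fate": fates,
         "period": f"{y0}-{y1}"}
    )
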