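"""Synthetic ground truth: niche-rule suitability, true occupancy, surveys.

Together with :mod:`coastrange.grid` and :mod:`coastrange.environment` this
provides everything needed to exercise the full pipeline against a known
truth: a threshold niche rule turns predictors into binary suitability, the
occupancy automaton with known (D*, L*) turns suitability into the true
distribution history, and a survey plan samples presences/absences from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import CoastlineGrid
from .occupancy import OccupancyHistory, SuitabilityHistory, dedupe_records, make_records
from .predictors import PredictorStack
from .reconstruction import ReconstructionParams, coastal_distance_matrix, reconstruct

_OPS = {
    "<=": np.less_equal,
    ">=": np.greater_equal,
    "<": np.less,
    ">": np.greater,
}


@dataclass(frozen=True)
class ThresholdNicheRule:
    """Conjunction of per-predictor threshold conditions.

    ``conditions`` maps a predictor name to an ("op", cutoff) pair; a
    cell-year is suitable iff every condition holds.  An empty condition set
    means everywhere-suitable.
    """

    conditions: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        for _, op, _ in self.conditions:
            if op not in _OPS:
                raise ValueError(f"unknown operator {op!r}")

    def suitability(self, stack: PredictorStack) -> SuitabilityHistory:
        """Evaluate the rule on every (cell, year) of a predictor stack."""
        years = stack.years
        n_cells = stack.n_cells
        ok = np.ones((n_cells, len(years)), dtype=bool)
        for name, op, cutoff in self.conditions:
            ok &= _OPS[op](stack.pivot(name), cutoff)
        return SuitabilityHistory(values=ok.astype(np.uint8), first_year=int(years[0]))


def simulate_true_occupancy(
    stack: PredictorStack,
    niche_rule: ThresholdNicheRule,
    grid: CoastlineGrid,
    D_true: float,
    L_true: int,
    seed: int = 0,
) -> OccupancyHistory:
    """Run the occupancy automaton on rule-derived suitability with (D*, L*).

    Deterministic given its inputs; ``seed`` is accepted for interface
    symmetry with the other generators.
    """
    if D_true < 0:
        raise ValueError("D_true must be >= 0")
    if L_true < 1:
        raise ValueError("L_true must be >= 1")
    suit = niche_rule.suitability(stack)
    dist = coastal_distance_matrix(grid)
    return reconstruct(suit, dist, ReconstructionParams(D=D_true, L=int(L_true)))


@dataclass
class SurveyPlan:
    """Which (cell, year) combinations get surveyed.

    Either give explicit ``points`` (possibly with repeat visits, which
    collapse to unique gridded cell-years) or let ``cells_per_year`` cells be
    drawn uniformly without replacement in each of ``years``
    (``cells_per_year=None`` surveys every cell).
    """

    years: tuple[int, ...] = ()
    cells_per_year: int | None = None
    seed: int = 0
    points: tuple[tuple[int, int], ...] = field(default_factory=tuple)  # (cell, year)

    def is_empty(self) -> bool:
        return not self.years and not self.points


def sample_surveys(
    truth: OccupancyHistory,
    plan: SurveyPlan,
    grid: CoastlineGrid | None = None,
) -> pd.DataFrame:
    """Perfect-detection reads of the true occupancy at the planned cell-years.

    Returns a record table with one row per unique gridded (cell, year).
    """
    if plan.is_empty():
        raise ValueError("survey plan is empty")

    cells: list[int] = []
    years: list[int] = []
    if plan.points:
        for c, y in plan.points:
            cells.append(int(c))
            years.append(int(y))
    rng = np.random.default_rng(plan.seed)
    for y in plan.years:
        if plan.cells_per_year is None:
            chosen = np.arange(truth.n_cells)
        else:
            chosen = rng.choice(truth.n_cells, size=plan.cells_per_year, replace=False)
        cells.extend(int(c) for c in chosen)
        years.extend([int(y)] * len(chosen))

    yi = np.array([truth.year_index(y) for y in years])
    ci = np.asarray(cells, dtype=int)
    if (ci < 0).any() or (ci >= truth.n_cells).any():
        raise ValueError("survey cell outside grid")
    presence = truth.values[ci, yi]
    records = make_records(ci, years, presence, grid=grid, source="survey")
    return dedupe_records(records)
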