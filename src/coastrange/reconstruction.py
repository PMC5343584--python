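"""Occupancy reconstruction through time under dispersal and latency rules.

The automaton starts from the earliest suitability map.  In every later year
t, a suitable cell i is occupied iff

  (1) it was occupied in any of the previous L years (latency / delayed
      stages), or
  (2) some other cell within D km along the coast was occupied in year t-1
      (rescue / spatial dispersal).

``grid_search_DL`` scores every (D, L) combination against occurrence
records with the True Skill Statistic, reported as the margin over a
no-dispersal baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .errors import DisconnectedGridError, UndefinedRateError
from .grid import CoastlineGrid
from .occupancy import OccupancyHistory, ProbabilityHistory, SuitabilityHistory, dedupe_records

Mode = Literal["no_dispersal", "unlimited", "explicit"]


@dataclass(frozen=True)
class ReconstructionParams:
    """Dispersal distance D (km/yr), latency L (yr) and reconstruction mode."""

    D: float = 0.0
    L: int = 1
    mode: Mode = "explicit"

    def __post_init__(self) -> None:
        if self.mode not in ("no_dispersal", "unlimited", "explicit"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "explicit":
            if not np.isfinite(self.D) or self.D < 0:
                raise ValueError("explicit mode requires finite D >= 0")
            if self.L < 0:
                raise ValueError("L must be >= 0")


def binarize(pred: ProbabilityHistory, threshold: float) -> SuitabilityHistory:
    """Suitable iff probability >= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    return SuitabilityHistory(
        values=(pred.values >= threshold).astype(np.uint8),
        first_year=pred.first_year,
        threshold=threshold,
    )


def coastal_distance_matrix(grid: CoastlineGrid) -> np.ndarray:
    """Along-coast shortest-path distance (km) for every cell pair."""
    n = grid.n_cells
    rows, cols, data = [], [], []
    for i, nbrs in enumerate(grid.neighbors):
        for j in nbrs:
            rows.append(i)
            cols.append(j)
            data.append(grid.spacing_km)
    adj = csr_matrix((data, (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="D", directed=False)
    if np.isinf(dist).any():
        raise DisconnectedGridError("coastline adjacency graph is disconnected")
    return dist


def reconstruct(
    suit: SuitabilityHistory,
    dist: np.ndarray | None,
    params: ReconstructionParams,
) -> OccupancyHistory:
    """Run the dispersal/latency occupancy automaton over a suitability history.

    Year 1 is seeded with the suitability map itself.  ``unlimited`` mode
    returns suitability unchanged; ``no_dispersal`` is (D=0, L=1):
    year-to-year persistence only, permanent absence once unsuitable.
    """
    S = suit.values.astype(bool)
    n_cells, n_years = S.shape
    if n_years < 1:
        raise ValueError("suitability history must span at least one year")

    if params.mode == "unlimited":
        return OccupancyHistory(values=S.astype(np.uint8), first_year=suit.first_year)

    if params.mode == "no_dispersal":
        D, L = 0.0, 1
    else:
        D, L = params.D, params.L

    if D > 0:
        if dist is None:
            raise ValueError("distance matrix required when D > 0")
        reach = (dist <= D) & ~np.eye(n_cells, dtype=bool)
    else:
        reach = None

    occ = np.zeros_like(S)
    occ[:, 0] = S[:, 0]
    for t in range(1, n_years):
        latent = (
            occ[:, max(0, t - L) : t].any(axis=1)
            if L >= 1
            else np.zeros(n_cells, dtype=bool)
        )
        if reach is not None:
            rescued = reach @ occ[:, t - 1]
        else:
            rescued = np.zeros(n_cells, dtype=bool)
        occ[:, t] = S[:, t] & (latent | rescued)
    return OccupancyHistory(values=occ.astype(np.uint8), first_year=suit.first_year)


def _records_index(records: pd.DataFrame, first_year: int, n_cells: int, n_years: int):
    """Deduped record arrays (cell idx, year idx, label) within the span."""
    rec = dedupe_records(records)
    ci = rec["cell_id"].to_numpy(dtype=int)
    yi = rec["year"].to_numpy(dtype=int) - first_year
    ok = (ci >= 0) & (ci < n_cells) & (yi >= 0) & (yi < n_years)
    if not ok.all():
        raise ValueError("records outside the reconstruction span or grid")
    return ci, yi, rec["presence"].to_numpy(dtype=int)


def _tss(pred: np.ndarray, obs: np.ndarray) -> float:
    pres = obs == 1
    if not pres.any() or pres.all():
        raise UndefinedRateError("TSS needs both presence and absence records")
    sens = float((pred[pres] == 1).mean())
    spec = float((pred[~pres] == 0).mean())
    return sens + spec - 1.0


@dataclass
class GridSearchResult:
    """Outcome of the (D, L) grid search."""

    best_D: int
    best_L: int
    best_tss: float
    baseline_tss: float
    surface: pd.DataFrame  # columns: D, L, tss, marginal_tss

    @property
    def best_marginal_tss(self) -> float:
        return self.best_tss - self.baseline_tss


def grid_search_DL(
    suit: SuitabilityHistory,
    dist: np.ndarray,
    records: pd.DataFrame,
    D_range: range = range(1, 501),
    L_range: range = range(1, 6),
    baseline_latency: int = 1,
) -> GridSearchResult:
    """Score every (D, L) reconstruction against records by marginal TSS.

    The baseline is the no-dispersal reconstruction (``baseline_latency`` = 1
    keeps simple persistence; 0 removes it entirely).  Ties are broken toward
    the highest TSS, then the smallest L, then the smallest D (parsimony).
    """
    n_cells, n_years = suit.values.shape
    ci, yi, obs = _records_index(records, suit.first_year, n_cells, n_years)

    base_params = (
        ReconstructionParams(mode="no_dispersal")
        if baseline_latency >= 1
        else ReconstructionParams(D=0.0, L=0, mode="explicit")
    )
    base_occ = reconstruct(suit, dist, base_params)
    baseline_tss = _tss(base_occ.values[ci, yi], obs)

    S = suit.values.astype(bool)
    rows = []
    for D in D_range:
        reach = (dist <= D) & ~np.eye(n_cells, dtype=bool)
        for L in L_range:
            occ = np.zeros_like(S)
            occ[:, 0] = S[:, 0]
            for t in range(1, n_years):
                latent = occ[:, max(0, t - L) : t].any(axis=1)
                rescued = reach @ occ[:, t - 1]
                occ[:, t] = S[:, t] & (latent | rescued)
            tss = _tss(occ[ci, yi].astype(int), obs)
            rows.append((int(D), int(L), tss, tss - baseline_tss))

    surface = pd.DataFrame(rows, columns=["D", "L", "tss", "marginal_tss"])
    ranked = surface.sort_values(
        ["tss", "L", "D"], ascending=[False, True, True]
    ).iloc[0]
    return GridSearchResult(
        best_D=int(ranked["D"]),
        best_L=int(ranked["L"]),
        best_tss=float(ranked["tss"]),
        baseline_tss=baseline_tss,
        surface=surface,
    )
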