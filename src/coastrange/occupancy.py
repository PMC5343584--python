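"""Binary per-cell per-year histories and occurrence record tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RECORD_COLUMNS = ["lon", "lat", "cell_id", "year", "presence", "source"]


@dataclass
class YearlyBinaryHistory:
    """Binary value per (cell, year); shape (n_cells, n_years)."""

    values: np.ndarray
    first_year: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cell, year)")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("values must be binary")
        self.values = self.values.astype(np.uint8)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_years(self) -> int:
        return self.values.shape[1]

    @property
    def last_year(self) -> int:
        return self.first_year + self.n_years - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.n_years)

    def year_index(self, year: int) -> int:
        idx = year - self.first_year
        if not 0 <= idx < self.n_years:
            raise ValueError(f"year {year} outside span {self.first_year}..{self.last_year}")
        return idx

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with cell_id, year, value columns."""
        cells, yrs = np.meshgrid(np.arange(self.n_cells), self.years, indexing="ij")
        return pd.DataFrame(
            {"cell_id": cells.ravel(), "year": yrs.ravel(), "value": self.values.ravel()}
        )


class OccupancyHistory(YearlyBinaryHistory):
    """Presence (1) / absence (0) per (cell, year)."""


@dataclass
class SuitabilityHistory(YearlyBinaryHistory):
    """Binary habitat suitability per (cell, year), with the threshold used."""

    threshold: float = np.nan


@dataclass
class ProbabilityHistory:
    """Occurrence probability per (cell, year); shape (n_cells, n_years)."""

    values: np.ndarray
    first_year: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cell, year)")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.values.shape[1])


def make_records(
    cell_ids,
    years,
    presence,
    grid=None,
    source: str = "survey",
) -> pd.DataFrame:
    """Assemble an occurrence-record table (one row per observation)."""
    cell_ids = np.asarray(cell_ids, dtype=int)
    years = np.asarray(years, dtype=int)
    presence = np.asarray(presence, dtype=int)
    if not np.isin(presence, (0, 1)).all():
        raise ValueError("presence flags must be 0/1")
    lon = grid.lon[cell_ids] if grid is not None else np.full(len(cell_ids), np.nan)
    lat = grid.lat[cell_ids] if grid is not None else np.full(len(cell_ids), np.nan)
    return pd.DataFrame(
        {
            "lon": lon,
            "lat": lat,
            "cell_id": cell_ids,
            "year": years,
            "presence": presence,
            "source": source,
        }
    )


def dedupe_records(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate (cell, year) observations to one row each.

    When duplicate observations disagree, presence wins over absence
    (repeat surveys are run precisely to rule out false absences).
    """
    out = (
        records.sort_values("presence")
        .groupby(["cell_id", "year"], as_index=False)
        .last()
    )
    return out[[c for c in RECORD_COLUMNS if c in out.columns]].reset_index(drop=True)
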