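"""Seasonal extreme-event predictors derived from daily environment series.

Predictors summarise one daily variable (SST, SWH, or the wind-derived
coastal upwelling index) over one season of a focal year with one statistic:
the seasonal maximum, the longest run of days strictly above a threshold, or
the longest run of upwelling-favourable days.

Season-year assignment: months listed in ``prev_year_months`` are drawn from
the calendar year before the focal year, so e.g. winter of year t spans
October(t-1) through February(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .calendar import season_length
from .errors import IncompleteSeasonError, UnsupportedLatitudeError

EARTH_OMEGA = 7.2921e-5  # rad/s


@dataclass(frozen=True)
class SeasonDefinition:
    """A named set of calendar months, some of which belong to the prior year."""

    name: str
    months: tuple[int, ...]
    prev_year_months: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        months = tuple(self.months)
        if not months:
            raise ValueError("season needs at least one month")
        if len(set(months)) != len(months):
            raise ValueError("duplicate months in season")
        if not set(months) <= set(range(1, 13)):
            raise ValueError("months must be in 1..12")
        if not set(self.prev_year_months) <= set(months):
            raise ValueError("prev_year_months must be a subset of months")

    @property
    def n_days(self) -> int:
        return season_length(list(self.months))


WINTER = SeasonDefinition("winter", (10, 11, 12, 1, 2), prev_year_months=(10, 11, 12))
SPRING = SeasonDefinition("spring", (3, 4, 5, 6))
PREV_SUMMER = SeasonDefinition("prev_summer", (7, 8, 9), prev_year_months=(7, 8, 9))

DEFAULT_SEASONS = {s.name: s for s in (WINTER, SPRING, PREV_SUMMER)}


@dataclass(frozen=True)
class CuiParams:
    """Constants of the Ekman-transport upwelling index (Bakun convention)."""

    rho_air: float = 1.22  # kg/m^3
    drag_coefficient: float = 1.4e-3
    rho_seawater: float = 1025.0  # kg/m^3
    earth_omega: float = EARTH_OMEGA  # rad/s
    reporting_length_m: float = 100.0  # CUI reported per this length of coast

    def __post_init__(self) -> None:
        for f in ("rho_air", "drag_coefficient", "rho_seawater", "earth_omega",
                  "reporting_length_m"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be strictly positive")


def compute_cui(
    wind_u: np.ndarray,
    wind_v: np.ndarray,
    coast_angle: float,
    lat: float,
    params: CuiParams = CuiParams(),
) -> np.ndarray:
    """Coastal upwelling index: offshore Ekman transport per reporting length.

    Wind stress tau = rho_air * C_d * |W| * W; Ekman transport per unit
    coastline Q = (tau_y / (rho_sw f), -tau_x / (rho_sw f)) with
    f = 2 Omega sin(lat).  The CUI is the component of Q along the offshore
    normal (coast tangent rotated +90 deg), scaled to the reporting length;
    positive values mean offshore transport (upwelling-favourable).
    """
    if abs(lat) <= 1.0:
        raise UnsupportedLatitudeError(
            f"latitude {lat} within 1 degree of the equator; Coriolis ill-defined"
        )
    wind_u = np.asarray(wind_u, dtype=float)
    wind_v = np.asarray(wind_v, dtype=float)
    speed = np.hypot(wind_u, wind_v)
    tau_x = params.rho_air * params.drag_coefficient * speed * wind_u
    tau_y = params.rho_air * params.drag_coefficient * speed * wind_v
    f = 2.0 * params.earth_omega * np.sin(np.deg2rad(lat))
    qx = tau_y / (params.rho_seawater * f)
    qy = -tau_x / (params.rho_seawater * f)
    offshore = np.deg2rad(coast_angle + 90.0)
    cui = qx * np.cos(offshore) + qy * np.sin(offshore)
    return cui * params.reporting_length_m


def favourable_upwelling_day(cui, threshold: float = 16.0):
    """True iff the daily CUI strictly exceeds the threshold (default 16 m3/s)."""
    return np.asarray(cui) > threshold


def longest_run_above(series, threshold: float) -> int:
    """Length of the longest maximal run of values strictly above ``threshold``."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return 0
    return longest_true_run(x > threshold)


def longest_true_run(mask) -> int:
    """Length of the longest run of True values in a boolean sequence."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0 or not m.any():
        return 0
    padded = np.concatenate([[0], m.astype(np.int8), [0]])
    edges = np.flatnonzero(np.diff(padded))
    return int((edges[1::2] - edges[::2]).max())


@dataclass(frozen=True)
class PredictorDef:
    """One named predictor: variable x season x statistic (+ threshold)."""

    name: str
    variable: str  # 'sst' | 'swh' | 'cui'
    season: str  # key into the season map
    stat: str  # 'max' | 'run_above' | 'run_favourable'
    threshold: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.variable not in ("sst", "swh", "cui"):
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.stat not in ("max", "run_above", "run_favourable"):
            raise ValueError(f"unknown stat {self.stat!r}")
        if self.stat == "run_above" and self.threshold is None:
            raise ValueError("run_above requires a threshold")

    @property
    def monotone_sign(self) -> int:
        """Default monotone response direction: -1 for SST/SWH, +1 for CUI."""
        return 1 if self.variable == "cui" else -1


DEFAULT_PREDICTORS = (
    PredictorDef("sst_winter_run_above_18", "sst", "winter", "run_above", 18.0, "days"),
    PredictorDef("sst_spring_run_above_18", "sst", "spring", "run_above", 18.0, "days"),
    PredictorDef("sst_winter_max", "sst", "winter", "max", None, "degC"),
    PredictorDef("cui_spring_favourable_run", "cui", "spring", "run_favourable",
                 16.0, "days"),
    PredictorDef("swh_winter_max", "swh", "winter", "max", None, "m"),
    PredictorDef("swh_spring_run_above_3", "swh", "spring", "run_above", 3.0, "days"),
)


@dataclass
class PredictorStack:
    """Per (cell_id, year) predictor values plus per-predictor metadata."""

    frame: pd.DataFrame  # columns: cell_id, year, <predictor names>
    definitions: dict[str, PredictorDef] = field(default_factory=dict)

    @property
    def predictor_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("cell_id", "year")]

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.frame["year"])

    @property
    def n_cells(self) -> int:
        return self.frame["cell_id"].nunique()

    def year_slice(self, year: int) -> pd.DataFrame:
        sub = self.frame[self.frame["year"] == year]
        if sub.empty:
            raise ValueError(f"year {year} not in stack")
        return sub.sort_values("cell_id").reset_index(drop=True)

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        return self.frame[names or self.predictor_names].to_numpy(dtype=float)

    def pivot(self, name: str) -> np.ndarray:
        """(n_cells, n_years) array of one predictor."""
        return (
            self.frame.pivot(index="cell_id", columns="year", values=name)
            .sort_index()
            .to_numpy(dtype=float)
        )


def _season_day_mask(month_ax, year_ax, season: SeasonDefinition, year: int):
    cur = set(season.months) - set(season.prev_year_months)
    mask = np.isin(month_ax, list(cur)) & (year_ax == year)
    if season.prev_year_months:
        mask |= np.isin(month_ax, list(season.prev_year_months)) & (year_ax == year - 1)
    return mask


def seasonal_stat(
    series: np.ndarray,
    month_ax: np.ndarray,
    year_ax: np.ndarray,
    season: SeasonDefinition,
    year: int,
    stat: str,
    threshold: float | None = None,
) -> float:
    """Apply a statistic to exactly the days of one season-year.

    ``series`` is one cell's daily values aligned with ``month_ax``/``year_ax``.
    Raises :class:`IncompleteSeasonError` unless every day of the season-year
    is present.
    """
    mask = _season_day_mask(month_ax, year_ax, season, year)
    n = int(mask.sum())
    if n != season.n_days:
        raise IncompleteSeasonError(
            f"season {season.name!r} of year {year}: found {n} days, "
            f"expected {season.n_days}"
        )
    vals = np.asarray(series)[mask]
    if stat == "max":
        return float(vals.max())
    if stat == "run_above":
        return float(longest_run_above(vals, threshold))
    if stat == "run_favourable":
        th = 16.0 if threshold is None else threshold
        return float(longest_true_run(favourable_upwelling_day(vals, th)))
    raise ValueError(f"unknown stat {stat!r}")


def build_predictor_stack(
    env: xr.Dataset,
    definitions: tuple[PredictorDef, ...] = DEFAULT_PREDICTORS,
    seasons: dict[str, SeasonDefinition] | None = None,
    cui_params: CuiParams = CuiParams(),
) -> PredictorStack:
    """Derive all configured predictors from a daily environment dataset.

    Emits one row per (cell, year) for every year in which all configured
    season-years are complete; a pure function of (env, definitions).
    """
    seasons = dict(DEFAULT_SEASONS if seasons is None else seasons)
    month_ax = env["month"].to_numpy()
    year_ax = env["year"].to_numpy()
    n_cells = env.sizes["cell"]

    daily: dict[str, np.ndarray] = {
        "sst": env["sst"].to_numpy(),
        "swh": env["swh"].to_numpy(),
    }
    if any(d.variable == "cui" for d in definitions):
        wind_u = env["wind_u"].to_numpy()
        wind_v = env["wind_v"].to_numpy()
        cui = np.empty_like(wind_u)
        angles = env["coast_angle"].to_numpy()
        lats = env["lat"].to_numpy()
        for i in range(n_cells):
            cui[i] = compute_cui(wind_u[i], wind_v[i], angles[i], lats[i], cui_params)
        daily["cui"] = cui

    env_years = np.unique(year_ax)
    rows_years = [
        y
        for y in env_years
        if all(
            _season_day_mask(month_ax, year_ax, seasons[d.season], y).sum()
            == seasons[d.season].n_days
            for d in definitions
        )
    ]
    if not rows_years:
        raise IncompleteSeasonError("no year with all configured seasons complete")

    # Precompute boolean day masks once per (season, year); stats are
    # vectorised across cells via reductions over the masked day axis.
    out = {"cell_id": np.tile(np.arange(n_cells), len(rows_years)),
           "year": np.repeat(rows_years, n_cells)}
    cols: dict[str, list[np.ndarray]] = {d.name: [] for d in definitions}
    for y in rows_years:
        for d in definitions:
            mask = _season_day_mask(month_ax, year_ax, seasons[d.season], y)
            block = daily[d.variable][:, mask]  # (cells, season days)
            if d.stat == "max":
                vals = block.max(axis=1)
            else:
                th = d.threshold if d.threshold is not None else 16.0
                above = block > th
                vals = np.array([longest_true_run(row) for row in above], dtype=float)
            cols[d.name].append(vals)
    for d in definitions:
        out[d.name] = np.concatenate(cols[d.name])

    frame = pd.DataFrame(out).sort_values(["year", "cell_id"]).reset_index(drop=True)
    return PredictorStack(frame=frame, definitions={d.name: d for d in definitions})
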