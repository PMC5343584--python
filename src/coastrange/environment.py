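"""Synthetic daily coastal environment generator.

Daily SST is built additively:

    sst = latitudinal mean + seasonal sinusoid + linear warming trend
          + AR(1) anomaly + heat-wave pulses

so every component can be recovered by differencing two runs that toggle it.
Wind is a weak background flow except inside configured upwelling zones,
where it blows alongshore toward the equator during the zone's active months
(upwelling-favourable on a west-facing coast in the northern hemisphere).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .calendar import DAYS_PER_YEAR, absolute_day, time_axis
from .grid import CoastlineGrid


@dataclass
class HeatwaveEpisode:
    """Additive SST pulse over a day window and a contiguous cell range."""

    start_year: int
    start_doy: int  # 0-based day of year
    duration_days: int
    amplitude: float  # degrees C, added to SST
    cell_lo: int
    cell_hi: int  # inclusive

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("heat-wave amplitude must be >= 0")
        if self.duration_days < 1:
            raise ValueError("heat-wave duration must be >= 1 day")
        if self.cell_lo > self.cell_hi:
            raise ValueError("cell_lo must be <= cell_hi")


@dataclass
class UpwellingZone:
    """Cell range with alongshore equatorward wind during active months."""

    cell_lo: int
    cell_hi: int  # inclusive
    months: tuple[int, ...] = (3, 4, 5, 6)
    wind_speed: float = 8.0  # m/s

    def __post_init__(self) -> None:
        if self.wind_speed < 0:
            raise ValueError("wind_speed must be >= 0")


@dataclass
class ClimateScenarioParams:
    """All knobs of the synthetic climate; every run is a pure function of these."""

    sst_mean: float = 15.0  # degrees C at reference latitude
    reference_lat: float = 40.0
    sst_lat_gradient: float = -0.8  # degrees C per degree latitude northward
    seasonal_amplitude: float = 4.0  # degrees C
    seasonal_peak_doy: int = 227  # mid-August
    trend_per_decade: float = 0.0  # degrees C / decade
    anomaly_phi: float = 0.8  # AR(1) coefficient of daily anomalies
    anomaly_sd: float = 0.0  # innovation standard deviation, degrees C
    heatwaves: list[HeatwaveEpisode] = field(default_factory=list)
    upwelling_zones: list[UpwellingZone] = field(default_factory=list)
    background_wind: tuple[float, float] = (1.0, 0.5)  # (u, v) m/s
    swh_mean: float = 2.0  # m
    swh_seasonal_amplitude: float = 1.0  # m, peaking in winter
    swh_peak_doy: int = 15  # mid-January
    swh_anomaly_sd: float = 0.0  # m
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("seasonal_amplitude", "anomaly_sd", "swh_seasonal_amplitude",
                     "swh_anomaly_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.anomaly_phi < 1:
            raise ValueError("anomaly_phi must be in [0, 1)")


def _ar1(rng: np.random.Generator, phi: float, sd: float, shape: tuple[int, int]) -> np.ndarray:
    """Per-cell independent AR(1) series along the last (time) axis."""
    if sd == 0:
        return np.zeros(shape)
    n_cells, n_days = shape
    eps = rng.normal(0.0, sd, size=shape)
    out = np.empty(shape)
    # stationary start
    out[:, 0] = eps[:, 0] / np.sqrt(1 - phi**2)
    for t in range(1, n_days):
        out[:, t] = phi * out[:, t - 1] + eps[:, t]
    return out


def generate_daily_environment(
    grid: CoastlineGrid,
    years: range,
    params: ClimateScenarioParams,
) -> xr.Dataset:
    """Generate the per-cell daily SST/SWH/wind dataset for ``years``.

    Returns an :class:`xarray.Dataset` with dims ``(cell, time)`` and
    auxiliary time coordinates ``year``, ``month`` (1..12) and ``doy``
    (0-based day of year on the package's 365-day calendar).
    """
    years = range(min(years), max(years) + 1)
    if len(years) == 0:
        raise ValueError("year range must be non-empty")
    first_year, n_years = years[0], len(years)
    n_days = n_years * DAYS_PER_YEAR
    n_cells = grid.n_cells

    for ep in params.heatwaves:
        if not (first_year <= ep.start_year <= years[-1]):
            raise ValueError(f"heat-wave start year {ep.start_year} outside {years}")
        end_day = absolute_day(first_year, ep.start_year, ep.start_doy) + ep.duration_days
        if end_day > n_days:
            raise ValueError("heat-wave episode extends past the simulated span")
        if ep.cell_hi >= n_cells:
            raise ValueError("heat-wave cell range outside grid")
    for zone in params.upwelling_zones:
        if zone.cell_hi >= n_cells:
            raise ValueError("upwelling zone cell range outside grid")

    year, month, doy = time_axis(first_year, n_years)
    t_years = np.arange(n_days) / DAYS_PER_YEAR
    rng = np.random.default_rng(params.seed)

    # --- SST ---------------------------------------------------------------
    lat_mean = params.sst_mean + params.sst_lat_gradient * (grid.lat - params.reference_lat)
    seasonal = params.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - params.seasonal_peak_doy) / DAYS_PER_YEAR
    )
    trend = (params.trend_per_decade / 10.0) * t_years
    sst = lat_mean[:, None] + seasonal[None, :] + trend[None, :]
    sst += _ar1(rng, params.anomaly_phi, params.anomaly_sd, (n_cells, n_days))
    for ep in params.heatwaves:
        d0 = absolute_day(first_year, ep.start_year, ep.start_doy)
        sst[ep.cell_lo : ep.cell_hi + 1, d0 : d0 + ep.duration_days] += ep.amplitude

    # --- SWH ---------------------------------------------------------------
    swh = params.swh_mean + params.swh_seasonal_amplitude * np.cos(
        2 * np.pi * (doy - params.swh_peak_doy) / DAYS_PER_YEAR
    )
    swh = np.broadcast_to(swh, (n_cells, n_days)).copy()
    swh += _ar1(rng, params.anomaly_phi, params.swh_anomaly_sd, (n_cells, n_days))
    np.clip(swh, 0.0, None, out=swh)

    # --- wind --------------------------------------------------------------
    wind_u = np.full((n_cells, n_days), params.background_wind[0])
    wind_v = np.full((n_cells, n_days), params.background_wind[1])
    theta = np.deg2rad(grid.coast_angle)
    tangent = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (cell, 2)
    # equatorward alongshore direction: tangent flipped to point southward
    equatorward = np.where(tangent[:, 1:2] > 0, -tangent, tangent)
    for zone in params.upwelling_zones:
        in_season = np.isin(month, zone.months)
        cells = slice(zone.cell_lo, zone.cell_hi + 1)
        u_zone = zone.wind_speed * equatorward[cells, 0]
        v_zone = zone.wind_speed * equatorward[cells, 1]
        wind_u[cells] = np.where(in_season[None, :], u_zone[:, None], wind_u[cells])
        wind_v[cells] = np.where(in_season[None, :], v_zone[:, None], wind_v[cells])

    return xr.Dataset(
        data_vars={
            "sst": (("cell", "time"), sst),
            "swh": (("cell", "time"), swh),
            "wind_u": (("cell", "time"), wind_u),
            "wind_v": (("cell", "time"), wind_v),
        },
        coords={
            "cell": np.arange(n_cells),
            "time": np.arange(n_days),
            "year": ("time", year),
            "month": ("time", month),
            "doy": ("time", doy),
            "lon": ("cell", grid.lon),
            "lat": ("cell", grid.lat),
            "coast_angle": ("cell", grid.coast_angle),
        },
        attrs={
            "calendar": "noleap_365",
            "first_year": first_year,
            "n_years": n_years,
        },
    )
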