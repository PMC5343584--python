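"""Virtual coastline: an ordered 1-D chain of coastal cells.

The chain is the spatial substrate of the whole pipeline: cells are indexed
0..n-1 in along-coast order, adjacency connects consecutive cells, and
along-coast distances are exact on the chain.

Convention: ``coast_angle`` is the direction of the local coastline tangent
in degrees counterclockwise from east, pointing in the direction of
increasing cell index.  The ocean lies to the LEFT of that direction, so the
offshore normal is the tangent rotated +90 degrees.  A meridional,
west-facing coast walked northward has ``coast_angle = 90`` and offshore
normal pointing west.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KM_PER_DEG_LAT = 111.32


@dataclass
class CoastlineGrid:
    """Ordered coastal cells with coordinates and along-coast adjacency."""

    lon: np.ndarray
    lat: np.ndarray
    coast_angle: np.ndarray  # degrees CCW from east, tangent direction
    spacing_km: float
    cell_size: float = 0.05  # degrees
    cell_area: float = field(default=25.0)  # km^2 per cell

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.coast_angle = np.asarray(self.coast_angle, dtype=float)
        if not (len(self.lon) == len(self.lat) == len(self.coast_angle)):
            raise ValueError("lon, lat and coast_angle must have equal length")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.lon)

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    @property
    def neighbors(self) -> list[list[int]]:
        """Along-coast adjacency: interior cells have 2 neighbors, ends 1."""
        n = self.n_cells
        return [
            [j for j in (i - 1, i + 1) if 0 <= j < n]
            for i in range(n)
        ]

    @property
    def along_coast_km(self) -> np.ndarray:
        """Cumulative along-coast position of each cell (km)."""
        return np.arange(self.n_cells) * self.spacing_km


def generate_coastline(n_cells: int, spacing_km: float, seed: int) -> CoastlineGrid:
    """Generate a gently curving, roughly south-to-north coastal chain.

    Adjacent cells are exactly ``spacing_km`` apart along the coast and the
    tangent angle varies smoothly (seeded sum of low-frequency sinusoids).
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    if spacing_km <= 0:
        raise ValueError("spacing_km must be positive")

    rng = np.random.default_rng(seed)
    s = np.arange(n_cells, dtype=float)
    # smooth meander around due north (90 deg), max ~ +/-25 deg
    phases = rng.uniform(0, 2 * np.pi, size=3)
    amps = rng.uniform(3.0, 10.0, size=3)
    wavelens = rng.uniform(0.5, 1.5, size=3) * max(n_cells, 10)
    angle = 90.0 + sum(
        a * np.sin(2 * np.pi * s / w + p) for a, w, p in zip(amps, wavelens, phases)
    )

    theta = np.deg2rad(angle)
    lat = np.empty(n_cells)
    lon = np.empty(n_cells)
    lat[0], lon[0] = 36.0, -9.5
    for i in range(1, n_cells):
        km_per_deg_lon = KM_PER_DEG_LAT * np.cos(np.deg2rad(lat[i - 1]))
        lon[i] = lon[i - 1] + spacing_km * np.cos(theta[i - 1]) / km_per_deg_lon
        lat[i] = lat[i - 1] + spacing_km * np.sin(theta[i - 1]) / KM_PER_DEG_LAT

    return CoastlineGrid(
        lon=lon,
        lat=lat,
        coast_angle=angle,
        spacing_km=spacing_km,
        cell_area=spacing_km**2,
    )
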