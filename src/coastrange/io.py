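"""Readers/writers for the pipeline's on-disk formats.

Daily environment travels as NetCDF (cell x time, variables sst/swh/wind_u/
wind_v); everything else is plain CSV/JSON so artifacts stay text-friendly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .occupancy import OccupancyHistory, SuitabilityHistory, YearlyBinaryHistory
from .predictors import PredictorDef, PredictorStack

RECORD_COLUMNS = ["lon", "lat", "cell_id", "year", "presence", "source"]


def write_environment(env: xr.Dataset, path: str | Path) -> None:
    env.to_netcdf(path)


def read_environment(path: str | Path) -> xr.Dataset:
    return xr.load_dataset(path)


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    records[RECORD_COLUMNS].to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_predictor_stack(stack: PredictorStack, path: str | Path) -> None:
    """CSV with cell_id, year and one column per predictor; metadata in a sidecar."""
    stack.frame.to_csv(path, index=False)
    meta = {
        name: dataclasses.asdict(d) for name, d in stack.definitions.items()
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_predictor_stack(path: str | Path) -> PredictorStack:
    frame = pd.read_csv(path)
    meta_path = Path(str(path) + ".meta.json")
    definitions = {}
    if meta_path.exists():
        for name, kw in json.loads(meta_path.read_text()).items():
            definitions[name] = PredictorDef(**kw)
    return PredictorStack(frame=frame, definitions=definitions)


def write_history(hist: YearlyBinaryHistory, path: str | Path) -> None:
    """Wide CSV: one row per cell, one column per year."""
    df = pd.DataFrame(
        hist.values, index=pd.Index(range(hist.n_cells), name="cell_id"),
        columns=hist.years,
    )
    df.to_csv(path)


def read_occupancy(path: str | Path) -> OccupancyHistory:
    df = pd.read_csv(path, index_col="cell_id")
    years = df.columns.astype(int)
    return OccupancyHistory(values=df.to_numpy(), first_year=int(years.min()))


def read_suitability(path: str | Path, threshold: float = np.nan) -> SuitabilityHistory:
    df = pd.read_csv(path, index_col="cell_id")
    years = df.columns.astype(int)
    return SuitabilityHistory(
        values=df.to_numpy(), first_year=int(years.min()), threshold=threshold
    )


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
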