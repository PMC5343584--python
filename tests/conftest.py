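import numpy as np
import pandas as pd
import pytest

from coastrange import CoastlineGrid, generate_coastline
from coastrange.predictors import PredictorDef, PredictorStack


def brute_force_reconstruct(suit: np.ndarray, dist: np.ndarray, D: float, L: int) -> np.ndarray:
    """Independent oracle: literal evaluation of the two occupancy conditions.

    Re-derives each year by looping over all cells, all lag years within L,
    and all cell pairs for the rescue condition.  Deliberately naive.
    """
    n, T = suit.shape
    occ = np.zeros((n, T), dtype=int)
    for i in range(n):
        occ[i, 0] = suit[i, 0]
    for t in range(1, T):
        for i in range(n):
            if suit[i, t] == 0:
                continue
            latency = any(occ[i, tau] for tau in range(max(0, t - L), t))
            rescue = any(
                occ[j, t - 1] and dist[i, j] <= D for j in range(n) if j != i
            )
            occ[i, t] = int(latency or rescue)
    return occ


@pytest.fixture
def oracle():
    return brute_force_reconstruct


@pytest.fixture
def small_grid() -> CoastlineGrid:
    return generate_coastline(10, 5.0, seed=42)


@pytest.fixture
def chain_distances():
    def _make(n: int, spacing: float = 5.0) -> np.ndarray:
        s = np.arange(n) * spacing
        return np.abs(np.subtract.outer(s, s))

    return _make


def make_stack(values: dict[str, np.ndarray], years, definitions=None) -> PredictorStack:
    """Assemble a PredictorStack from (n_cells, n_years) arrays per predictor."""
    first = next(iter(values.values()))
    n_cells, n_years = np.asarray(first).shape
    years = np.asarray(years)
    assert len(years) == n_years
    cols = {
        "cell_id": np.tile(np.arange(n_cells), n_years),
        "year": np.repeat(years, n_cells),
    }
    for name, arr in values.items():
        cols[name] = np.asarray(arr, dtype=float).T.ravel()
    frame = pd.DataFrame(cols)
    defs = definitions or {
        name: PredictorDef(name, "sst", "winter", "max") for name in values
    }
    return PredictorStack(frame=frame, definitions=defs)


@pytest.fixture
def stack_factory():
    return make_stack
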