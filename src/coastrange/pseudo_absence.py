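"""Pseudo-absence generation outside the species' ecological space.

A Mahalanobis suitability surface (chi-square probability of the squared
distance to the presence centroid in normalized predictor space) identifies
environmentally dissimilar cells; K-means with k equal to the number of
presences stratifies them, and one cell is drawn per cluster so the
pseudo-absences match the presences in count and span the dissimilar space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .errors import DegenerateCovarianceError, InsufficientBackgroundError


@dataclass
class SuitabilitySurface:
    """Per-cell Mahalanobis D^2 and the derived suitability probability."""

    cell_ids: np.ndarray
    d2: np.ndarray
    suitability: np.ndarray  # 1 - CDF_chi2(d2; df = n predictors)
    df: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "d2": self.d2, "suitability": self.suitability}
        )


@dataclass
class PseudoAbsenceSet:
    """Selected background cells, the cutoff used and the clustering seed."""

    cell_ids: np.ndarray
    cluster: np.ndarray
    suitability: np.ndarray
    cutoff: float
    seed: int

    def __len__(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "suitability": self.suitability,
                "cluster": self.cluster,
            }
        )


def _normalize(X: np.ndarray) -> np.ndarray:
    """Z-score each column over all rows (sd 0 columns left centred)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def mahalanobis_suitability(
    rows: pd.DataFrame,
    presences: set[int] | np.ndarray,
    predictor_names: list[str] | None = None,
) -> SuitabilitySurface:
    """Habitat suitability from Mahalanobis distance to the presence centroid.

    ``rows`` holds one row per cell (``cell_id`` plus predictor columns);
    predictors are z-scored over all cells, the centroid and covariance come
    from the presence cells, and D^2 maps to a probability through the upper
    tail of the chi-square distribution with df = number of predictors.
    """
    names = predictor_names or [c for c in rows.columns if c not in ("cell_id", "year")]
    cell_ids = rows["cell_id"].to_numpy(dtype=int)
    X = _normalize(rows[names].to_numpy(dtype=float))
    pres_mask = np.isin(cell_ids, list(presences))
    n_pres = int(pres_mask.sum())
    p = len(names)
    if n_pres <= p:
        raise ValueError(
            f"need more presence rows ({n_pres}) than predictors ({p})"
        )
    P = X[pres_mask]
    mu = P.mean(axis=0)
    cov = np.cov(P, rowvar=False, ddof=1).reshape(p, p)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or np.linalg.cond(cov) > 1e12:
        raise DegenerateCovarianceError("presence covariance matrix is singular")
    prec = np.linalg.inv(cov)
    diff = X - mu
    d2 = np.einsum("ij,jk,ik->i", diff, prec, diff)
    suitability = stats.chi2.sf(d2, df=p)
    return SuitabilitySurface(cell_ids=cell_ids, d2=d2, suitability=suitability, df=p)


def draw_pseudo_absences(
    surface: SuitabilitySurface,
    rows: pd.DataFrame,
    presences: set[int] | np.ndarray,
    cutoff: float = 0.2,
    seed: int = 0,
    predictor_names: list[str] | None = None,
) -> PseudoAbsenceSet:
    """Draw one low-suitability cell per K-means cluster, k = n presences.

    Presence cells are never eligible.  Raises
    :class:`InsufficientBackgroundError` when fewer eligible cells than
    presences exist.
    """
    names = predictor_names or [c for c in rows.columns if c not in ("cell_id", "year")]
    cell_ids = rows["cell_id"].to_numpy(dtype=int)
    presences = set(int(c) for c in np.asarray(list(presences)))
    n_pres = len(presences)
    if n_pres == 0:
        raise ValueError("no presence cells given")

    order = {cid: i for i, cid in enumerate(surface.cell_ids)}
    suit = np.array([surface.suitability[order[c]] for c in cell_ids])
    eligible = (suit <= cutoff) & ~np.isin(cell_ids, list(presences))
    n_eligible = int(eligible.sum())
    if n_eligible < n_pres:
        raise InsufficientBackgroundError(
            f"{n_eligible} eligible background cells < {n_pres} presences"
        )

    X = _normalize(rows[names].to_numpy(dtype=float))[eligible]
    elig_ids = cell_ids[eligible]
    elig_suit = suit[eligible]

    rng = np.random.default_rng(seed)
    if n_eligible == n_pres:
        labels = np.arange(n_pres)
    else:
        km = KMeans(n_clusters=n_pres, n_init=10, random_state=seed)
        labels = km.fit_predict(X)

    chosen_idx: list[int] = []
    chosen_cluster: list[int] = []
    for k in np.unique(labels):
        members = np.flatnonzero(labels == k)
        chosen_idx.append(int(rng.choice(members)))
        chosen_cluster.append(int(k))
    # guard: refill from largest clusters if any cluster came back empty
    while len(chosen_idx) < n_pres:
        counts = np.bincount(labels, minlength=n_pres)
        big = int(np.argmax(counts))
        pool = np.setdiff1d(np.flatnonzero(labels == big), chosen_idx)
        if pool.size == 0:
            raise InsufficientBackgroundError("could not fill all clusters")
        chosen_idx.append(int(rng.choice(pool)))
        chosen_cluster.append(big)

    sel = np.asarray(chosen_idx, dtype=int)
    return PseudoAbsenceSet(
        cell_ids=elig_ids[sel],
        cluster=np.asarray(chosen_cluster),
        suitability=elig_suit[sel],
        cutoff=cutoff,
        seed=seed,
    )
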