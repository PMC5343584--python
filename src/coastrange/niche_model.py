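"""Monotone boosted-tree niche models, MPA transferability and ensembling.

Candidate models are all predictor subsets free of strong pairwise Spearman
correlation.  Each is a binomial boosted-tree classifier with per-predictor
monotone constraints (negative for SST/SWH metrics, positive for CUI),
hyperparameters tuned by k-fold cross-validation on holdout deviance.
Transferability is judged by the Minimum Predicted Area (MPA) criterion in a
train-one-year / test-another-year scheme; the most parsimonious (lowest
mean MPA) models form the prediction ensemble.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import UndefinedContributionError
from .occupancy import ProbabilityHistory
from .predictors import PredictorStack
from .pseudo_absence import draw_pseudo_absences, mahalanobis_suitability

ALLOWED_LEARNING_RATES = (0.01, 0.005, 0.001)


@dataclass(frozen=True)
class HyperparameterGrid:
    """BRT tuning grid; defaults follow the standard protocol.

    ``n_trees`` spans 100..10000 step 50 and learning rates are restricted to
    {0.01, 0.005, 0.001} unless ``allow_custom`` is set.  Tree complexity
    (interaction depth) runs from 1 up to the number of predictors in the
    model; the bag fraction is fixed at 0.5.
    """

    n_trees: tuple[int, ...] = tuple(range(100, 10001, 50))
    learning_rates: tuple[float, ...] = ALLOWED_LEARNING_RATES
    max_complexity: int | None = None  # None -> |subset|
    bag_fraction: float = 0.5
    allow_custom: bool = False
    min_samples_leaf: int = 5

    def __post_init__(self) -> None:
        if not self.allow_custom:
            bad = set(self.learning_rates) - set(ALLOWED_LEARNING_RATES)
            if bad:
                raise ValueError(
                    f"learning rates {sorted(bad)} outside the standard grid "
                    f"{ALLOWED_LEARNING_RATES}; set allow_custom=True to override"
                )
            if any(t < 100 or t > 10000 or (t - 100) % 50 != 0 for t in self.n_trees):
                raise ValueError(
                    "n_trees must lie in 100..10000 step 50; "
                    "set allow_custom=True to override"
                )

    def complexities(self, n_predictors: int) -> tuple[int, ...]:
        hi = self.max_complexity or n_predictors
        return tuple(range(1, min(hi, n_predictors) + 1))


@dataclass(frozen=True)
class NicheModelSpec:
    """A fitted model's identity: predictor subset, signs, tuned hyperparameters."""

    predictors: tuple[str, ...]
    monotone_signs: tuple[int, ...]
    n_trees: int
    learning_rate: float
    complexity: int
    bag_fraction: float = 0.5
    cv_deviance: float = np.nan


@dataclass
class FittedModel:
    """A trained boosted-tree model bound to its spec."""

    spec: NicheModelSpec
    estimator: HistGradientBoostingClassifier

    def predict_proba(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [p for p in self.spec.predictors if p not in rows.columns]
        if missing:
            raise ValueError(f"missing predictor columns: {missing}")
        X = rows[list(self.spec.predictors)].to_numpy(dtype=float)
        return self.estimator.predict_proba(X)[:, 1]


def enumerate_predictor_sets(
    stack: PredictorStack,
    rho_max: float = 0.8,
    max_size: int = 8,
) -> list[tuple[str, ...]]:
    """All non-empty predictor subsets with every pairwise |Spearman R| < rho_max.

    Correlations are computed over all cell-years.  ``max_size`` caps the
    subset size to bound the 2^p enumeration.
    """
    names = stack.predictor_names
    if not names:
        raise ValueError("stack has no predictors")
    p = len(names)
    if p == 1:
        corr_ok = np.ones((1, 1), dtype=bool)
    else:
        rho = spearmanr(stack.matrix(names)).statistic
        rho = np.atleast_2d(rho)
        # constant columns yield NaN correlations; treat them as uncorrelated
        corr_ok = ~(np.abs(rho) >= rho_max)
    subsets: list[tuple[str, ...]] = []
    for r in range(1, min(p, max_size) + 1):
        for combo in itertools.combinations(range(p), r):
            if all(corr_ok[i, j] for i, j in itertools.combinations(combo, 2)):
                subsets.append(tuple(names[i] for i in combo))
    return subsets


def _deviance(y: np.ndarray, prob: np.ndarray) -> float:
    """Mean binomial deviance."""
    p = np.clip(prob, 1e-9, 1 - 1e-9)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _make_estimator(
    lr: float, n_trees: int, depth: int, signs, grid: HyperparameterGrid, seed: int
) -> HistGradientBoostingClassifier:
    return HistGradientBoostingClassifier(
        loss="log_loss",
        learning_rate=lr,
        max_iter=n_trees,
        max_depth=depth,
        max_leaf_nodes=None,
        min_samples_leaf=grid.min_samples_leaf,
        monotonic_cst=list(signs),
        early_stopping=False,
        random_state=seed,
    )


def fit_brt(
    train: pd.DataFrame,
    predictors: tuple[str, ...],
    monotone_signs: dict[str, int],
    grid: HyperparameterGrid = HyperparameterGrid(),
    seed: int = 0,
    cv_folds: int = 10,
) -> FittedModel:
    """Fit a monotone boosted-tree model, tuning hyperparameters by k-fold CV.

    ``train`` holds the predictor columns plus a binary ``presence`` column.
    The (n_trees, learning rate, complexity) combination minimising mean
    holdout deviance wins; the model is then refit on all rows.
    """
    y = train["presence"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    missing = [p for p in predictors if p not in monotone_signs]
    if missing:
        raise ValueError(f"monotone sign missing for {missing}")
    X = train[list(predictors)].to_numpy(dtype=float)
    signs = tuple(monotone_signs[p] for p in predictors)

    combos = [
        (lr, nt, cx)
        for lr in grid.learning_rates
        for nt in grid.n_trees
        for cx in grid.complexities(len(predictors))
    ]
    if len(combos) == 1:
        best = combos[0]
        best_dev = np.nan
    else:
        n_splits = min(cv_folds, int(np.bincount(y).min()))
        n_splits = max(n_splits, 2)
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
        best, best_dev = None, np.inf
        for lr, nt, cx in combos:
            devs = []
            for tr_idx, te_idx in folds:
                est = _make_estimator(lr, nt, cx, signs, grid, seed)
                est.fit(X[tr_idx], y[tr_idx])
                devs.append(_deviance(y[te_idx], est.predict_proba(X[te_idx])[:, 1]))
            mean_dev = float(np.mean(devs))
            if mean_dev < best_dev:
                best, best_dev = (lr, nt, cx), mean_dev

    lr, nt, cx = best
    est = _make_estimator(lr, nt, cx, signs, grid, seed)
    est.fit(X, y)
    spec = NicheModelSpec(
        predictors=tuple(predictors),
        monotone_signs=signs,
        n_trees=nt,
        learning_rate=lr,
        complexity=cx,
        bag_fraction=grid.bag_fraction,
        cv_deviance=best_dev,
    )
    return FittedModel(spec=spec, estimator=est)


def mpa_score(
    probabilities: np.ndarray,
    test_presences: np.ndarray,
    sens_min: float = 0.9,
) -> tuple[float, float]:
    """Minimum Predicted Area at the loosest threshold keeping sensitivity.

    ``test_presences`` indexes (or boolean-masks) the presence cells among
    ``probabilities``.  The threshold is the largest predicted probability at
    which at least ``sens_min`` of the presences remain predicted present;
    MPA is the fraction of all test cells at or above it.
    """
    probs = np.asarray(probabilities, dtype=float)
    mask = np.zeros(len(probs), dtype=bool)
    mask[test_presences] = True
    if not mask.any():
        raise ValueError("at least one test presence required")
    pres_probs = probs[mask]
    threshold = None
    for theta in np.unique(probs)[::-1]:
        if (pres_probs >= theta).mean() >= sens_min:
            threshold = float(theta)
            break
    # the minimum probability always attains sensitivity 1
    assert threshold is not None
    mpa = float((probs >= threshold).mean())
    return threshold, mpa


@dataclass
class SubsetResult:
    """Transferability of one predictor subset across train/test directions."""

    predictors: tuple[str, ...]
    mpa_by_direction: dict[tuple[int, int], float]
    thresholds: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def mean_mpa(self) -> float:
        return float(np.mean(list(self.mpa_by_direction.values())))


@dataclass
class TransferabilityResult:
    """MPA scores of every candidate subset in the temporal cross-validation."""

    subsets: list[SubsetResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictors": ["+".join(s.predictors) for s in self.subsets],
                "mean_mpa": [s.mean_mpa for s in self.subsets],
            }
        )

    def best(self) -> SubsetResult:
        return min(self.subsets, key=lambda s: s.mean_mpa)


def _training_table(
    stack: PredictorStack,
    year: int,
    presences: set[int],
    pa_cutoff: float,
    seed: int,
) -> pd.DataFrame:
    """Presences of one year plus freshly drawn pseudo-absences, labelled.

    Predictors that are (near-)constant over the year's cells or over the
    presence cells cannot support a Mahalanobis surface and are dropped from
    the background-selection step only; models still see every predictor.
    """
    rows = stack.year_slice(year)
    pres_rows = rows[rows["cell_id"].isin(presences)]
    usable = [
        c
        for c in stack.predictor_names
        if rows[c].std() > 1e-9 and pres_rows[c].std() > 1e-9
    ]
    if not usable:
        raise ValueError(f"no non-degenerate predictors in year {year}")
    surface = mahalanobis_suitability(rows, presences, usable)
    pa = draw_pseudo_absences(
        surface, rows, presences, cutoff=pa_cutoff, seed=seed,
        predictor_names=usable,
    )
    pres_rows = rows[rows["cell_id"].isin(presences)].copy()
    pres_rows["presence"] = 1
    abs_rows = rows[rows["cell_id"].isin(pa.cell_ids)].copy()
    abs_rows["presence"] = 0
    return pd.concat([pres_rows, abs_rows], ignore_index=True)


def default_monotone_signs(stack: PredictorStack) -> dict[str, int]:
    """-1 for SST- and SWH-derived predictors, +1 for CUI-derived ones."""
    signs = {}
    for name in stack.predictor_names:
        d = stack.definitions.get(name)
        signs[name] = d.monotone_sign if d is not None else -1
    return signs


def temporal_transferability(
    stack: PredictorStack,
    presences_by_year: dict[int, set[int]],
    subsets: list[tuple[str, ...]],
    grid: HyperparameterGrid = HyperparameterGrid(),
    monotone_signs: dict[str, int] | None = None,
    sens_min: float = 0.9,
    pa_cutoff: float = 0.2,
    seed: int = 0,
    cv_folds: int = 10,
) -> TransferabilityResult:
    """Train on each year, score MPA on each other year, for every subset."""
    years = sorted(presences_by_year)
    if len(years) < 2:
        raise ValueError("need at least two year-datasets")
    for y, pres in presences_by_year.items():
        if not pres:
            raise ValueError(f"year {y} has no presences")
    signs = monotone_signs or default_monotone_signs(stack)

    train_tables = {
        y: _training_table(stack, y, presences_by_year[y], pa_cutoff, seed)
        for y in years
    }
    test_rows = {y: stack.year_slice(y) for y in years}
    test_presence_masks = {
        y: test_rows[y]["cell_id"].isin(presences_by_year[y]).to_numpy()
        for y in years
    }

    results = []
    for subset in subsets:
        mpa_dir: dict[tuple[int, int], float] = {}
        thr_dir: dict[tuple[int, int], float] = {}
        for train_year, test_year in itertools.permutations(years, 2):
            model = fit_brt(
                train_tables[train_year], subset, signs, grid, seed, cv_folds
            )
            probs = model.predict_proba(test_rows[test_year])
            thr, mpa = mpa_score(probs, test_presence_masks[test_year], sens_min)
            mpa_dir[(train_year, test_year)] = mpa
            thr_dir[(train_year, test_year)] = thr
        results.append(SubsetResult(subset, mpa_dir, thr_dir))
    return TransferabilityResult(subsets=results)


def select_ensemble(
    result: TransferabilityResult,
    tol_fraction: float = 0.1,
) -> list[SubsetResult]:
    """Subsets whose mean MPA falls within the lowest ``tol_fraction`` of the range.

    With the default 0.1 this keeps everything within the bottom decile of
    the [min, max] mean-MPA span; ties at the minimum are always kept.
    """
    if not result.subsets:
        raise ValueError("no candidates")
    mpas = np.array([s.mean_mpa for s in result.subsets])
    cut = mpas.min() + tol_fraction * (mpas.max() - mpas.min())
    return [s for s in result.subsets if s.mean_mpa <= cut + 1e-12]


def fit_ensemble_members(
    stack: PredictorStack,
    presences_by_year: dict[int, set[int]],
    selected: list[SubsetResult],
    grid: HyperparameterGrid = HyperparameterGrid(),
    monotone_signs: dict[str, int] | None = None,
    pa_cutoff: float = 0.2,
    seed: int = 0,
    cv_folds: int = 10,
) -> list[FittedModel]:
    """Refit each selected subset on the pooled training years."""
    signs = monotone_signs or default_monotone_signs(stack)
    pooled = pd.concat(
        [
            _training_table(stack, y, presences_by_year[y], pa_cutoff, seed)
            for y in sorted(presences_by_year)
        ],
        ignore_index=True,
    )
    return [
        fit_brt(pooled, s.predictors, signs, grid, seed, cv_folds) for s in selected
    ]


def ensemble_predict(models: list[FittedModel], stack: PredictorStack) -> ProbabilityHistory:
    """Mean member probability per (cell, year)."""
    if not models:
        raise ValueError("empty ensemble")
    frame = stack.frame
    probs = np.mean([m.predict_proba(frame) for m in models], axis=0)
    wide = (
        frame[["cell_id", "year"]]
        .assign(p=probs)
        .pivot(index="cell_id", columns="year", values="p")
        .sort_index()
    )
    if wide.isna().any().any():
        raise ValueError("stack has missing (cell, year) combinations")
    return ProbabilityHistory(
        values=wide.to_numpy(dtype=float), first_year=int(wide.columns.min())
    )


def ensemble_mpa_threshold(
    pred: ProbabilityHistory,
    presences_by_year: dict[int, set[int]],
    sens_min: float = 0.9,
) -> float:
    """MPA threshold of the ensemble itself, pooled over the training years."""
    probs, pres_idx, offset = [], [], 0
    for y in sorted(presences_by_year):
        col = pred.values[:, y - pred.first_year]
        probs.append(col)
        pres_idx.extend(offset + c for c in presences_by_year[y])
        offset += len(col)
    threshold, _ = mpa_score(np.concatenate(probs), np.asarray(pres_idx), sens_min)
    return min(max(threshold, 1e-9), 1.0)


def predictor_contributions(
    result: TransferabilityResult,
    method: str = "transform",
) -> dict[str, float]:
    """Per-predictor contribution scores rescaled to sum to 100.

    ``transform`` (default): a predictor's score is 1 minus its mean MPA over
    all models formed by adding it to an alternative model.  ``reduction``:
    the mean drop in MPA caused by adding it.  Either way scores are clipped
    at zero and rescaled so they sum to 100.
    """
    if method not in ("transform", "reduction"):
        raise ValueError(f"unknown method {method!r}")
    mpa = {frozenset(s.predictors): s.mean_mpa for s in result.subsets}
    predictors = sorted({p for s in result.subsets for p in s.predictors})

    raw: dict[str, float] = {}
    for p in predictors:
        with_p = []
        drops = []
        for subset in mpa:
            if p in subset and len(subset) > 1 and (subset - {p}) in mpa:
                with_p.append(mpa[subset])
                drops.append(mpa[subset - {p}] - mpa[subset])
        if not with_p:
            raise UndefinedContributionError(
                f"predictor {p!r} never appears as an addition to another model"
            )
        if method == "transform":
            raw[p] = max(0.0, 1.0 - float(np.mean(with_p)))
        else:
            raw[p] = max(0.0, float(np.mean(drops)))

    total = sum(raw.values())
    if total == 0:
        return {p: 100.0 / len(raw) for p in raw}
    return {p: 100.0 * v / total for p, v in raw.items()}
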