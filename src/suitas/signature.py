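"""Train, cross-validate and apply linear SVR signatures of anxious arousal.

A *signature* is a voxel weight vector plus intercept; its response to an
activation map is the plain dot product ``w · x + b`` interpreted as the
predicted 1–5 anxious-arousal rating.  The population-level model is
trained on per-rating activation maps pooled across participants with an
epsilon-insensitive linear SVR (C = 1, ε = 0.1 by default) and evaluated
with participant-grouped 10 × 10-fold cross-validation: all maps of a
participant fall into exactly one fold per repeat, so no model is ever
evaluated on a participant it saw during training.  Within-individual
models are trained per participant on single-trial beta series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.svm import SVR

from .images import ActivationMap, BrainMask

__all__ = [
    "TrainConfig",
    "SignatureModel",
    "CVScheme",
    "PredictionResult",
    "DegenerateLabelsError",
    "stack_maps",
    "train",
    "apply_signature",
    "cross_validate",
    "evaluate",
    "train_within_individual",
    "r_to_z",
    "z_to_r",
]

logger = logging.getLogger(__name__)


class DegenerateLabelsError(ValueError):
    """Training ratings are constant; the regression target is degenerate."""


@dataclass(frozen=True)
class TrainConfig:
    """Linear epsilon-insensitive SVR hyperparameters.

    ``feature_scaling="zscore"`` estimates per-voxel scaling on the
    training maps only and folds it into (weights, intercept), so that
    application always remains a plain dot product on raw maps.
    """

    cost_C: float = 1.0
    epsilon: float = 0.1
    feature_scaling: str = "off"  # off | zscore
    tol: float = 1e-6
    max_iter: int = 5_000_000  # finite cap: the SMO solver can cycle at tiny tol
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cost_C <= 0:
            raise ValueError("cost_C must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if self.feature_scaling not in ("off", "zscore"):
            raise ValueError("feature_scaling must be 'off' or 'zscore'")


@dataclass
class SignatureModel:
    """Voxel weight vector + intercept; responds to maps by dot product."""

    weights: np.ndarray
    intercept: float
    mask: BrainMask | None = None
    config: TrainConfig = field(default_factory=TrainConfig)
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.intercept):
            raise ValueError("model weights/intercept must be finite")

    def apply(self, maps: np.ndarray | Sequence[ActivationMap]) -> np.ndarray:
        return apply_signature(self, maps)


def stack_maps(maps: Sequence[ActivationMap]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack activation maps into (X, ratings, participants) arrays."""
    X = np.vstack([m.values for m in maps])
    ratings = np.asarray([m.rating for m in maps], dtype=float)
    participants = np.asarray([m.participant for m in maps])
    return X, ratings, participants


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig = TrainConfig(),
    mask: BrainMask | None = None,
) -> SignatureModel:
    """Fit a linear ε-SVR on (n_maps, n_voxels) features; deterministic."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n_maps, n_voxels) aligned with y")
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("need at least 2 distinct rating values")

    scale_mean = scale_sd = None
    Xfit = X
    if config.feature_scaling == "zscore":
        scale_mean = X.mean(axis=0)
        scale_sd = X.std(axis=0)
        scale_sd[scale_sd == 0] = 1.0
        Xfit = (X - scale_mean) / scale_sd

    svr = SVR(
        kernel="linear", C=config.cost_C, epsilon=config.epsilon,
        tol=config.tol, max_iter=config.max_iter,
    )
    svr.fit(Xfit, y)
    w = np.asarray(svr.coef_).ravel().astype(float)
    b = float(np.asarray(svr.intercept_).ravel()[0])
    if scale_sd is not None:
        # fold scaling into the weights so application stays a raw dot product
        w = w / scale_sd
        b = b - float(w @ scale_mean)
    return SignatureModel(
        weights=w,
        intercept=b,
        mask=mask,
        config=config,
        manifest={"n_maps": int(len(y)), "rating_values": sorted(set(y.tolist()))},
    )


def apply_signature(
    model: SignatureModel, maps: np.ndarray | Sequence[ActivationMap]
) -> np.ndarray:
    """Signature responses: dot product of the weight map with each map."""
    if len(maps) and isinstance(maps[0], ActivationMap):
        if model.mask is not None:
            for m in maps:
                if m.mask.n_voxels != model.mask.n_voxels or not m.mask.grid.matches(model.mask.grid):
                    raise ValueError("activation map mask does not match model mask")
        X = np.vstack([m.values for m in maps])
    else:
        X = np.atleast_2d(np.asarray(maps, dtype=float))
    if X.shape[1] != model.weights.size:
        raise ValueError("map length does not match model weights")
    return X @ model.weights + model.intercept


# ---------------------------------------------------------------------------
# evaluation


def r_to_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z with r clipped to ±(1 − 1e-12)."""
    return np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))


def z_to_r(z: np.ndarray | float) -> np.ndarray | float:
    return np.tanh(z)


@dataclass
class PredictionResult:
    """Predicted vs actual ratings with overall and within-participant metrics.

    ``evs`` is the explained-variance score 1 − mean((a − p)²) / Var(a):
    1 for perfect prediction, 0 for predicting the mean, negative for
    worse-than-mean predictors.  The within-participant mean correlation
    is averaged on the Fisher-z scale and back-transformed; its standard
    error is a participant-resampling bootstrap.
    """

    predicted: np.ndarray
    actual: np.ndarray
    groups: np.ndarray | None
    overall_r: float
    overall_p: float
    evs: float
    within_r: dict
    within_mean_r: float
    within_mean_se: float
    constant_prediction: bool = False


def evaluate(
    predicted: np.ndarray,
    actual: np.ndarray,
    groups: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> PredictionResult:
    """Overall Pearson r, EVS, and r-to-z-averaged within-participant r."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.size < 3:
        raise ValueError("predicted and actual must be equal-length (>= 3)")
    if np.var(actual) == 0:
        raise ValueError("actual ratings have zero variance; r undefined")
    constant = bool(np.var(predicted) == 0)
    if constant:
        overall_r, overall_p = np.nan, np.nan
    else:
        overall_r, overall_p = stats.pearsonr(predicted, actual)
    evs = 1.0 - float(np.mean((actual - predicted) ** 2)) / float(np.var(actual))

    within_r: dict = {}
    within_mean = np.nan
    within_se = np.nan
    if groups is not None:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            sel = groups == g
            if sel.sum() >= 3 and np.var(actual[sel]) > 0 and np.var(predicted[sel]) > 0:
                within_r[g] = float(stats.pearsonr(predicted[sel], actual[sel])[0])
        if within_r:
            rs = np.asarray(list(within_r.values()))
            within_mean = float(z_to_r(np.mean(r_to_z(rs))))
            rng = np.random.default_rng(seed)
            boots = [
                z_to_r(np.mean(r_to_z(rs[rng.integers(len(rs), size=len(rs))])))
                for _ in range(n_boot)
            ]
            within_se = float(np.std(boots))
    return PredictionResult(
        predicted=predicted,
        actual=actual,
        groups=groups,
        overall_r=float(overall_r),
        overall_p=float(overall_p),
        evs=float(evs),
        within_r=within_r,
        within_mean_r=within_mean,
        within_mean_se=within_se,
        constant_prediction=constant,
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class CVScheme:
    """Repeated participant-grouped k-fold CV (10 x 10-fold by default)."""

    n_folds: int = 10
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("need n_folds >= 2 and n_repeats >= 1")


def group_folds(
    groups: np.ndarray, scheme: CVScheme
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Per repeat, a shuffled partition of participants into ``n_folds`` folds.

    Returns, for each repeat, a list of (train_index, test_index) pairs
    over map rows.  Folds partition participants, never split them.
    """
    groups = np.asarray(groups)
    unique = np.unique(groups)
    if unique.size < scheme.n_folds:
        raise ValueError("need at least n_folds participants")
    rng = np.random.default_rng(scheme.seed)
    repeats = []
    for _ in range(scheme.n_repeats):
        order = rng.permutation(unique)
        chunks = np.array_split(order, scheme.n_folds)
        folds = []
        for chunk in chunks:
            test = np.isin(groups, chunk)
            folds.append((np.flatnonzero(~test), np.flatnonzero(test)))
        repeats.append(folds)
    return repeats


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    scheme: CVScheme = CVScheme(),
    config: TrainConfig = TrainConfig(),
    return_models: bool = False,
) -> PredictionResult | tuple[PredictionResult, list[SignatureModel]]:
    """Participant-grouped repeated k-fold CV of the population signature.

    Every map is predicted only by models that never saw its participant;
    per-map predictions are averaged across the repeats before computing
    the overall correlation and EVS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    preds = np.zeros((scheme.n_repeats, len(y)))
    models: list[SignatureModel] = []
    for rep, folds in enumerate(group_folds(groups, scheme)):
        covered = np.zeros(len(y), dtype=bool)
        for train_idx, test_idx in folds:
            train_participants = set(groups[train_idx].tolist())
            test_participants = set(groups[test_idx].tolist())
            assert not train_participants & test_participants, "participant leakage"
            model = train(X[train_idx], y[train_idx], config=config)
            preds[rep, test_idx] = apply_signature(model, X[test_idx])
            covered[test_idx] = True
            if return_models:
                models.append(model)
        assert covered.all(), "CV folds failed to cover all maps"
    result = evaluate(preds.mean(axis=0), y, groups=groups, seed=scheme.seed)
    return (result, models) if return_models else result


@dataclass
class WithinIndividualResult:
    participant: object
    model: SignatureModel
    cv_result: PredictionResult


def train_within_individual(
    beta_series_list: Sequence,
    scheme: CVScheme = CVScheme(),
    config: TrainConfig = TrainConfig(),
    min_trials: int = 10,
) -> list[WithinIndividualResult]:
    """Per-participant SVR on no-shock single trials with trial-wise CV.

    Participants with fewer than ``min_trials`` eligible trials or fewer
    than 2 distinct ratings are skipped (logged).  The returned model for
    each participant is trained on all of their eligible trials; the CV
    result uses shuffled trial-wise folds (no grouping needed within one
    participant).
    """
    out: list[WithinIndividualResult] = []
    for bs in beta_series_list:
        keep = ~bs.table["shock_followed"].to_numpy(dtype=bool)
        X = bs.data[keep]
        y = bs.table.loc[keep, "rating"].to_numpy(dtype=float)
        participant = bs.table["participant"].iloc[0]
        if len(y) < min_trials or np.unique(y).size < 2:
            logger.info(
                "skipping participant %s: %d eligible trials, %d rating values",
                participant, len(y), np.unique(y).size,
            )
            continue
        rng = np.random.default_rng(scheme.seed)
        preds = np.zeros((scheme.n_repeats, len(y)))
        for rep in range(scheme.n_repeats):
            order = rng.permutation(len(y))
            chunks = np.array_split(order, scheme.n_folds)
            for chunk in chunks:
                train_idx = np.setdiff1d(np.arange(len(y)), chunk)
                if np.unique(y[train_idx]).size < 2:
                    continue
                model = train(X[train_idx], y[train_idx], config=config)
                preds[rep, chunk] = apply_signature(model, X[chunk])
        full_model = train(X, y, config=config, mask=bs.mask)
        full_model.manifest["participant"] = participant
        cv_result = evaluate(preds.mean(axis=0), y, seed=scheme.seed)
        out.append(
            WithinIndividualResult(participant=participant, model=full_model, cv_result=cv_result)
        )
    return out
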