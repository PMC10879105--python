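"""Functional and spatial comparison between signatures and ROI sets.

Covers three complementary comparisons used to argue specificity:

* cross-application — apply one signature to another process's dataset and
  compare prediction–outcome correlations (feeding the Δr permutation
  test);
* spatial topography — Pearson correlation between weight maps over the
  analysis mask, unthresholded or restricted to bootstrap-surviving
  voxels;
* ROI profiles — cosine similarity between positively thresholded weight
  maps and ROI indicator vectors, with normalized "ribbon" weights and
  per-ROI model contribution fractions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import (
    BootstrapWeightMap,
    ForcedChoiceResult,
    forced_choice,
    _pearson,
)
from .signature import PredictionResult, SignatureModel, apply_signature, evaluate

__all__ = [
    "ROISet",
    "SimilarityReport",
    "cross_predict",
    "spatial_correlation",
    "roi_cosine_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class ROISet:
    """Named binary ROI vectors over the common analysis mask."""

    rois: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, vec in self.rois.items():
            vec = np.asarray(vec, dtype=bool)
            if not vec.any():
                raise ValueError(f"ROI {name!r} is empty within the analysis mask")
            self.rois[name] = vec


def cross_predict(
    model: SignatureModel,
    X: np.ndarray,
    ratings: np.ndarray,
    participants: np.ndarray,
    with_forced_choice: bool = True,
) -> tuple[PredictionResult, ForcedChoiceResult | None]:
    """Apply a signature to a foreign dataset: dot-product responses, metrics."""
    responses = apply_signature(model, X)
    result = evaluate(responses, np.asarray(ratings, dtype=float), groups=participants)
    fc = None
    if with_forced_choice:
        try:
            fc = forced_choice(model, X, ratings, participants)
        except ValueError:
            logger.info("forced choice skipped: no participant with both extremes")
    return result, fc


@dataclass
class SpatialCorrelation:
    r: float
    p: float
    n_voxels: int
    unstable: bool = False


def spatial_correlation(
    w1: np.ndarray,
    w2: np.ndarray,
    threshold_p: float | None = None,
    bootstrap_1: BootstrapWeightMap | None = None,
    bootstrap_2: BootstrapWeightMap | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> SpatialCorrelation:
    """Pearson correlation of two weight maps over the analysis mask.

    With ``threshold_p`` set, both maps must come with their bootstrap
    maps; the correlation is computed over the union of surviving voxels
    (values zeroed outside each map's own surviving set).  The p-value
    permutes one map's voxel values (unstructured shuffle; see the methods
    note for the smoothness caveat).  Fewer than 10 overlapping voxels is
    flagged unstable.
    """
    w1 = np.asarray(w1, dtype=float).copy()
    w2 = np.asarray(w2, dtype=float).copy()
    if w1.shape != w2.shape:
        raise ValueError("weight maps must share the mask")
    if threshold_p is not None:
        if bootstrap_1 is None or bootstrap_2 is None:
            raise ValueError("thresholded correlation requires both bootstrap maps")
        surv1 = bootstrap_1.threshold_mask(threshold_p)
        surv2 = bootstrap_2.threshold_mask(threshold_p)
        union = surv1 | surv2
        w1 = np.where(surv1, w1, 0.0)[union]
        w2 = np.where(surv2, w2, 0.0)[union]
    n = w1.size
    unstable = n < 10
    if unstable:
        warnings.warn("fewer than 10 voxels after thresholding; correlation unstable")
    r = _pearson(w1, w2)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _pearson(w1[rng.permutation(n)], w2)
    p = (1 + np.sum(np.abs(null) >= abs(r))) / (1 + n_perm)
    return SpatialCorrelation(r=float(r), p=float(p), n_voxels=int(n), unstable=unstable)


@dataclass
class SimilarityReport:
    cosine: pd.DataFrame  # models x ROIs
    ribbons: pd.DataFrame  # cosine normalized by the report-wide maximum
    contributions: pd.DataFrame  # per ROI, fraction of voxels won by each model


def _thresholded_positive(
    weights: np.ndarray, boot: BootstrapWeightMap | None, threshold_p: float | None
) -> np.ndarray:
    out = np.asarray(weights, dtype=float).copy()
    if threshold_p is not None and boot is not None:
        out = np.where(boot.threshold_mask(threshold_p), out, 0.0)
    out[out < 0] = 0.0
    return out


def roi_cosine_profile(
    models: dict[str, np.ndarray],
    rois: ROISet,
    bootstraps: dict[str, BootstrapWeightMap] | None = None,
    threshold_p: float | None = None,
) -> SimilarityReport:
    """Cosine similarity of positively thresholded weight maps with ROIs.

    Per (model, ROI): cosine between the model's thresholded positive
    weight vector and the ROI indicator, both over the analysis mask.
    Ribbons are the cosines normalized by the maximum cosine in the
    report.  Per-ROI contributions assign each in-ROI voxel to the model
    with the largest absolute thresholded weight there (ties split
    evenly); a model's contribution is its share of assigned voxels.
    Models whose thresholded map is empty are dropped with a log message.
    """
    vectors: dict[str, np.ndarray] = {}
    for name, w in models.items():
        boot = (bootstraps or {}).get(name)
        vec = _thresholded_positive(w, boot, threshold_p)
        if not np.any(vec > 0):
            logger.info("model %s dropped: empty thresholded positive map", name)
            continue
        vectors[name] = vec
    if not vectors:
        raise ValueError("no model has a non-empty thresholded positive map")

    model_names = list(vectors)
    roi_names = list(rois.rois)
    cos = pd.DataFrame(index=model_names, columns=roi_names, dtype=float)
    for mname, vec in vectors.items():
        vnorm = np.linalg.norm(vec)
        for rname, roi in rois.rois.items():
            rnorm = np.sqrt(roi.sum())
            cos.loc[mname, rname] = float(vec @ roi) / (vnorm * rnorm)
    ribbons = cos / cos.to_numpy().max()

    contrib = pd.DataFrame(0.0, index=model_names, columns=roi_names)
    stacked = np.abs(np.vstack([vectors[m] for m in model_names]))
    for rname, roi in rois.rois.items():
        sub = stacked[:, roi]
        nonzero = sub.max(axis=0) > 0
        if not nonzero.any():
            contrib[rname] = np.nan
            continue
        sub = sub[:, nonzero]
        best = sub == sub.max(axis=0, keepdims=True)
        shares = best / best.sum(axis=0, keepdims=True)
        contrib[rname] = shares.sum(axis=1) / sub.shape[1]
    return SimilarityReport(cosine=cos, ribbons=ribbons, contributions=contrib)
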