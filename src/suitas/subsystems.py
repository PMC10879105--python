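"""ROI-restricted retraining and random-voxel-subsampling curves.

These analyses test whether any single region or network suffices to
predict subjective anxious arousal: signatures are retrained with
features restricted to an ROI (same grouped CV scheme and metrics as the
whole-brain model), and performance-versus-feature-count curves are built
by retraining on uniform random voxel subsets of a source mask, which
controls for the number of features when comparing whole-brain against
single-system models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signature import (
    CVScheme,
    PredictionResult,
    SignatureModel,
    TrainConfig,
    cross_validate,
    train,
)

__all__ = ["restrict_train", "voxel_sampling_curve", "RestrictedModelResult"]


@dataclass
class RestrictedModelResult:
    model: SignatureModel  # weights embedded in the full mask (zero outside ROI)
    cv_result: PredictionResult
    roi_voxels: np.ndarray


def restrict_train(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    roi: np.ndarray,
    scheme: CVScheme = CVScheme(),
    config: TrainConfig = TrainConfig(),
) -> RestrictedModelResult:
    """Retrain the signature using only ROI voxels as features.

    ``roi`` is a boolean vector over the analysis-mask voxels.  The
    returned model's weights are embedded back into the full mask (zeros
    outside the ROI) so it can be applied to whole-mask maps.
    """
    X = np.asarray(X, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != (X.shape[1],):
        raise ValueError("roi must be a boolean vector over mask voxels")
    if not roi.any():
        raise ValueError("ROI does not intersect the analysis mask")
    Xr = X[:, roi]
    cv_result = cross_validate(Xr, y, groups, scheme=scheme, config=config)
    sub = train(Xr, y, config=config)
    weights = np.zeros(X.shape[1])
    weights[roi] = sub.weights
    model = SignatureModel(
        weights=weights,
        intercept=sub.intercept,
        config=config,
        manifest={**sub.manifest, "n_roi_voxels": int(roi.sum())},
    )
    return RestrictedModelResult(model=model, cv_result=cv_result, roi_voxels=np.flatnonzero(roi))


def voxel_sampling_curve(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    source: np.ndarray,
    sizes: list[int],
    n_reps: int = 5,
    scheme: CVScheme = CVScheme(),
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated r as a function of random feature-subset size.

    For each size, ``n_reps`` voxel subsets are drawn uniformly without
    replacement from ``source`` (a boolean vector over mask voxels) and a
    signature is retrained and cross-validated on each.  A subset equal to
    the full source is evaluated once.  Returns a tidy frame with columns
    size, rep, r, evs plus a ``summary()``-style mean/sd via groupby.
    """
    X = np.asarray(X, dtype=float)
    source = np.asarray(source, dtype=bool)
    source_idx = np.flatnonzero(source)
    if max(sizes) > source_idx.size:
        raise ValueError("requested size exceeds the source mask")
    if min(sizes) < 2:
        raise ValueError("subset sizes must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        reps = 1 if size == source_idx.size else n_reps
        for rep in range(reps):
            chosen = (
                source_idx
                if size == source_idx.size
                else rng.choice(source_idx, size=size, replace=False)
            )
            res = cross_validate(X[:, chosen], y, groups, scheme=scheme, config=config)
            rows.append(dict(size=size, rep=rep, r=res.overall_r, evs=res.evs))
    return pd.DataFrame(rows)
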