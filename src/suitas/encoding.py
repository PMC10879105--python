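"""Forward-model (structure-coefficient) transformation and the core system.

A linear decoder's weight map W answers "how do I read the rating out of
the data", not "which voxels carry rating-related activity".  The
structure-coefficient transformation reconstructs the activation pattern a
backward model tracks:

    A = cov(X) @ W / Var(Wᵀ X)

for a one-dimensional latent — equivalently, per voxel,
A_v = cov(x_v, ŷ) / Var(ŷ) where ŷ = X W is the latent model output.
Columns of X are mean-centered over trials and covariances use the
unbiased (n − 1) estimator.  A is invariant to rescaling W by any
positive constant.

The *core system* is the conjunction of group-level one-sample t-tests
(BH-FDR at q, one-sided positive by default) on the per-participant
weight maps AND on their encoding maps, keeping voxels whose group means
are positive in both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import fdr_bh, group_ttest_map

__all__ = ["EncodingMap", "structure_coefficients", "core_system", "CoreSystemResult"]


@dataclass
class EncodingMap:
    """Structure coefficients of one participant's decoder."""

    coefficients: np.ndarray
    participant: object = None
    n_trials: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("encoding coefficients must be finite")


def structure_coefficients(
    X: np.ndarray, W: np.ndarray, participant: object = None
) -> EncodingMap:
    """Transform decoder weights into the activation pattern they track.

    ``X`` is (trials, voxels); ``W`` the weight vector.  Requires at least
    2 trials and a non-degenerate latent Var(WᵀX) > 0.  W is normalized to
    unit Euclidean norm internally: the latent model output is defined
    only up to scale, and fixing ‖W‖ = 1 makes A exactly invariant to any
    positive rescaling of the decoder weights.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float).ravel()
    norm = np.linalg.norm(W)
    if norm > 0:
        W = W / norm
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be (n_trials >= 2, n_voxels)")
    if X.shape[1] != W.size:
        raise ValueError("W length must match the number of voxels")
    Xc = X - X.mean(axis=0)
    latent = Xc @ W
    var_latent = float(latent @ latent) / (X.shape[0] - 1)
    if var_latent <= 0:
        raise ValueError("zero latent variance; structure coefficients undefined")
    A = (Xc.T @ latent) / (X.shape[0] - 1) / var_latent
    return EncodingMap(coefficients=A, participant=participant, n_trials=X.shape[0])


@dataclass
class CoreSystemResult:
    core: np.ndarray  # boolean over mask voxels
    t_weights: np.ndarray
    p_weights: np.ndarray
    t_encodings: np.ndarray
    p_encodings: np.ndarray
    q: float
    negative_core: np.ndarray | None = None


def core_system(
    weight_maps: np.ndarray,
    encoding_maps: np.ndarray,
    q: float = 0.05,
    signed: bool = False,
) -> CoreSystemResult:
    """Conjunction core map from per-participant weight and encoding maps.

    A voxel belongs to the core iff the one-sided group t-test on weights
    passes BH-FDR at ``q`` AND the one-sided test on encodings passes AND
    both group means are positive.  ``signed=True`` additionally returns
    the mirrored negative-direction conjunction.
    """
    Wm = np.asarray(weight_maps, dtype=float)
    Am = np.asarray(encoding_maps, dtype=float)
    if Wm.shape != Am.shape:
        raise ValueError("weight and encoding map stacks must align")
    if Wm.shape[0] < 3:
        raise ValueError("need >= 3 participants for the group conjunction")

    t_w, p_w, _ = group_ttest_map(Wm, sidedness="one")
    t_a, p_a, _ = group_ttest_map(Am, sidedness="one")
    sig_w, _ = fdr_bh(p_w, q)
    sig_a, _ = fdr_bh(p_a, q)
    pos = (Wm.mean(axis=0) > 0) & (Am.mean(axis=0) > 0)
    core = sig_w & sig_a & pos

    negative = None
    if signed:
        _, p_w_neg, _ = group_ttest_map(-Wm, sidedness="one")
        _, p_a_neg, _ = group_ttest_map(-Am, sidedness="one")
        sig_w_neg, _ = fdr_bh(p_w_neg, q)
        sig_a_neg, _ = fdr_bh(p_a_neg, q)
        neg = (Wm.mean(axis=0) < 0) & (Am.mean(axis=0) < 0)
        negative = sig_w_neg & sig_a_neg & neg
    return CoreSystemResult(
        core=core,
        t_weights=t_w,
        p_weights=p_w,
        t_encodings=t_a,
        p_encodings=p_a,
        q=q,
        negative_core=negative,
    )
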