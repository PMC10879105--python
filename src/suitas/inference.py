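"""Permutation, bootstrap, forced-choice and multiple-comparison machinery.

All p-values from resampling use the add-one convention
``p = (1 + #extreme) / (1 + n_resamples)`` so that a permutation test can
never report exactly zero, and every routine takes an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .images import BrainMask
from .signature import SignatureModel, TrainConfig, train

__all__ = [
    "PermutationResult",
    "BootstrapWeightMap",
    "ForcedChoiceResult",
    "permutation_test_r",
    "permutation_test_delta_r",
    "bootstrap_weight_map",
    "bootstrap_mean_positive",
    "paired_extreme_maps",
    "forced_choice",
    "forced_choice_from_responses",
    "fdr_bh",
    "group_ttest_map",
]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float(xc @ yc / denom) if denom > 0 else np.nan


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    n_perm: int
    p: float
    sidedness: str
    seed: int


def permutation_test_r(
    responses: np.ndarray,
    ratings: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    sidedness: str = "one",
    refit: Callable[[np.ndarray], np.ndarray] | None = None,
) -> PermutationResult:
    """Permutation test of the prediction–outcome correlation.

    For a fixed pretrained model, ratings are shuffled against the
    responses.  In cross-validation mode pass ``refit``: a callable
    mapping a permuted rating vector to a fresh prediction vector (labels
    shuffled before refitting).  One-sided p by default:
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm == 0:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value")
    responses = np.asarray(responses, dtype=float)
    ratings = np.asarray(ratings, dtype=float)
    rng = np.random.default_rng(seed)
    observed = _pearson(responses, ratings)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(ratings))
        y_perm = ratings[perm]
        resp = refit(y_perm) if refit is not None else responses
        null[i] = _pearson(resp, y_perm)
    if sidedness == "one":
        p = (1 + np.sum(null >= observed)) / (1 + n_perm)
    elif sidedness == "two":
        p = (1 + np.sum(np.abs(null) >= abs(observed))) / (1 + n_perm)
    else:
        raise ValueError("sidedness must be 'one' or 'two'")
    return PermutationResult(observed, null, n_perm, float(p), sidedness, seed)


def permutation_test_delta_r(
    responses_a: np.ndarray,
    targets_a: np.ndarray,
    responses_b: np.ndarray,
    targets_b: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
) -> PermutationResult:
    """One-sided permutation test of a correlation difference Δr = r_a − r_b.

    The two (response, target) sets are matched row-by-row; unequal-length
    sets are paired by random subsampling of the longer set to the common
    length.  The null is built by swapping, for each matched row
    independently with probability 1/2, the (response, target) pair between
    sets A and B and recomputing Δr — exchangeable under the hypothesis of
    equal prediction performance.  Swapping the roles of A and B negates
    the observed statistic.
    """
    if n_perm == 0:
        raise ValueError("n_perm must be positive")
    ra = np.asarray(responses_a, dtype=float)
    ta = np.asarray(targets_a, dtype=float)
    rb = np.asarray(responses_b, dtype=float)
    tb = np.asarray(targets_b, dtype=float)
    if len(ra) != len(ta) or len(rb) != len(tb):
        raise ValueError("each response vector must match its target length")
    rng = np.random.default_rng(seed)
    n = min(len(ra), len(rb))
    if len(ra) > n:
        keep = rng.choice(len(ra), size=n, replace=False)
        ra, ta = ra[keep], ta[keep]
    if len(rb) > n:
        keep = rng.choice(len(rb), size=n, replace=False)
        rb, tb = rb[keep], tb[keep]
    observed = _pearson(ra, ta) - _pearson(rb, tb)
    null = np.empty(n_perm)
    for i in range(n_perm):
        swap = rng.uniform(size=n) < 0.5
        ra2 = np.where(swap, rb, ra)
        ta2 = np.where(swap, tb, ta)
        rb2 = np.where(swap, ra, rb)
        tb2 = np.where(swap, ta, tb)
        null[i] = _pearson(ra2, ta2) - _pearson(rb2, tb2)
    p = (1 + np.sum(null >= observed)) / (1 + n_perm)
    return PermutationResult(float(observed), null, n_perm, float(p), "one", seed)


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapWeightMap:
    """Voxelwise bootstrap distribution of signature weights.

    z = mean/sd across replicates; two-sided normal-approximation p by
    default (a percentile option is available at threshold time).
    """

    mean_w: np.ndarray
    sd_w: np.ndarray
    z: np.ndarray
    p: np.ndarray
    n_boot: int
    n_redrawn: int = 0
    mask: BrainMask | None = None
    replicate_weights: np.ndarray | None = None

    def threshold_mask(self, p_level: float = 0.001, positive_only: bool = False) -> np.ndarray:
        out = self.p < p_level
        if positive_only:
            out &= self.mean_w > 0
        return out


def bootstrap_weight_map(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    config: TrainConfig = TrainConfig(),
    n_boot: int = 5000,
    seed: int = 0,
    mask: BrainMask | None = None,
    keep_replicates: bool = False,
) -> BootstrapWeightMap:
    """Participant-resampling bootstrap of the population weight map.

    Each replicate resamples participants with replacement (keeping all
    their maps), retrains the signature, and stores the weights.
    Replicates whose resampled ratings collapse to fewer than 2 values are
    redrawn (counted in ``n_redrawn``) so the replicate count stays fixed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    unique = np.unique(groups)
    if unique.size < 10:
        raise ValueError("participant bootstrap needs >= 10 participants")
    if n_boot < 100:
        warnings.warn("n_boot < 100 yields unstable voxelwise sd estimates")
    rng = np.random.default_rng(seed)
    index_of = {g: np.flatnonzero(groups == g) for g in unique}
    W = np.empty((n_boot, X.shape[1]))
    redrawn = 0
    for b in range(n_boot):
        while True:
            chosen = rng.choice(unique, size=unique.size, replace=True)
            rows = np.concatenate([index_of[g] for g in chosen])
            if np.unique(y[rows]).size >= 2:
                break
            redrawn += 1
        W[b] = train(X[rows], y[rows], config=config).weights
    mean_w = W.mean(axis=0)
    sd_w = W.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_w > 0, mean_w / sd_w, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return BootstrapWeightMap(
        mean_w=mean_w,
        sd_w=sd_w,
        z=z,
        p=p,
        n_boot=n_boot,
        n_redrawn=redrawn,
        mask=mask,
        replicate_weights=W if keep_replicates else None,
    )


def bootstrap_mean_positive(values: np.ndarray, n_boot: int = 5000, seed: int = 0) -> float:
    """One-sided bootstrap p that the mean of ``values`` exceeds zero.

    Resamples with replacement; p = fraction of bootstrap means <= 0,
    floored at 1/(n_boot + 1).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 values")
    rng = np.random.default_rng(seed)
    means = values[rng.integers(values.size, size=(n_boot, values.size))].mean(axis=1)
    p = np.mean(means <= 0.0)
    return float(max(p, 1.0 / (n_boot + 1)))


# ---------------------------------------------------------------------------
# forced choice


@dataclass
class ForcedChoiceResult:
    accuracy: float
    se: float
    cohens_d: float
    binomial_p: float
    roc_points: np.ndarray
    n_pairs: int
    n_excluded: int = 0
    diffs: np.ndarray = field(default_factory=lambda: np.empty(0))


def paired_extreme_maps(
    X: np.ndarray,
    ratings: np.ndarray,
    participants: np.ndarray,
    high: Sequence[int] = (4, 5),
    low: Sequence[int] = (1, 2),
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per participant, the averaged high-rating and low-rating maps.

    High = mean of maps rated 4/5, low = mean of maps rated 1/2;
    participants lacking either side are excluded (counted).
    """
    X = np.asarray(X, dtype=float)
    ratings = np.asarray(ratings, dtype=float)
    participants = np.asarray(participants)
    highs, lows, excluded = [], [], 0
    for p in np.unique(participants):
        sel = participants == p
        hi = sel & np.isin(ratings, high)
        lo = sel & np.isin(ratings, low)
        if hi.any() and lo.any():
            highs.append(X[hi].mean(axis=0))
            lows.append(X[lo].mean(axis=0))
        else:
            excluded += 1
    if not highs:
        raise ValueError("no participant has both a high- and a low-rating map")
    return np.vstack(highs), np.vstack(lows), excluded


def forced_choice_from_responses(
    high_responses: np.ndarray, low_responses: np.ndarray, n_excluded: int = 0
) -> ForcedChoiceResult:
    """Two-alternative forced choice on matched response pairs.

    A pair is correct iff response(high) > response(low); exact ties score
    0.5.  Cohen's d is mean/sd of the paired differences; the p-value is a
    two-sided exact binomial test of the win count against 0.5.
    """
    hi = np.asarray(high_responses, dtype=float)
    lo = np.asarray(low_responses, dtype=float)
    if hi.shape != lo.shape or hi.size == 0:
        raise ValueError("need matched, non-empty response vectors")
    diffs = hi - lo
    wins = int(np.sum(diffs > 0))
    losses = int(np.sum(diffs < 0))
    ties = diffs.size - wins - losses
    accuracy = (wins + 0.5 * ties) / diffs.size
    se = float(np.sqrt(accuracy * (1 - accuracy) / diffs.size))
    sd = np.std(diffs, ddof=1) if diffs.size > 1 else 0.0
    d = float(diffs.mean() / sd) if sd > 0 else np.inf * np.sign(diffs.mean())
    n_informative = wins + losses
    if n_informative > 0:
        binom_p = float(stats.binomtest(wins, n_informative, 0.5, alternative="two-sided").pvalue)
    else:
        binom_p = 1.0
    scores = np.concatenate([hi, lo])
    labels = np.concatenate([np.ones(hi.size), np.zeros(lo.size)])
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order])
    fps = np.cumsum(1 - labels[order])
    roc = np.column_stack([fps / lo.size, tps / hi.size])
    roc = np.vstack([[0.0, 0.0], roc])
    return ForcedChoiceResult(
        accuracy=float(accuracy),
        se=se,
        cohens_d=d,
        binomial_p=binom_p,
        roc_points=roc,
        n_pairs=int(diffs.size),
        n_excluded=n_excluded,
        diffs=diffs,
    )


def forced_choice(
    model: SignatureModel,
    X: np.ndarray,
    ratings: np.ndarray,
    participants: np.ndarray,
    high: Sequence[int] = (4, 5),
    low: Sequence[int] = (1, 2),
) -> ForcedChoiceResult:
    """High-vs-low forced choice of signature responses, paired by participant."""
    hi_maps, lo_maps, excluded = paired_extreme_maps(X, ratings, participants, high, low)
    hi = model.apply(hi_maps)
    lo = model.apply(lo_maps)
    return forced_choice_from_responses(hi, lo, n_excluded=excluded)


# ---------------------------------------------------------------------------
# multiple comparisons and group maps


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up: boolean significance mask + threshold.

    Returns the largest p-value passing (0.0 when nothing passes).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    passing = np.flatnonzero(ranked <= (np.arange(1, m + 1) / m) * q)
    if passing.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    threshold = ranked[passing[-1]]
    return p <= threshold, float(threshold)


def group_ttest_map(
    maps: np.ndarray, sidedness: str = "one"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxelwise one-sample t-test of participant maps against zero.

    ``sidedness="one"`` tests the positive direction.  Voxels with zero
    across-participant variance are flagged and given the limit p (0 if
    the common value is in the tested direction, 1 otherwise).
    Returns (t, p, degenerate_flags).
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 3:
        raise ValueError("need >= 3 participant maps")
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.sign(mean) * np.inf, mean / (sd / np.sqrt(n)))
    if sidedness == "one":
        p = stats.t.sf(t, df=n - 1)
    elif sidedness == "two":
        p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    else:
        raise ValueError("sidedness must be 'one' or 'two'")
    p = np.where(degenerate, np.where(mean > 0, 0.0, 1.0) if sidedness == "one" else np.where(mean != 0, 0.0, 1.0), p)
    t = np.where(degenerate & (mean == 0), 0.0, t)
    return t, p, degenerate
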