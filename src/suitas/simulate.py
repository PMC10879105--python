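"""Synthetic cohorts emulating the uncertainty-variation threat-anticipation task.

The generator produces per-participant single-trial beta maps (and
optionally HRF-convolved BOLD series) with a known multivariate ground
truth, so that every downstream stage — GLM, signature training,
cross-validation, bootstrap/permutation inference, encoding maps,
specificity and subsystem analyses — can be scored against the generating
patterns.

Generative model for a trial t of participant s::

    beta_t = A * g_s * rating_t * p_anx
           + c_amp * c_t * p_arousal
           + v_amp * v_t * p_visual
           + smooth Gaussian noise (per-voxel sd = noise_sd)

where ``p_anx`` is a unit-norm distributed blob pattern (the latent
"anxiety" representation), ``c_t`` is an autonomic-arousal-like covariate
sharing a latent Gaussian with the rating (correlation
``confound_rating_correlation``), ``v_t`` is a standardized condition-cue
covariate, and ``g_s`` is a log-normal participant gain.  Ratings are
drawn from a Gaussian around the condition mean, rounded and clipped to
the 1–5 scale; each of the four cue conditions repeats
``trials_per_condition_per_run`` times per run and uncertain-condition
trials are followed by a shock with the stated probability.  Trials
followed by a shock are excluded when averaging into per-rating maps,
mirroring how anticipation epochs contaminated by shock delivery are
dropped from model training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import glm as _glm
from .images import ActivationMap, BrainMask, Volume, VolumeGrid, unvectorize

__all__ = [
    "SyntheticSpec",
    "SyntheticGroundTruth",
    "BetaSeries",
    "PatternPlacementError",
    "default_grid",
    "ellipsoid_mask",
    "make_pattern",
    "make_ground_truth",
    "simulate_trials",
    "simulate_cohort",
    "aggregate_by_rating",
    "simulate_bold",
]

CONDITIONS = ("safety", "low", "medium", "high")


class PatternPlacementError(RuntimeError):
    """Blobs could not be placed inside the mask."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Cohort-level generative parameters (defaults = the study conditions).

    Per-run trial counts, the 60% shock probability for uncertain
    conditions, the 1–5 rating scale and the monotone condition means
    follow the anticipation paradigm this generator emulates; amplitude
    and noise defaults define the package's "moderate SNR" operating
    point (see docs/methods.md).
    """

    n_participants: int = 30
    n_runs: int = 4
    trials_per_condition_per_run: int = 5
    conditions: tuple[str, ...] = CONDITIONS
    condition_rating_means: tuple[float, ...] = (1.2, 2.4, 3.3, 4.3)
    rating_sd: float = 0.8
    shock_probability: Mapping[str, float] = field(
        default_factory=lambda: {"safety": 0.0, "low": 0.6, "medium": 0.6, "high": 0.6}
    )
    signal_amplitude: float = 1.0  # beta units per rating unit
    confound_amplitude: float = 0.3  # beta units (arousal-like covariate)
    confound_rating_correlation: float = 0.5
    visual_amplitude: float = 0.3  # beta units (condition-cue covariate)
    noise_sd: float = 0.5  # beta units per voxel
    regional_noise_sd: float = 0.0  # rating units; per-trial per-blob jitter
    regional_gain_sigma: float = 0.0  # sd of log per-(participant, blob) gain
    smoothing_fwhm: float = 3.0  # mm
    gain_sigma: float = 0.1  # sd of log participant gain
    seed: int = 0

    def __post_init__(self) -> None:
        means = np.asarray(self.condition_rating_means, dtype=float)
        if len(means) != len(self.conditions):
            raise ValueError("one rating mean per condition required")
        if np.any(np.diff(means) < 0):
            raise ValueError("condition_rating_means must be nondecreasing")
        for cond in self.conditions:
            p = self.shock_probability.get(cond, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError("shock probabilities must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.rating_sd < 0:
            raise ValueError("rating_sd must be nonnegative")
        if not -1.0 <= self.confound_rating_correlation <= 1.0:
            raise ValueError("confound_rating_correlation must be in [-1, 1]")

    @property
    def trials_per_run(self) -> int:
        return self.trials_per_condition_per_run * len(self.conditions)

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run


@dataclass
class SyntheticGroundTruth:
    """Generating patterns and per-participant gains for scoring recovery."""

    anxiety_pattern: ActivationMap
    confound_patterns: dict[str, ActivationMap]
    per_participant_gain: np.ndarray
    generative_noise_sd: float

    def __post_init__(self) -> None:
        norm = np.linalg.norm(self.anxiety_pattern.values)
        if not np.isclose(norm, 1.0, atol=1e-8):
            raise ValueError("anxiety_pattern must have unit Euclidean norm")
        mask = self.anxiety_pattern.mask
        for name, pat in self.confound_patterns.items():
            if pat.mask is not mask and pat.mask.n_voxels != mask.n_voxels:
                raise ValueError(f"confound pattern {name!r} is on a different mask")


@dataclass
class BetaSeries:
    """Single-trial beta matrix (trials x voxels) plus the trial table."""

    mask: BrainMask
    data: np.ndarray
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.table), self.mask.n_voxels):
            raise ValueError("beta matrix shape must be (n_trials, mask.n_voxels)")


# ---------------------------------------------------------------------------
# grids, masks, patterns


def default_grid(shape: tuple[int, int, int] = (18, 18, 15), voxel_mm: float = 3.0) -> VolumeGrid:
    """Small MNI-like grid: isotropic voxels, origin at the volume center."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -np.asarray(shape) * voxel_mm / 2.0
    return VolumeGrid(shape=shape, affine=affine)


def ellipsoid_mask(grid: VolumeGrid, semi_axes_vox: Sequence[float] | None = None) -> BrainMask:
    """Brain-like ellipsoidal analysis mask centered in the grid."""
    shape = np.asarray(grid.shape, dtype=float)
    if semi_axes_vox is None:
        semi_axes_vox = shape * 0.45
    center = (shape - 1) / 2.0
    ijk = np.stack(np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij"), axis=-1)
    d2 = (((ijk - center) / np.asarray(semi_axes_vox)) ** 2).sum(axis=-1)
    return BrainMask.from_array(grid, d2 <= 1.0)


def make_pattern(
    mask: BrainMask,
    n_blobs: int = 3,
    blob_radius_mm: float = 7.5,
    seed: int = 0,
    avoid: np.ndarray | None = None,
    min_separation_mm: float | None = None,
    rng: np.random.Generator | None = None,
) -> ActivationMap:
    """Distributed multi-blob pattern with unit Euclidean norm.

    Blob centers are sampled (deterministically for a given seed) from
    voxels deep enough inside the mask that the whole ball fits, pairwise
    separated by ``min_separation_mm`` (default 2·radius + 2 voxels, which
    keeps blob supports disjoint under 6-connectivity).  ``avoid`` is an
    optional boolean in-mask vector whose support the blobs must clear —
    used to build mutually orthogonal ground-truth patterns.  Each blob is
    a Gaussian bump (sigma = radius/2) truncated at the radius.
    """
    if n_blobs < 1:
        raise ValueError("n_blobs must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    grid = mask.grid
    voxel = float(np.mean(grid.voxel_size))
    radius_vox = blob_radius_mm / voxel
    if min_separation_mm is None:
        min_separation_mm = 2.0 * blob_radius_mm + 2.0 * voxel

    mask_arr = mask.to_array()
    # centers at least half a radius inside the mask; a blob clipped by the
    # mask boundary keeps a compact connected support (ball ∩ convex mask)
    depth = ndimage.distance_transform_edt(mask_arr, sampling=grid.voxel_size)
    eligible = depth.ravel(order="C")[mask.indices] >= blob_radius_mm / 2.0
    if avoid is not None:
        avoid = np.asarray(avoid, dtype=bool)
        avoid_arr = unvectorize(avoid.astype(float), mask) > 0
        if avoid_arr.any():
            dist_avoid = ndimage.distance_transform_edt(~avoid_arr, sampling=grid.voxel_size)
            eligible &= dist_avoid.ravel(order="C")[mask.indices] > blob_radius_mm + voxel
    candidates = mask.voxel_coords[eligible]
    if len(candidates) == 0:
        raise PatternPlacementError("no eligible voxels for blob centers")

    vs = np.asarray(grid.voxel_size)
    centers: list[np.ndarray] = []
    for _ in range(20000):
        cand = candidates[rng.integers(len(candidates))]
        if all(np.linalg.norm((cand - c) * vs) >= min_separation_mm for c in centers):
            centers.append(cand)
        if len(centers) == n_blobs:
            break
    else:
        raise PatternPlacementError(
            f"could not place {n_blobs} blobs of radius {blob_radius_mm} mm in the mask"
        )

    coords_mm = mask.voxel_coords * vs
    sigma = blob_radius_mm / 2.0
    components = np.zeros((n_blobs, mask.n_voxels))
    for j, c in enumerate(centers):
        d = np.linalg.norm(coords_mm - c * vs, axis=1)
        bump = np.exp(-(d**2) / (2.0 * sigma**2))
        bump[d > blob_radius_mm] = 0.0
        components[j] = bump
    norm = np.linalg.norm(components.sum(axis=0))
    components /= norm
    return ActivationMap(
        mask=mask,
        values=components.sum(axis=0),
        kind="contrast",
        meta={"centers": [c.tolist() for c in centers], "components": components},
    )


def make_ground_truth(
    spec: SyntheticSpec,
    mask: BrainMask,
    n_blobs: int = 3,
    blob_radius_mm: float | None = None,
    min_separation_mm: float | None = None,
) -> SyntheticGroundTruth:
    """Anxiety pattern + arousal/visual confound patterns with disjoint support.

    ``blob_radius_mm`` defaults to 7.5 mm, shrunk on small masks so that
    three mutually avoiding patterns still fit.
    """
    if blob_radius_mm is None:
        extent = float(np.ptp(mask.world_coords(), axis=0).min())
        blob_radius_mm = float(min(7.5, 0.2 * extent))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    anx = make_pattern(
        mask, n_blobs=n_blobs, blob_radius_mm=blob_radius_mm,
        min_separation_mm=min_separation_mm, rng=rng,
    )
    arousal = make_pattern(
        mask, n_blobs=2, blob_radius_mm=blob_radius_mm,
        avoid=anx.values != 0, rng=rng,
    )
    visual = make_pattern(
        mask, n_blobs=1, blob_radius_mm=blob_radius_mm,
        avoid=(anx.values != 0) | (arousal.values != 0), rng=rng,
    )
    gains = np.exp(rng.normal(0.0, spec.gain_sigma, size=spec.n_participants))
    return SyntheticGroundTruth(
        anxiety_pattern=anx,
        confound_patterns={"arousal": arousal, "visual": visual},
        per_participant_gain=gains,
        generative_noise_sd=spec.noise_sd,
    )


# ---------------------------------------------------------------------------
# noise


def _smoothing_kernel_norm(grid: VolumeGrid, sigma_vox: np.ndarray) -> float:
    """L2 norm of the discrete Gaussian smoothing kernel on this grid.

    Smoothing white noise of unit variance with kernel k yields per-voxel
    sd ||k||_2 (exact away from the boundary); dividing by this norm makes
    the generated noise sd equal the requested value.
    """
    impulse = np.zeros(grid.shape)
    impulse[tuple(s // 2 for s in grid.shape)] = 1.0
    k = ndimage.gaussian_filter(impulse, sigma=sigma_vox)
    return float(np.sqrt((k**2).sum()))


def smooth_noise(
    rng: np.random.Generator,
    mask: BrainMask,
    n_fields: int,
    fwhm_mm: float,
    sd: float,
) -> np.ndarray:
    """(n_fields, n_voxels) spatially smooth Gaussian noise, per-voxel sd ``sd``."""
    grid = mask.grid
    sigma_vox = np.full(3, fwhm_mm / 2.3548) / np.asarray(grid.voxel_size)
    scale = sd / _smoothing_kernel_norm(grid, sigma_vox)
    flat_idx = mask.indices
    out = np.empty((n_fields, mask.n_voxels))
    for i in range(n_fields):
        white = rng.standard_normal(grid.shape)
        smoothed = ndimage.gaussian_filter(white, sigma=sigma_vox)
        out[i] = smoothed.ravel(order="C")[flat_idx] * scale
    return out


# ---------------------------------------------------------------------------
# trial-level simulation


def _participant_rng(spec: SyntheticSpec, participant: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, 1000 + participant]))


def simulate_trials(
    spec: SyntheticSpec,
    gt: SyntheticGroundTruth,
    participant: int,
) -> BetaSeries:
    """Simulate one participant's single-trial beta series and trial table.

    Deterministic given ``spec.seed`` and the participant index.  With
    ``noise_sd`` → 0 and confound amplitudes 0, each trial vector equals
    ``signal_amplitude · gain · rating · anxiety_pattern`` exactly.
    """
    if not 0 <= participant < len(gt.per_participant_gain):
        raise ValueError("participant index out of range of ground-truth gains")
    rng = _participant_rng(spec, participant)
    mask = gt.anxiety_pattern.mask
    gain = float(gt.per_participant_gain[participant])
    means = dict(zip(spec.conditions, spec.condition_rating_means))

    rows = []
    for run in range(spec.n_runs):
        order = np.repeat(np.arange(len(spec.conditions)), spec.trials_per_condition_per_run)
        rng.shuffle(order)
        t = 0.0
        for trial, cond_idx in enumerate(order):
            cond = spec.conditions[cond_idx]
            t += rng.uniform(4.0, 6.0)  # fixation
            duration = 8.0 if cond == "low" else float(rng.uniform(6.0, 10.0))
            onset = t
            t += duration + 0.75 + 4.0  # outcome screen + rating epoch
            latent = rng.normal(means[cond], spec.rating_sd)
            rating = int(np.clip(np.rint(latent), 1, 5))
            shock = bool(rng.uniform() < spec.shock_probability.get(cond, 0.0))
            rows.append(
                dict(
                    participant=participant,
                    run=run,
                    trial=trial,
                    condition=cond,
                    condition_index=int(cond_idx),
                    onset=onset,
                    duration=duration,
                    rating=rating,
                    latent_rating=latent,
                    shock_followed=shock,
                )
            )
    table = pd.DataFrame(rows)

    latent = table["latent_rating"].to_numpy()
    z = (latent - latent.mean()) / latent.std() if latent.std() > 0 else np.zeros_like(latent)
    rho = spec.confound_rating_correlation
    confound = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(len(table))
    cond_rank = table["condition_index"].to_numpy(dtype=float)
    visual = (cond_rank - cond_rank.mean()) / (cond_rank.std() if cond_rank.std() > 0 else 1.0)
    table["confound"] = confound
    table["visual"] = visual

    noise = smooth_noise(rng, mask, len(table), spec.smoothing_fwhm, spec.noise_sd)
    ratings = table["rating"].to_numpy(dtype=float)
    scale = spec.signal_amplitude * gain
    regional = (
        spec.regional_noise_sd > 0 or spec.regional_gain_sigma > 0
    ) and "components" in gt.anxiety_pattern.meta
    if regional:
        # each region encodes a noisy, participant-idiosyncratic copy of the
        # latent rating: single subsystems are then genuinely less
        # informative than their pooled whole-brain representation
        comps = np.asarray(gt.anxiety_pattern.meta["components"])
        n_blobs = comps.shape[0]
        region_gain = np.ones(n_blobs)
        if spec.regional_gain_sigma > 0:
            region_gain = np.exp(rng.normal(0.0, spec.regional_gain_sigma, size=n_blobs))
        jitter = np.zeros((len(table), n_blobs))
        if spec.regional_noise_sd > 0:
            jitter = rng.normal(0.0, spec.regional_noise_sd, size=(len(table), n_blobs))
        signal = scale * ((ratings[:, None] + jitter) * region_gain[None, :]) @ comps
    else:
        signal = scale * ratings[:, None] * gt.anxiety_pattern.values[None, :]
    data = (
        signal
        + spec.confound_amplitude * confound[:, None] * gt.confound_patterns["arousal"].values[None, :]
        + spec.visual_amplitude * visual[:, None] * gt.confound_patterns["visual"].values[None, :]
        + noise
    )
    return BetaSeries(mask=mask, data=data, table=table)


def simulate_cohort(
    spec: SyntheticSpec,
    mask: BrainMask | None = None,
    gt: SyntheticGroundTruth | None = None,
) -> tuple[list[BetaSeries], SyntheticGroundTruth, BrainMask]:
    """Simulate all participants of a cohort; returns (series, truth, mask)."""
    if mask is None:
        mask = ellipsoid_mask(default_grid())
    if gt is None:
        gt = make_ground_truth(spec, mask)
    series = [simulate_trials(spec, gt, p) for p in range(spec.n_participants)]
    return series, gt, mask


def aggregate_by_rating(beta_series: BetaSeries) -> list[ActivationMap]:
    """Per-rating mean maps over no-shock trials (levels with no trials absent)."""
    table = beta_series.table
    keep = ~table["shock_followed"].to_numpy(dtype=bool)
    if not keep.any():
        warnings.warn("all trials were followed by a shock; no rating maps produced")
        return []
    maps = []
    participant = table["participant"].iloc[0] if "participant" in table else None
    for rating in sorted(table.loc[keep, "rating"].unique()):
        sel = keep & (table["rating"].to_numpy() == rating)
        maps.append(
            ActivationMap(
                mask=beta_series.mask,
                values=beta_series.data[sel].mean(axis=0),
                participant=participant,
                kind="rating-level",
                rating=int(rating),
                meta={"n_trials": int(sel.sum())},
            )
        )
    return maps


# ---------------------------------------------------------------------------
# BOLD-level simulation


def simulate_bold(
    table: pd.DataFrame,
    pattern: ActivationMap,
    gain: float = 1.0,
    tr_s: float = 2.0,
    noise_sd: float = 0.0,
    ar_phi: float = 0.4,
    seed: int = 0,
    hrf: _glm.HRFSpec = _glm.HRFSpec(),
    signal_amplitude: float = 1.0,
    n_frames: int | None = None,
    n_motion_regressors: int = 6,
) -> tuple[Volume, pd.DataFrame]:
    """HRF-convolved BOLD series for one run's trial table plus nuisance table.

    Voxel series = Σ_trials amplitude_t · (boxcar ⊛ HRF) · pattern_v +
    AR(1) noise (stationary sd ``noise_sd``, lag-1 autocorrelation
    ``ar_phi``).  Amplitude_t = signal_amplitude · gain · rating_t.  The
    returned nuisance table holds motion-like random-walk regressors (not
    added to the data; they are inputs for the GLM nuisance block).
    """
    if (table["duration"] < 0).any():
        raise ValueError("durations must be nonnegative")
    rng = np.random.default_rng(seed)
    mask = pattern.mask
    if n_frames is None:
        t_end = float((table["onset"] + table["duration"]).max()) + hrf.kernel_length_s
        n_frames = int(np.ceil(t_end / tr_s))
    frame_times = np.arange(n_frames) * tr_s
    if float((table["onset"] + table["duration"]).max()) > n_frames * tr_s:
        raise ValueError("events do not fit within the scan length")

    amplitudes = signal_amplitude * gain * table["rating"].to_numpy(dtype=float)
    ts = _glm.sampled_regressor(
        table["onset"].to_numpy(),
        table["duration"].to_numpy(),
        frame_times,
        tr_s,
        hrf=hrf,
        amplitudes=amplitudes,
    )
    series = ts[:, None] * pattern.values[None, :]
    if noise_sd > 0:
        innov = rng.standard_normal((n_frames, mask.n_voxels))
        noise = np.empty_like(innov)
        noise[0] = innov[0]
        c = np.sqrt(1.0 - ar_phi**2)
        for t in range(1, n_frames):
            noise[t] = ar_phi * noise[t - 1] + c * innov[t]
        series = series + noise_sd * noise

    data4d = np.zeros(mask.grid.shape + (n_frames,))
    flat = data4d.reshape(-1, n_frames, order="C")
    flat[mask.indices] = series.T
    motion = np.cumsum(rng.normal(0.0, 0.02, size=(n_frames, n_motion_regressors)), axis=0)
    nuisance = pd.DataFrame(motion, columns=[f"motion_{i}" for i in range(n_motion_regressors)])
    nuisance["frame_time_s"] = frame_times
    return Volume(grid=mask.grid, data=data4d), nuisance


def null_spec(spec: SyntheticSpec) -> SyntheticSpec:
    """Copy of a spec with all rating-linked map structure removed.

    Under the null, ratings are statistically independent of every voxel:
    signal, arousal-confound and cue amplitudes are all zero.
    """
    return replace(spec, signal_amplitude=0.0, confound_amplitude=0.0, visual_amplitude=0.0)
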