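"""First-level GLM: double-gamma HRF, design construction, voxelwise OLS.

Design matrices are built from event tables in one of two modes:

* ``per-rating`` — one boxcar regressor per observed anxious-arousal rating,
  restricted to anticipation epochs *not* followed by a shock (shock-followed
  anticipations, dummy trials, missed trials, outcome and rating epochs get
  separate no-interest regressors; fixation is the implicit baseline);
* ``per-trial`` — one regressor per no-shock anticipation trial, yielding
  the single-trial beta series used for within-individual modeling.

Task regressors are built on an oversampled time grid (dt = TR/16),
convolved with the canonical double-gamma HRF and sampled at frame
midpoints.  Runs are analyzed as temporally concatenated frames with
per-run intercepts.  Estimation is plain OLS per voxel (no prewhitening):
the betas feed a cross-validated decoder, not parametric time-series
inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr as _qr
from scipy.stats import gamma as gamma_dist

from .images import ActivationMap, BrainMask, Volume, vectorize

__all__ = [
    "HRFSpec",
    "NuisanceSpec",
    "DesignMatrix",
    "RankDeficientDesignError",
    "canonical_hrf",
    "sampled_regressor",
    "motion_24",
    "dct_drift_basis",
    "build_design",
    "fit_glm",
    "GLMResult",
]


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma canonical HRF parameters (seconds).

    Defaults follow the widespread convention: peak delay 6 s, undershoot
    delay 16 s, unit dispersions, peak:undershoot ratio 6, 32 s kernel.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length_s: float = 32.0

    def __post_init__(self) -> None:
        for name in (
            "peak_delay_s",
            "undershoot_delay_s",
            "peak_dispersion",
            "undershoot_dispersion",
            "peak_undershoot_ratio",
            "kernel_length_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def canonical_hrf(spec: HRFSpec = HRFSpec(), dt_s: float = 0.1) -> np.ndarray:
    """Sample the double-gamma kernel at ``dt_s``; peak-normalized to max 1.

    kernel(t) = gamma_pdf(t; peak) − gamma_pdf(t; undershoot) / ratio, with
    gamma shape = delay / dispersion and scale = dispersion.
    """
    n = spec.kernel_length_s / dt_s
    if abs(n - round(n)) > 1e-9:
        raise ValueError("dt_s must divide kernel_length_s")
    t = np.arange(0, round(n) + 1) * dt_s
    peak = gamma_dist.pdf(t, a=spec.peak_delay_s / spec.peak_dispersion, scale=spec.peak_dispersion)
    under = gamma_dist.pdf(
        t, a=spec.undershoot_delay_s / spec.undershoot_dispersion, scale=spec.undershoot_dispersion
    )
    kernel = peak - under / spec.peak_undershoot_ratio
    return kernel / kernel.max()


def sampled_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    frame_times_s: np.ndarray,
    tr_s: float,
    hrf: HRFSpec = HRFSpec(),
    oversample: int = 16,
    amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at frame midpoints.

    ``frame_times_s`` are acquisition-start times, 0-based within the run;
    the convolved response is evaluated at ``frame_time + tr/2``.
    Overlapping boxcars sum.  This helper is the single convolution
    convention shared by design construction and the BOLD simulator.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if np.any(durations < 0):
        raise ValueError("durations must be nonnegative")
    if amplitudes is None:
        amplitudes = np.ones_like(onsets)
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    dt = tr_s / oversample
    t_end = float(frame_times_s[-1]) + tr_s + hrf.kernel_length_s
    grid = np.arange(0.0, t_end + dt, dt)
    box = np.zeros_like(grid)
    for on, dur, amp in zip(onsets, durations, amplitudes):
        box[(grid >= on) & (grid < on + dur)] += amp
    kernel = canonical_hrf(hrf, dt_s=dt)
    conv = np.convolve(box, kernel)[: grid.size]
    return np.interp(np.asarray(frame_times_s, dtype=float) + tr_s / 2.0, grid, conv)


@dataclass(frozen=True)
class NuisanceSpec:
    """Nuisance regressor configuration.

    ``motion_expansion`` builds the 24-parameter motion set from 6 inputs
    (6 demeaned + their first differences + squares of those 12); spike
    frames are flagged when framewise displacement exceeds
    ``fd_spike_threshold_mm`` (default 0.50 mm) or are listed explicitly.
    """

    motion_expansion: bool = True
    fd_spike_threshold_mm: float = 0.50
    extra_spikes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.fd_spike_threshold_mm <= 0:
            raise ValueError("fd_spike_threshold_mm must be positive")


def motion_24(motion: np.ndarray) -> np.ndarray:
    """Expand 6 realignment parameters to the 24-parameter set."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be an (n_frames, 6) array")
    demeaned = motion - motion.mean(axis=0)
    deriv = np.diff(demeaned, axis=0, prepend=demeaned[:1])
    twelve = np.hstack([demeaned, deriv])
    return np.hstack([twelve, twelve**2])


def dct_drift_basis(frame_times_s: np.ndarray, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass drift columns (periods > cutoff; no constant)."""
    ft = np.asarray(frame_times_s, dtype=float)
    n = ft.size
    duration = ft[-1] - ft[0] + (ft[1] - ft[0] if n > 1 else 1.0)
    order = int(np.floor(2.0 * duration / cutoff_s))
    if order < 1:
        return np.empty((n, 0))
    k = np.arange(1, order + 1)
    u = (ft - ft[0]) / duration
    return np.cos(np.pi * np.outer(u, k) * 1.0) * np.sqrt(2.0 / n)


@dataclass
class DesignMatrix:
    """Concatenated-run design: frame times, named columns, run labels."""

    frame_times_s: np.ndarray
    matrix: pd.DataFrame
    run_labels: np.ndarray
    task_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matrix.columns.duplicated().any():
            dupes = self.matrix.columns[self.matrix.columns.duplicated()].tolist()
            raise ValueError(f"duplicate design column names: {dupes}")
        if len(self.matrix) != len(self.frame_times_s):
            raise ValueError("design rows must match number of frames")
        for col in self.task_columns:
            if not np.any(self.matrix[col].to_numpy() != 0):
                raise ValueError(f"all-zero task column: {col}")


class RankDeficientDesignError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


def build_design(
    events: pd.DataFrame,
    frame_times_s: np.ndarray,
    tr_s: float,
    hrf: HRFSpec = HRFSpec(),
    mode: str = "per-rating",
    run_labels: np.ndarray | None = None,
    motion: np.ndarray | None = None,
    fd_mm: np.ndarray | None = None,
    nuisance: NuisanceSpec = NuisanceSpec(),
    highpass_s: float | None = 128.0,
    oversample: int = 16,
    dummy_grouping: str = "together",
) -> DesignMatrix:
    """Build the concatenated-run design matrix from an event table.

    ``events`` uses within-run onsets; rows with ``event_type`` other than
    "anticipation" (e.g. "outcome", "rating") become no-interest columns.
    A requested rating level with no events is simply omitted.  Dummy
    trials (condition == "dummy") are modeled together or split fast/slow
    via ``dummy_grouping`` ("together" | "split", using a ``speed``
    column when present).
    """
    frame_times_s = np.asarray(frame_times_s, dtype=float)
    n_frames = frame_times_s.size
    if run_labels is None:
        run_labels = np.zeros(n_frames, dtype=int)
    run_labels = np.asarray(run_labels)
    runs = [r for r in pd.unique(run_labels)]

    ev = events.copy()
    if "event_type" not in ev.columns:
        ev["event_type"] = "anticipation"

    antic = ev[ev["event_type"] == "anticipation"]
    is_dummy = antic["condition"].astype(str) == "dummy"
    missed = antic["rating"].isna() & ~is_dummy
    shock = antic["shock_followed"].astype(bool) & ~is_dummy & ~missed
    valid = ~is_dummy & ~missed & ~shock

    groups: list[tuple[str, pd.DataFrame]] = []
    if mode == "per-rating":
        for rating in sorted(antic.loc[valid, "rating"].dropna().unique()):
            groups.append((f"rating_{int(rating)}", antic[valid & (antic["rating"] == rating)]))
    elif mode == "per-trial":
        for i, (_, row) in enumerate(antic[valid].iterrows()):
            groups.append((f"trial_{i:03d}", pd.DataFrame([row])))
    else:
        raise ValueError("mode must be 'per-rating' or 'per-trial'")
    n_task = len(groups)

    # no-interest task-locked regressors
    if shock.any():
        groups.append(("anticipation_shock", antic[shock]))
    if missed.any():
        groups.append(("missed", antic[missed]))
    if is_dummy.any():
        if dummy_grouping == "split" and "speed" in antic.columns:
            for speed in sorted(antic.loc[is_dummy, "speed"].astype(str).unique()):
                sel = is_dummy & (antic["speed"].astype(str) == speed)
                groups.append((f"dummy_{speed}", antic[sel]))
        else:
            groups.append(("dummy", antic[is_dummy]))
    for etype, name in (("outcome", "outcome"), ("rating", "rating_period")):
        rows = ev[ev["event_type"] == etype]
        if len(rows):
            groups.append((name, rows))

    cols: dict[str, np.ndarray] = {}
    for name, rows in groups:
        column = np.zeros(n_frames)
        for run in runs:
            sel = run_labels == run
            rrows = rows[rows["run"] == run] if "run" in rows.columns else rows
            if not len(rrows):
                continue
            run_ft = frame_times_s[sel] - frame_times_s[sel][0]
            column[sel] = sampled_regressor(
                rrows["onset"].to_numpy(),
                rrows["duration"].to_numpy(),
                run_ft,
                tr_s,
                hrf=hrf,
                oversample=oversample,
            )
        cols[name] = column
    task_names = [name for name, _ in groups[:n_task]]

    # nuisance block
    if motion is not None:
        block = motion_24(motion) if nuisance.motion_expansion else np.asarray(motion, float)
        for i in range(block.shape[1]):
            cols[f"motion_{i:02d}"] = block[:, i]
    spikes = set(int(i) for i in nuisance.extra_spikes)
    if fd_mm is not None:
        spikes |= set(np.flatnonzero(np.asarray(fd_mm) > nuisance.fd_spike_threshold_mm).tolist())
    for i in sorted(spikes):
        onehot = np.zeros(n_frames)
        onehot[i] = 1.0
        cols[f"spike_{i:04d}"] = onehot
    for run in runs:
        sel = run_labels == run
        if highpass_s is not None:
            drift = dct_drift_basis(frame_times_s[sel] - frame_times_s[sel][0], highpass_s)
            for i in range(drift.shape[1]):
                column = np.zeros(n_frames)
                column[sel] = drift[:, i]
                cols[f"drift_run{run}_{i:02d}"] = column
        intercept = np.zeros(n_frames)
        intercept[sel] = 1.0
        cols[f"intercept_run{run}"] = intercept

    matrix = pd.DataFrame(cols, index=np.arange(n_frames))
    return DesignMatrix(
        frame_times_s=frame_times_s,
        matrix=matrix,
        run_labels=run_labels,
        task_columns=task_names,
    )


@dataclass
class GLMResult:
    betas: dict[str, ActivationMap]
    residual_variance: ActivationMap
    dof: int

    def beta_matrix(self) -> np.ndarray:
        return np.vstack([m.values for m in self.betas.values()])


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R, piv = _qr(X, pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def fit_glm(bold: Volume, mask: BrainMask, design: DesignMatrix) -> GLMResult:
    """Ordinary least squares per voxel; returns betas for task columns.

    Raises :class:`RankDeficientDesignError` naming collinear columns.
    """
    if bold.data.ndim != 4:
        raise ValueError("fit_glm expects a 4-D BOLD volume")
    Y = vectorize(bold, mask)  # (n_frames, n_voxels)
    X = design.matrix.to_numpy(dtype=float)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("number of frames does not match design rows")
    names = list(design.matrix.columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise RankDeficientDesignError(f"design is rank deficient; collinear columns: {bad}")
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = Y.shape[0] - X.shape[1]
    resid_var = (resid**2).sum(axis=0) / max(dof, 1)
    betas = {
        name: ActivationMap(mask=mask, values=coef[names.index(name)], kind="trial" if name.startswith("trial_") else "rating-level")
        for name in design.task_columns
    }
    return GLMResult(
        betas=betas,
        residual_variance=ActivationMap(mask=mask, values=resid_var, kind="contrast"),
        dof=dof,
    )
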