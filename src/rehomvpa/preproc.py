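"""Temporal preprocessing of aligned 4D BOLD data.

Stages (in pipeline order): motion quality control, discard of initial
volumes, nuisance regression (six motion parameters, linear trend, mean
white-matter and ventricular signals, intercept), and band-pass filtering
in the 0.01-0.08 Hz band.  No spatial operations are performed — input
data are assumed aligned on a common grid and are deliberately not
smoothed, preserving the fine-grained local pattern that regional
homogeneity measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .errors import ConfigurationError, FormatError

__all__ = [
    "MotionQCConfig",
    "PreprocConfig",
    "MotionQCResult",
    "qc_motion",
    "discard_initial",
    "regress_nuisance",
    "bandpass",
    "build_nuisance_design",
    "preprocess_subject",
]

_MOTION_AXES = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass(frozen=True)
class MotionQCConfig:
    """Head-motion exclusion gate: 1.5 mm translation / 1.5 deg rotation."""

    max_translation_mm: float = 1.5
    max_rotation_deg: float = 1.5

    def __post_init__(self):
        if self.max_translation_mm <= 0 or self.max_rotation_deg <= 0:
            raise ConfigurationError("motion QC thresholds must be positive")


@dataclass(frozen=True)
class PreprocConfig:
    """Temporal preprocessing parameters.

    ``nuisance_set`` selects design columns by name from
    ``{"motion6", "linear_trend", "wm_mean", "csf_mean", "intercept"}``.
    ``filter_type`` is the ideal rectangular DFT filter by default; a
    zero-phase Butterworth (order 2, filtfilt) is available as a variant.
    """

    n_discard: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    tr_s: float = 2.0
    nuisance_set: frozenset = field(
        default_factory=lambda: frozenset(
            {"motion6", "linear_trend", "wm_mean", "csf_mean", "intercept"}
        )
    )
    filter_type: str = "ideal"  # "ideal" | "butterworth"

    def __post_init__(self):
        nyquist = 1.0 / (2.0 * self.tr_s)
        if not (0.0 <= self.band_low_hz < self.band_high_hz < nyquist):
            raise ConfigurationError(
                f"band [{self.band_low_hz}, {self.band_high_hz}] Hz must lie "
                f"inside (0, Nyquist={nyquist:.4f}) Hz"
            )
        if self.n_discard < 0:
            raise ConfigurationError("n_discard must be >= 0")


@dataclass
class MotionQCResult:
    passed: bool
    offending_axis: str | None = None
    max_abs: float = 0.0


def qc_motion(motion: np.ndarray, config: MotionQCConfig | None = None) -> MotionQCResult:
    """Check a t x 6 motion table against the translation/rotation gate.

    A subject fails if any |translation| strictly exceeds the translation
    threshold on any cardinal axis at any time, or any |rotation| strictly
    exceeds the rotation threshold (boundary values pass).
    """
    config = config or MotionQCConfig()
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise FormatError(
            f"motion table must have 6 columns (3 translations mm, "
            f"3 rotations deg); got shape {motion.shape}"
        )
    limits = [config.max_translation_mm] * 3 + [config.max_rotation_deg] * 3
    peaks = np.abs(motion).max(axis=0)
    for axis, peak, limit in zip(_MOTION_AXES, peaks, limits):
        if peak > limit:
            return MotionQCResult(False, axis, float(peak))
    return MotionQCResult(True, None, float(peaks.max(initial=0.0)))


def discard_initial(bold: np.ndarray, n_discard: int) -> np.ndarray:
    """Drop the first ``n_discard`` frames (magnetization equilibration)."""
    n_t = bold.shape[-1]
    if n_discard >= n_t:
        raise ConfigurationError(
            f"cannot discard {n_discard} of {n_t} volumes"
        )
    return bold[..., n_discard:]


def regress_nuisance(ts: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Residualize time series against a nuisance design by least squares.

    ``ts`` may be a single t-vector or a (t, m) matrix of series; the same
    design is removed from every column.  Residuals are orthogonal to every
    design column.  Raises on a rank-deficient design, naming the collinear
    columns.
    """
    X = np.asarray(regressors, dtype=float)
    if X.ndim != 2:
        raise FormatError("regressors must be a t x k matrix")
    t, k = X.shape
    if t <= k:
        raise ConfigurationError(f"need more time points ({t}) than regressors ({k})")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name columns whose removal restores full rank
        bad = [
            str(j)
            for j in range(k)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ConfigurationError(
            f"nuisance design is rank-deficient (rank {rank} < {k} columns); "
            f"collinear columns: {', '.join(bad) or 'unidentified'}"
        )
    Y = np.asarray(ts, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return resid[:, 0] if squeeze else resid


def bandpass(
    ts: np.ndarray,
    tr_s: float,
    low_hz: float,
    high_hz: float,
    filter_type: str = "ideal",
) -> np.ndarray:
    """Band-pass filter along the last axis.

    The default "ideal" filter zeroes every discrete-Fourier bin whose
    frequency lies outside ``[low_hz, high_hz]`` (including DC) and is
    therefore exactly linear and idempotent on bin-aligned content.
    ``filter_type="butterworth"`` applies a zero-phase order-2 Butterworth
    instead.
    """
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0.0 <= low_hz < high_hz < nyquist):
        raise ConfigurationError(
            f"band [{low_hz}, {high_hz}] Hz outside (0, Nyquist={nyquist:.4f})"
        )
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[-1]
    if filter_type == "butterworth":
        sos = _signal.butter(
            2, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_s, output="sos"
        )
        return _signal.sosfiltfilt(sos, ts, axis=-1)
    if filter_type != "ideal":
        raise ConfigurationError(f"unknown filter_type {filter_type!r}")
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(ts, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def build_nuisance_design(
    motion: np.ndarray,
    wm_mean: np.ndarray | None,
    csf_mean: np.ndarray | None,
    nuisance_set: frozenset,
) -> np.ndarray:
    """Assemble the t x k nuisance design from the selected components."""
    t = motion.shape[0]
    cols = []
    if "intercept" in nuisance_set:
        cols.append(np.ones(t))
    if "linear_trend" in nuisance_set:
        cols.append(np.linspace(-1.0, 1.0, t))
    if "motion6" in nuisance_set:
        cols.extend(np.asarray(motion, float).T)
    if "wm_mean" in nuisance_set:
        if wm_mean is None:
            raise ConfigurationError("wm_mean requested but no WM mask signal given")
        cols.append(np.asarray(wm_mean, float))
    if "csf_mean" in nuisance_set:
        if csf_mean is None:
            raise ConfigurationError("csf_mean requested but no CSF mask signal given")
        cols.append(np.asarray(csf_mean, float))
    if not cols:
        raise ConfigurationError("empty nuisance set")
    return np.column_stack(cols)


def preprocess_subject(
    bold: np.ndarray,
    motion: np.ndarray,
    wm_mask: np.ndarray | None,
    csf_mask: np.ndarray | None,
    config: PreprocConfig | None = None,
) -> np.ndarray:
    """Full temporal pipeline for one subject.

    Order: discard initial volumes -> nuisance regression -> band-pass.
    Returns the preprocessed 4D array (time length reduced by
    ``n_discard``).
    """
    config = config or PreprocConfig()
    bold = discard_initial(np.asarray(bold, dtype=float), config.n_discard)
    motion = np.asarray(motion, dtype=float)[config.n_discard :]
    if motion.shape[0] != bold.shape[-1]:
        raise FormatError(
            "motion table and BOLD series have different time lengths"
        )
    wm_mean = bold[wm_mask].mean(axis=0) if ("wm_mean" in config.nuisance_set) else None
    csf_mean = (
        bold[csf_mask].mean(axis=0) if ("csf_mean" in config.nuisance_set) else None
    )
    X = build_nuisance_design(motion, wm_mean, csf_mean, config.nuisance_set)
    shape = bold.shape
    flat = bold.reshape(-1, shape[-1]).T  # (t, n_voxels)
    resid = regress_nuisance(flat, X)
    filtered = bandpass(
        resid.T, config.tr_s, config.band_low_hz, config.band_high_hz,
        filter_type=config.filter_type,
    )
    return filtered.reshape(shape)
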