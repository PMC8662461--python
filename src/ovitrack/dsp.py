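"""FMCW radar signal processing: range-azimuth maps, clutter normalization,
per-frame target detection, and 2D track assembly.

The clutter-mitigation statistic is the standardized amplitude

    D(t, r, theta) = (S(t, r, theta) - mean(r, theta)) / std(r, theta)

where ``mean`` and ``std`` are the per-cell time statistics of the radar
signal recorded with no animal in the arena. A target then shows up as a
cell whose amplitude is many background standard deviations above its own
background mean, regardless of how strongly that cell normally reflects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import get_window
from sklearn.base import BaseEstimator, TransformerMixin

from .config import C, ArenaConfig, RadarConfig
from .trajectory import Trajectory


@dataclass
class RangeAzimuthFrame:
    """One radar measurement S(t, r, theta) on the polar (range x angle) grid."""

    timestamp: float
    values: np.ndarray  # (n_range_bins, n_angle_bins), non-negative amplitudes
    radar: RadarConfig

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        expected = (self.radar.n_range_bins, self.radar.n_angle_bins)
        if self.values.shape != expected:
            raise ValueError(f"frame shape {self.values.shape} != grid {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("frame amplitudes must be finite")


@dataclass
class ClutterStats:
    """Per-cell time mean and standard deviation of the background signal."""

    mean: np.ndarray
    std: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        if self.mean.shape != self.std.shape:
            raise ValueError("mean/std shapes differ")
        if np.any(self.std < 0):
            raise ValueError("std must be non-negative")


@dataclass
class Detection:
    """Per-frame target fix on the polar grid (sub-bin refined)."""

    timestamp: float
    range_m: float
    azimuth_deg: float
    score: float
    valid: bool


def _stack(frames) -> np.ndarray:
    """Accept an (n, R, A) array or a list of frames/arrays."""
    if isinstance(frames, np.ndarray) and frames.ndim == 3:
        return frames
    arrs = [f.values if isinstance(f, RangeAzimuthFrame) else np.asarray(f)
            for f in frames]
    return np.stack(arrs)


def frame_to_map(raw: np.ndarray, radar: RadarConfig,
                 window_name: str = "hann", timestamp: float = 0.0
                 ) -> RangeAzimuthFrame:
    """Convert one raw beat-signal frame to a range-azimuth amplitude map.

    ``raw`` is complex, shape (fast-time samples, virtual channels). A
    windowed FFT along fast-time maps beat frequency to range
    (r = f_b c T_ramp / 2B, one bin = c/2B); a windowed, zero-padded FFT
    across the virtual array maps spatial frequency to sin(azimuth). The
    output is scaled by the window coherent gains so an isolated unit-
    amplitude tone peaks near 1.
    """
    raw = np.asarray(raw)
    if raw.shape != (radar.n_fast_samples, radar.n_channels):
        raise ValueError(
            f"raw frame shape {raw.shape} != "
            f"({radar.n_fast_samples}, {radar.n_channels})")
    w_fast = get_window(window_name, radar.n_fast_samples, fftbins=True)
    w_ch = get_window(window_name, radar.n_channels, fftbins=True)
    z = raw * w_fast[:, None] * w_ch[None, :]
    spec = np.fft.fft(z, axis=0)[: radar.n_range_bins]
    spec = np.fft.fftshift(np.fft.fft(spec, n=radar.n_angle_bins, axis=1), axes=1)
    scale = 1.0 / (w_fast.sum() * w_ch.sum())
    return RangeAzimuthFrame(timestamp, np.abs(spec) * scale, radar)


class ClutterNormalizer(BaseEstimator, TransformerMixin):
    """Standardize radar frames by the per-cell background statistics.

    ``fit`` estimates the per-cell time mean and standard deviation from
    frames recorded with the animal absent; ``transform`` returns the
    standardized amplitude D = (S - mean) / max(std, eps).

    Parameters
    ----------
    eps : float
        Guard for zero-variance cells (the division is undefined there);
        amplitude units.
    """

    def __init__(self, eps: float = 1e-12):
        self.eps = eps

    def fit(self, X, y=None):
        X = _stack(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 background frames")
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0, ddof=1)
        self.n_frames_ = X.shape[0]
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "mean_")
        X = np.asarray(X)
        single = X.ndim == 2
        S = _stack([X] if single else X)
        if S.shape[1:] != self.mean_.shape:
            raise ValueError(f"frame grid {S.shape[1:]} != clutter grid "
                             f"{self.mean_.shape}")
        D = (S - self.mean_) / np.maximum(self.std_, self.eps)
        return D[0] if single else D

    @property
    def clutter_stats_(self) -> ClutterStats:
        return ClutterStats(self.mean_, self.std_, self.n_frames_)


def estimate_clutter(background_frames) -> ClutterStats:
    """Per-cell sample mean/std of the animal-absent recording (>= 2 frames)."""
    norm = ClutterNormalizer().fit(background_frames)
    return norm.clutter_stats_


def normalize_frame(frame, clutter: ClutterStats, eps: float = 1e-12):
    """Apply D = (S - mean) / max(std, eps) cell-wise.

    Accepts a :class:`RangeAzimuthFrame` (returns one) or a bare array.
    """
    norm = ClutterNormalizer(eps=eps)
    norm.mean_, norm.std_, norm.n_frames_ = clutter.mean, clutter.std, clutter.n_frames
    if isinstance(frame, RangeAzimuthFrame):
        D = norm.transform(frame.values)
        out = RangeAzimuthFrame.__new__(RangeAzimuthFrame)
        out.timestamp, out.values, out.radar = frame.timestamp, D, frame.radar
        return out
    return norm.transform(np.asarray(frame))


def _parabolic_offset(a_minus: float, a0: float, a_plus: float) -> float:
    denom = a_minus - 2.0 * a0 + a_plus
    if denom >= 0:  # not a local peak / flat
        return 0.0
    return float(np.clip(0.5 * (a_minus - a_plus) / denom, -0.5, 0.5))


def detect_target(D, radar: RadarConfig, threshold: float = 5.0,
                  timestamp: float | None = None) -> Detection:
    """Locate the animal as the global maximum of the standardized map.

    Returns an invalid detection when no cell reaches ``threshold``. The
    peak is refined to sub-bin precision by 3-point parabolic interpolation
    along each axis (range bins, then sin-azimuth bins). Ties are broken
    toward the smaller range bin, then the smaller angle bin (row-major
    argmax order).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(D, RangeAzimuthFrame):
        if timestamp is None:
            timestamp = D.timestamp
        vals = D.values
    else:
        vals = np.asarray(D)
    if timestamp is None:
        timestamp = 0.0
    i, j = np.unravel_index(int(np.argmax(vals)), vals.shape)
    score = float(vals[i, j])
    if score < threshold:
        return Detection(timestamp, np.nan, np.nan, score, False)
    di = dj = 0.0
    if 0 < i < vals.shape[0] - 1:
        di = _parabolic_offset(vals[i - 1, j], vals[i, j], vals[i + 1, j])
    if 0 < j < vals.shape[1] - 1:
        dj = _parabolic_offset(vals[i, j - 1], vals[i, j], vals[i, j + 1])
    range_m = (i + di) * radar.range_bin_width
    sin_theta = (j + dj - radar.n_angle_bins // 2) / (
        radar.n_angle_bins * radar.element_spacing)
    azimuth = float(np.degrees(np.arcsin(np.clip(sin_theta, -1.0, 1.0))))
    return Detection(timestamp, float(range_m), azimuth, score, True)


def assemble_track(detections: list[Detection], rate: float,
                   arena: ArenaConfig) -> Trajectory:
    """Build the 2D arena-coordinate trajectory from per-frame detections.

    Valid fixes are converted polar -> Cartesian using the radar pose. Runs
    of invalid detections are filled by constant-velocity interpolation
    between the flanking valid fixes (the same rule the video pipeline uses
    for missed frames); leading/trailing gaps hold the nearest valid fix.
    Out-of-arena fixes are clamped to the walls.
    """
    if not detections:
        raise ValueError("no detections")
    times = np.array([d.timestamp for d in detections])
    order = np.argsort(times)
    detections = [detections[i] for i in order]
    times = times[order]
    valid = np.array([d.valid for d in detections], dtype=bool)
    if not valid.any():
        raise ValueError("zero valid detections")
    rx, ry = arena.radar_position
    head = np.radians(arena.radar_heading)
    r = np.array([d.range_m if d.valid else np.nan for d in detections])
    az = np.radians([d.azimuth_deg if d.valid else np.nan for d in detections])
    x = rx + r * np.sin(az + head)
    y = ry + r * np.cos(az + head)
    tv = times[valid]
    x = np.interp(times, tv, x[valid])
    y = np.interp(times, tv, y[valid])
    x = np.clip(x, *arena.x_limits)
    y = np.clip(y, *arena.y_limits)
    phase = np.minimum(arena.phase_of(times), arena.n_phases)
    return Trajectory(times, x, y, phase, source="radar", valid=valid)


def range_resolution(bandwidth: float) -> float:
    """Theoretical range resolution c / (2 B) [m] (5 cm at B = 3 GHz)."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    return C / (2.0 * bandwidth)


def free_space_gain(f_high: float, f_low: float) -> float:
    """Free-space path-loss gain from operating at ``f_low`` instead of
    ``f_high``: 20 log10(f_high / f_low) [dB] (10.13 dB for 77 vs 24 GHz)."""
    if f_high <= 0 or f_low <= 0:
        raise ValueError("frequencies must be positive")
    return 20.0 * np.log10(f_high / f_low)
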