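"""Ricker-wavelet change detection on the position signals.

Each coordinate of the trajectory is filtered with Ricker ("Mexican hat")
kernels over a ladder of time scales; the zero-mean kernel annihilates
constant and linear trends, so coefficient energy concentrates where the
animal changes its way of moving. Counting the local maxima of the
|coefficient| field over (scale x time) gives a per-axis, per-phase count
of movement transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .trajectory import Trajectory


@dataclass
class CwtResult:
    """Continuous wavelet transform of one coordinate signal.

    ``coefficients`` has one row per scale (scales in samples);
    ``supports`` holds the kernel support length used at each scale, which
    downstream counting uses to exclude boundary-contaminated columns.
    """

    scales: np.ndarray
    coefficients: np.ndarray  # (n_scales, n_times)
    axis: str = "X"
    supports: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, float)
        self.coefficients = np.asarray(self.coefficients, float)
        if self.coefficients.shape[0] != len(self.scales):
            raise ValueError("one coefficient row per scale required")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")


@dataclass
class TransitionCount:
    """Number (and locations) of detected movement changes."""

    axis: str
    phase: int | None
    count: int
    maxima_positions: list[tuple[int, int]]  # (scale row, time index)

    def __post_init__(self) -> None:
        if self.count != len(self.maxima_positions):
            raise ValueError("count must equal number of maxima")


def ricker_kernel(scale: float, support: int | None = None) -> np.ndarray:
    """L2-normalized Ricker kernel psi(t) ~ (1 - (t/a)^2) exp(-t^2 / 2a^2).

    ``scale`` a is in samples; the default support is the smallest odd
    length >= 8 a. The kernel is zero-mean (to numerical precision), peaks
    at its centre, and has zero crossings at t = +/- a.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if support is None:
        support = int(np.ceil(8 * scale))
    if support < 8 * scale - 1e-9:
        raise ValueError("support must be at least 8 * scale")
    if support % 2 == 0:
        support += 1
    t = np.arange(support) - support // 2
    u = t / scale
    psi = (1.0 - u ** 2) * np.exp(-0.5 * u ** 2)
    psi -= psi.mean()  # exact zero mean on the truncated support
    return psi / np.linalg.norm(psi)


def default_scales(rate: float, t_min: float = 0.2, t_max: float = 2.0,
                   n: int = 8) -> np.ndarray:
    """Geometric ladder of n scales from ``t_min`` to ``t_max`` seconds,
    expressed in samples at the native rate.

    The ladder tops out at 2 s: a kernel of scale a needs 8 a of support,
    and within 60-s phases much longer kernels leave little usable interior
    after the boundary margin while smearing changes spaced a few seconds
    apart into each other.
    """
    return np.geomspace(t_min * rate, t_max * rate, n)


def cwt(signal: np.ndarray, scales, axis: str = "X") -> CwtResult:
    """Convolve the position signal with the Ricker kernel at each scale.

    Same-length output with reflective boundary padding; a constant signal
    (and any linear ramp, in the interior) maps to ~0 at every scale.
    """
    scales = np.atleast_1d(np.asarray(scales, float))
    if scales.size == 0:
        raise ValueError("scale list is empty")
    signal = np.asarray(signal, float)
    n = len(signal)
    rows, supports = [], []
    for a in scales:
        k = ricker_kernel(a)
        if n <= len(k):
            raise ValueError(
                f"signal length {n} too short for scale {a} "
                f"(kernel support {len(k)})")
        half = len(k) // 2
        padded = np.pad(signal, half, mode="reflect")
        rows.append(fftconvolve(padded, k, mode="valid"))
        supports.append(len(k))
    return CwtResult(scales, np.vstack(rows), axis=axis,
                     supports=np.asarray(supports))


def count_transitions(result: CwtResult, phase_mask: np.ndarray | None = None,
                      rel_threshold: float = 0.1,
                      phase: int | None = None,
                      abs_floor: float = 1e-9) -> TransitionCount:
    """Count local maxima of |coefficients| in the (scale x time) field.

    A local maximum is a cell strictly greater than its 8 neighbours with
    value >= ``rel_threshold`` x the field maximum (taken inside the phase
    mask). Columns within half a kernel support of the signal boundary are
    excluded per scale. ``abs_floor`` (coefficient units; positions are in
    metres) keeps numerical noise on a flat signal from registering as
    movement. Maxima are enumerated scale-major so counts and positions are
    reproducible.
    """
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must be in (0, 1)")
    A = np.abs(result.coefficients)
    n_scales, n_t = A.shape
    if phase_mask is None:
        phase_mask = np.ones(n_t, bool)
    else:
        phase_mask = np.asarray(phase_mask, bool)
        if phase_mask.shape != (n_t,):
            raise ValueError("phase mask length must match the time axis")
        if not phase_mask.any():
            raise ValueError("empty phase mask")
    supports = (result.supports if result.supports is not None
                else np.ceil(8 * result.scales).astype(int))
    # boundary-contaminated columns (within half a kernel support of either
    # signal end, per scale) are invalid: excluded as candidates, barred
    # from suppressing valid neighbours, and ignored by the field maximum
    A = A.copy()
    cols = np.arange(n_t)
    for i in range(n_scales):
        margin = int(supports[i]) // 2
        A[i, (cols < margin) | (cols >= n_t - margin)] = -np.inf
    valid_cols = A[:, phase_mask]
    field_max = valid_cols[np.isfinite(valid_cols)].max(initial=0.0)
    if field_max <= abs_floor:
        return TransitionCount(result.axis, phase, 0, [])
    # strict 8-neighbour maxima, vectorized; pad with -inf so edges compare
    P = np.pad(A, 1, mode="constant", constant_values=-np.inf)
    core = P[1:-1, 1:-1]
    is_max = np.isfinite(A)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            is_max &= core > P[1 + di:1 + di + n_scales, 1 + dj:1 + dj + n_t]
    is_max &= A >= rel_threshold * field_max
    is_max &= phase_mask[None, :]
    positions = [tuple(p) for p in np.argwhere(is_max)]  # scale-major order
    return TransitionCount(result.axis, phase, len(positions), positions)


def transition_features(traj: Trajectory, scales=None, phases=(2, 3),
                        rel_threshold: float = 0.1) -> dict:
    """Wavelet transition counts per axis (X lateral, Y longitudinal) and
    per phase: ``{("X", 2): count, ("Y", 2): ..., ...}``.

    The CWT runs once over the whole signal per axis; counts are taken
    inside each phase's time mask so phase boundaries introduce no edge
    artefacts of their own.
    """
    if scales is None:
        scales = default_scales(traj.rate)
    out = {}
    for axis, sig in (("X", traj.x), ("Y", traj.y)):
        res = cwt(sig, scales, axis=axis)
        for p in phases:
            mask = traj.phase == p
            if not mask.any():
                raise ValueError(f"trajectory has no samples in phase {p}")
            tc = count_transitions(res, phase_mask=mask,
                                   rel_threshold=rel_threshold, phase=p)
            out[(axis, p)] = tc.count
    return out
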