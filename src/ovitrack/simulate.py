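"""Synthetic radar sessions: clutter scenes, frame synthesis, covariates.

Every downstream stage is testable without recorded data. Two synthesis
levels are provided:

* ``synthesize_beat_signal`` — the physical FMCW model: each point
  reflector at range r contributes a complex tone of beat frequency
  f_b = 2 B r / (c T_ramp) across fast-time, with the array-geometry phase
  ramp 2 pi d sin(theta) / lambda across the virtual channels.
* ``synthesize_map`` — a map-level shortcut placing a small separable
  point-spread (about one bin wide per axis) straight onto the
  range-azimuth grid, bypassing the FFTs; used to exercise the clutter /
  detection / tracking stages in isolation and at scale.

Both levels use the deterministic two-way propagation phase
(-4 pi r / lambda) for each reflector, so the static clutter is identical
from frame to frame and only the additive circular Gaussian noise varies.
The animal is modelled as a single point reflector.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import ArenaConfig, RadarConfig
from .dsp import RangeAzimuthFrame, frame_to_map
from .occupancy import infrared_events
from .trajectory import (MovementState, Trajectory, TrajectoryModel,
                         default_movement_states, simulate_trajectory,
                         switching_matrix)

#: indices of the "active" movement modes in the default state order
_ACTIVE_STATES = (1, 2)


@dataclass
class ClutterScene:
    """Static reflectors: array of (range m, azimuth deg, amplitude) rows."""

    scatterers: np.ndarray

    def __post_init__(self) -> None:
        self.scatterers = np.atleast_2d(np.asarray(self.scatterers, float))
        if self.scatterers.size == 0:
            self.scatterers = np.empty((0, 3))
        if self.scatterers.shape[1] != 3:
            raise ValueError("scatterers must be (range, azimuth, amplitude)")
        if np.any(self.scatterers[:, 0] < 0):
            raise ValueError("scatterer ranges must be non-negative")

    @classmethod
    def empty(cls) -> "ClutterScene":
        return cls(np.empty((0, 3)))


def polar_from_arena(x, y, arena: ArenaConfig):
    """(range m, azimuth deg) of arena point(s) as seen from the radar."""
    rx, ry = arena.radar_position
    dx = np.asarray(x, float) - rx
    dy = np.asarray(y, float) - ry
    r = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dx, dy)) - arena.radar_heading
    return r, theta


def wall_clutter_scene(arena: ArenaConfig, radar: RadarConfig,
                       spacing: float = 0.25, amplitude: float = 2.0,
                       seed=None) -> ClutterScene:
    """Wall-like lines of scatterers along the three far pen walls.

    Scatterer amplitudes are drawn once (uniform in [0.5, 1.5] x amplitude)
    and are then static for the life of the scene. Points outside the radar
    field of view or beyond its maximum range are dropped, since the radar
    never illuminates them.
    """
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    x_lo, x_hi = arena.x_limits
    # side walls
    for xw in (x_lo, x_hi):
        yy = np.arange(0.0, arena.length + 1e-9, spacing)
        xs.append(np.full_like(yy, xw))
        ys.append(yy)
    # far wall (grid barrier end)
    xx = np.arange(x_lo, x_hi + 1e-9, spacing)
    xs.append(xx)
    ys.append(np.full_like(xx, arena.length))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    r, theta = polar_from_arena(x, y, arena)
    amp = amplitude * rng.uniform(0.5, 1.5, size=len(r))
    keep = (np.abs(theta) <= radar.field_of_view / 2) & (r < radar.max_range)
    return ClutterScene(np.column_stack([r[keep], theta[keep], amp[keep]]))


def _reflectors(position, scene: ClutterScene, radar: RadarConfig,
                arena: ArenaConfig | None, target_amplitude: float):
    """Stack clutter + (visible) target into (r, theta, amplitude) rows."""
    rows = [scene.scatterers] if len(scene.scatterers) else []
    if position is not None:
        if arena is None:
            r, theta = position  # already polar
        else:
            r, theta = polar_from_arena(position[0], position[1], arena)
        if r <= 0 or np.cos(np.radians(theta)) <= 0:
            raise ValueError("target behind the radar plane")
        # outside the antenna beam the target is simply not illuminated
        if abs(theta) <= radar.field_of_view / 2 and r < radar.max_range:
            rows.append(np.array([[r, theta, target_amplitude]]))
    if not rows:
        return np.empty((0, 3))
    return np.vstack(rows)


def synthesize_beat_signal(position, scene: ClutterScene, radar: RadarConfig,
                           seed=None, arena: ArenaConfig | None = None,
                           target_amplitude: float = 5.0) -> np.ndarray:
    """Raw complex beat signal, shape (fast-time samples, virtual channels).

    ``position`` is ``(x, y)`` in arena coordinates when ``arena`` is given,
    otherwise ``(range m, azimuth deg)``; ``None`` synthesizes background
    only. Additive circular Gaussian noise with per-component standard
    deviation ``noise_sigma / sqrt(2)``.
    """
    rng = np.random.default_rng(seed)
    refl = _reflectors(position, scene, radar, arena, target_amplitude)
    n_fast, n_ch = radar.n_fast_samples, radar.n_channels
    fs = n_fast / radar.ramp_time
    t = np.arange(n_fast) / fs
    m = np.arange(n_ch)
    out = np.zeros((n_fast, n_ch), dtype=complex)
    for r, theta, amp in refl:
        f_b = 2.0 * radar.bandwidth * r / (299_792_458.0 * radar.ramp_time)
        phi0 = -4.0 * np.pi * r / radar.wavelength
        ch_phase = 2.0 * np.pi * radar.element_spacing * np.sin(
            np.radians(theta)) * m
        out += amp * np.exp(1j * (2 * np.pi * f_b * t + phi0))[:, None] \
            * np.exp(1j * ch_phase)[None, :]
    if radar.noise_sigma > 0:
        s = radar.noise_sigma / np.sqrt(2.0)
        out = out + rng.normal(0, s, out.shape) + 1j * rng.normal(0, s, out.shape)
    return out


def _complex_point_map(refl: np.ndarray, radar: RadarConfig,
                       sigma_bins: float = 0.6, half_width: int = 4
                       ) -> np.ndarray:
    """Complex map of point-spread kernels (one per reflector row)."""
    R, A = radar.n_range_bins, radar.n_angle_bins
    out = np.zeros((R, A), dtype=np.complex64)
    for r, theta, amp in refl:
        ir = r / radar.range_bin_width
        ia = np.sin(np.radians(theta)) * A * radar.element_spacing + A // 2
        i0, j0 = int(round(ir)), int(round(ia))
        ii = np.arange(max(0, i0 - half_width), min(R, i0 + half_width + 1))
        jj = np.arange(max(0, j0 - half_width), min(A, j0 + half_width + 1))
        if len(ii) == 0 or len(jj) == 0:
            continue
        kr = np.exp(-0.5 * ((ii - ir) / sigma_bins) ** 2)
        ka = np.exp(-0.5 * ((jj - ia) / sigma_bins) ** 2)
        phase = np.exp(-4j * np.pi * r / radar.wavelength)
        out[np.ix_(ii, jj)] += (amp * phase) * np.outer(kr, ka).astype(
            np.complex64)
    return out


def clutter_complex_map(scene: ClutterScene, radar: RadarConfig) -> np.ndarray:
    """Static complex clutter map (time-invariant by construction)."""
    return _complex_point_map(scene.scatterers, radar)


def synthesize_map(position, scene: ClutterScene, radar: RadarConfig,
                   seed=None, arena: ArenaConfig | None = None,
                   target_amplitude: float = 5.0, timestamp: float = 0.0,
                   _clutter_map: np.ndarray | None = None
                   ) -> RangeAzimuthFrame:
    """Map-level frame: |static clutter + target kernel + complex noise|.

    Same conventions as :func:`synthesize_beat_signal`; the point spread is
    a separable Gaussian of about one bin width per axis centred on the
    reflector's fractional bin position.
    """
    rng = np.random.default_rng(seed)
    if _clutter_map is None:
        _clutter_map = clutter_complex_map(scene, radar)
    refl = _reflectors(position, scene, radar, arena, target_amplitude)
    n_clutter = len(scene.scatterers)
    target_rows = refl[n_clutter:] if len(refl) > n_clutter else np.empty((0, 3))
    z = _clutter_map + _complex_point_map(target_rows, radar)
    if radar.noise_sigma > 0:
        s = radar.noise_sigma / np.sqrt(2.0)
        shape = z.shape
        z = z + rng.normal(0, s, shape) + 1j * rng.normal(0, s, shape)
    return RangeAzimuthFrame(timestamp, np.abs(z).astype(np.float32), radar)


def piecewise_velocity_track(n_switches: int, duration: float = 60.0,
                             rate: float = 50.0, speeds=(0.05, 0.22),
                             arena: ArenaConfig | None = None,
                             axis: str = "Y", jitter: float = 0.2,
                             seed=None, phase: int = 2) -> tuple:
    """Track whose speed switches between two levels at known instants.

    The animal moves along one axis at a piecewise-constant velocity,
    alternating between the slow and fast speed at ``n_switches`` change
    points (evenly spaced with relative ``jitter``); each segment heads
    toward the arena centre, so the path never reaches a wall and every
    velocity kink in the signal is a planted one. Returns
    ``(Trajectory, switch_times)`` — ground truth for change detection.
    """
    if n_switches < 0:
        raise ValueError("n_switches must be non-negative")
    arena = arena or ArenaConfig()
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    edges = (np.arange(1, n_switches + 1)) * duration / (n_switches + 1)
    edges = edges + rng.uniform(-jitter, jitter, size=n_switches) \
        * duration / (n_switches + 1)
    seg = np.searchsorted(edges, t)
    speed = np.where(seg % 2 == 0, speeds[0], speeds[1])
    if axis.upper() == "Y":
        centre, lims = arena.length / 2, arena.y_limits
    else:
        centre, lims = 0.0, arena.x_limits
    pos = np.empty(n)
    pos[0] = centre
    seg_start = 0
    for i in range(1, n):
        if seg[i] != seg[i - 1]:
            seg_start = i
        if i == seg_start or i == 1:
            direction = 1.0 if pos[i - 1] <= centre else -1.0
        pos[i] = pos[i - 1] + direction * speed[i - 1] / rate
    if np.any(pos < lims[0]) or np.any(pos > lims[1]):
        raise ValueError("segment displacement exceeds the arena; reduce "
                         "speeds or shorten segments")
    if axis.upper() == "Y":
        traj = Trajectory(t, np.zeros(n), pos, np.full(n, phase))
    else:
        traj = Trajectory(t, pos, np.full(n, arena.length / 2),
                          np.full(n, phase))
    return traj, edges


#: window-feature cluster centres for the four canonical movement classes,
#: columns (mean_speed, sinuosity, path_length, lateral_speed,
#: longitudinal_speed); occupancies default to the canonical split
PLANTED_CLASS_CENTRES = np.array([
    [0.10, 1.10, 0.10, 0.05, 0.05],   # slow
    [0.80, 1.20, 0.80, 0.40, 0.40],   # fast
    [0.70, 3.00, 0.70, 0.35, 0.35],   # fast tortuous
    [0.12, 2.80, 0.12, 0.06, 0.06],   # slow tortuous
])
PLANTED_CLASS_SDS = np.array([
    [0.05, 0.10, 0.05, 0.03, 0.03],
    [0.10, 0.15, 0.10, 0.06, 0.06],
    [0.10, 0.40, 0.10, 0.06, 0.06],
    [0.05, 0.40, 0.05, 0.03, 0.03],
])


def planted_feature_windows(n: int = 400, weights=(0.513, 0.355, 0.102, 0.030),
                            centres: np.ndarray | None = None,
                            sds: np.ndarray | None = None,
                            seed=None) -> tuple[pd.DataFrame, np.ndarray]:
    """Window-feature table drawn from known Gaussian movement classes.

    Returns the feature table (with a ``phase`` column set to 2) and the
    ground-truth class label per window, for mixture-recovery tests. Pass
    two rows of ``centres``/``sds``/``weights`` for a two-mode structure.
    """
    from .movement import FEATURE_COLUMNS

    rng = np.random.default_rng(seed)
    weights = np.asarray(weights, float)
    weights = weights / weights.sum()
    if centres is None:
        centres = PLANTED_CLASS_CENTRES[: len(weights)]
    if sds is None:
        sds = PLANTED_CLASS_SDS[: len(weights)]
    counts = rng.multinomial(n, weights)
    X, labels = [], []
    for k, nk in enumerate(counts):
        X.append(rng.normal(centres[k], sds[k], size=(nk, len(FEATURE_COLUMNS))))
        labels += [k] * nk
    df = pd.DataFrame(np.vstack(X), columns=FEATURE_COLUMNS)
    df["phase"] = 2
    df["window_start"] = np.arange(n, dtype=float)
    return df, np.asarray(labels)


@dataclass
class CovariateSpec:
    """Distributions and effect sizes linking covariates to movement.

    Docility and sociability scores are drawn from standard normals (they
    are z-scored behavioural indices). Effects act log-linearly on the
    stationary propensity of the active movement modes and on the
    state-switching probability:

    * higher sociability -> more activity and more switching (positive
      coupling, the direction of the printed wavelet-Y and PC1 effects);
    * higher docility -> slightly less activity;
    * phase 3 multiplies the active-mode propensity by
      ``phase3_activity_multiplier`` < 1 (all sheep move less with the
      human present) and the switching rate by ``phase3_switch_multiplier``.
    """

    docility_mean: float = 0.0
    docility_sd: float = 1.0
    sociability_mean: float = 0.0
    sociability_sd: float = 1.0
    beta_sociability_activity: float = 0.35
    beta_docility_activity: float = -0.15
    beta_sociability_switch: float = 0.25
    phase3_activity_multiplier: float = 0.30
    phase3_switch_multiplier: float = 0.55

    @classmethod
    def null(cls) -> "CovariateSpec":
        """No covariate effects (phase-3 suppression kept)."""
        return cls(beta_sociability_activity=0.0,
                   beta_docility_activity=0.0,
                   beta_sociability_switch=0.0)


@dataclass
class SessionData:
    """One simulated arena-test session for one sheep."""

    sheep_id: str
    covariates: dict
    arena: ArenaConfig
    radar: RadarConfig
    ground_truth: Trajectory
    infrared: pd.DataFrame
    background_frames: np.ndarray | None = None  # (n, R, A)
    phase_frames: np.ndarray | None = None  # (n, R, A)
    frame_times: np.ndarray | None = None

    def to_hdf5(self, path: str | Path) -> None:
        import json
        from dataclasses import asdict

        with h5py.File(path, "w") as f:
            f.attrs["sheep_id"] = self.sheep_id
            f.attrs["arena_config"] = json.dumps(asdict(self.arena))
            f.attrs["radar_config"] = json.dumps(asdict(self.radar))
            for k, v in self.covariates.items():
                f.attrs[f"covariate_{k}"] = v
            g = f.create_group("trajectory")
            for col, arr in (("time_s", self.ground_truth.times),
                             ("x_m", self.ground_truth.x),
                             ("y_m", self.ground_truth.y),
                             ("phase", self.ground_truth.phase)):
                g.create_dataset(col, data=arr)
            ev = f.create_group("infrared")
            for col in self.infrared.columns:
                ev.create_dataset(col, data=self.infrared[col].to_numpy())
            if self.background_frames is not None:
                f.create_dataset("background_frames",
                                 data=self.background_frames)
            if self.phase_frames is not None:
                f.create_dataset("phase_frames", data=self.phase_frames)
                f.create_dataset("frame_times", data=self.frame_times)

    @classmethod
    def from_hdf5(cls, path: str | Path,
                  arena: ArenaConfig | None = None,
                  radar: RadarConfig | None = None) -> "SessionData":
        import json

        with h5py.File(path, "r") as f:
            if arena is None:
                raw = f.attrs.get("arena_config")
                arena = ArenaConfig(**json.loads(raw)) if raw \
                    else ArenaConfig()
            if radar is None:
                raw = f.attrs.get("radar_config")
                radar = RadarConfig(**json.loads(raw)) if raw \
                    else RadarConfig()
            cov = {k[len("covariate_"):]: float(v)
                   for k, v in f.attrs.items() if k.startswith("covariate_")}
            g = f["trajectory"]
            traj = Trajectory(g["time_s"][:], g["x_m"][:], g["y_m"][:],
                              g["phase"][:])
            ev = f["infrared"]
            infrared = pd.DataFrame({c: ev[c][:] for c in ev})
            bg = f["background_frames"][:] if "background_frames" in f else None
            pf = f["phase_frames"][:] if "phase_frames" in f else None
            ft = f["frame_times"][:] if "frame_times" in f else None
            return cls(str(f.attrs["sheep_id"]), cov, arena, radar, traj,
                       infrared, bg, pf, ft)


def _phase_model(covariates: dict, spec: CovariateSpec, phase: int,
                 base_stationary: np.ndarray, base_switch: float,
                 states: list[MovementState]) -> TrajectoryModel:
    """Movement model for one phase under the covariate coupling."""
    soc = covariates.get("sociability", 0.0)
    doc = covariates.get("docility", 0.0)
    w = np.array(base_stationary, float).copy()
    g = np.exp(spec.beta_sociability_activity * soc
               + spec.beta_docility_activity * doc)
    if phase == 3:
        g *= spec.phase3_activity_multiplier
    for i in _ACTIVE_STATES:
        w[i] *= g
    switch = base_switch * np.exp(spec.beta_sociability_switch * soc)
    if phase == 3:
        switch *= spec.phase3_switch_multiplier
    switch = float(np.clip(switch, 1e-4, 0.5))
    return TrajectoryModel(states, switching_matrix(w, switch))


def generate_session(arena: ArenaConfig | None = None,
                     radar: RadarConfig | None = None,
                     covariate_spec: CovariateSpec | None = None,
                     seed=0,
                     sheep_id: str = "sheep_0",
                     covariates: dict | None = None,
                     frames: str = "none",
                     n_background: int = 120,
                     target_amplitude: float = 5.0,
                     base_stationary=(0.513, 0.355, 0.102, 0.030),
                     base_switch: float = 0.02,
                     states: list[MovementState] | None = None,
                     scene: ClutterScene | None = None) -> SessionData:
    """Simulate one full arena-test session.

    ``frames`` selects the radar observation level: ``"none"`` keeps only
    the ground truth (cohort-scale behavioural work), ``"map"`` adds
    map-level frames for the full phases plus ``n_background`` animal-absent
    frames, ``"signal"`` runs the physical beat-signal model through
    :func:`ovitrack.dsp.frame_to_map` (slow; meant for short sessions).
    All randomness flows from ``seed``.
    """
    arena = arena or ArenaConfig()
    radar = radar or RadarConfig()
    spec = covariate_spec or CovariateSpec()
    states = states or default_movement_states()
    if frames not in ("none", "map", "signal"):
        raise ValueError("frames must be 'none', 'map' or 'signal'")
    if frames != "none" and n_background < 1:
        raise ValueError("need at least one background frame")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    traj_seeds, cov_seed, bg_seed, frame_seed, scene_seed = ss.spawn(5)
    rng_cov = np.random.default_rng(cov_seed)
    if covariates is None:
        covariates = {
            "docility": float(rng_cov.normal(spec.docility_mean,
                                             spec.docility_sd)),
            "sociability": float(rng_cov.normal(spec.sociability_mean,
                                                spec.sociability_sd)),
        }

    # one trajectory per phase, chained in position
    rate = radar.frame_rate
    pieces = []
    start = (0.0, 0.5)
    heading = None
    t0 = 0.0
    phase_seeds = traj_seeds.spawn(arena.n_phases)
    for p, dur in enumerate(arena.phase_durations, start=1):
        model = _phase_model(covariates, spec, p, np.asarray(base_stationary),
                             base_switch, states)
        piece = simulate_trajectory(model, arena, dur, rate,
                                    seed=phase_seeds[p - 1], start=start,
                                    heading0=heading, t0=t0)
        pieces.append(piece)
        start = (piece.x[-1], piece.y[-1])
        t0 = piece.times[-1] + 1.0 / rate
        heading = None
    traj = Trajectory(
        np.concatenate([p.times for p in pieces]),
        np.concatenate([p.x for p in pieces]),
        np.concatenate([p.y for p in pieces]),
        np.concatenate([p.phase for p in pieces]),
        latent_states=np.concatenate([p.latent_states for p in pieces]),
    )
    infrared = infrared_events(traj, arena=arena)

    bg = pf = ft = None
    if frames != "none":
        if scene is None:
            scene = wall_clutter_scene(arena, radar, seed=scene_seed)
        n = len(traj)
        bg_rngs = np.random.default_rng(bg_seed)
        fr_rngs = np.random.default_rng(frame_seed)
        if frames == "map":
            cmap = clutter_complex_map(scene, radar)
            bg = np.empty((n_background, radar.n_range_bins,
                           radar.n_angle_bins), np.float32)
            for i in range(n_background):
                bg[i] = synthesize_map(None, scene, radar, seed=bg_rngs,
                                       _clutter_map=cmap).values
            pf = np.empty((n, radar.n_range_bins, radar.n_angle_bins),
                          np.float32)
            for i in range(n):
                pf[i] = synthesize_map(
                    (traj.x[i], traj.y[i]), scene, radar, seed=fr_rngs,
                    arena=arena, target_amplitude=target_amplitude,
                    timestamp=traj.times[i], _clutter_map=cmap).values
        else:  # signal level
            bg = np.empty((n_background, radar.n_range_bins,
                           radar.n_angle_bins), np.float32)
            for i in range(n_background):
                raw = synthesize_beat_signal(None, scene, radar, seed=bg_rngs)
                bg[i] = frame_to_map(raw, radar).values
            pf = np.empty((n, radar.n_range_bins, radar.n_angle_bins),
                          np.float32)
            for i in range(n):
                raw = synthesize_beat_signal(
                    (traj.x[i], traj.y[i]), scene, radar, seed=fr_rngs,
                    arena=arena, target_amplitude=target_amplitude)
                pf[i] = frame_to_map(raw, radar,
                                     timestamp=traj.times[i]).values
        ft = traj.times.copy()
    return SessionData(sheep_id, covariates, arena, radar, traj, infrared,
                       bg, pf, ft)


def generate_cohort(n_sheep: int = 58,
                    arena: ArenaConfig | None = None,
                    radar: RadarConfig | None = None,
                    covariate_spec: CovariateSpec | None = None,
                    seed=0, frames: str = "none",
                    **session_kwargs) -> list[SessionData]:
    """Simulate a cohort of independent sheep sessions from one seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_sheep)):
        out.append(generate_session(
            arena=arena, radar=radar, covariate_spec=covariate_spec,
            seed=child, sheep_id=f"sheep_{i:02d}", frames=frames,
            **session_kwargs))
    return out
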