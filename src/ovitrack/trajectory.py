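"""Trajectory containers and ground-truth movement simulators.

The movement model is a discrete-time Markov chain over behavioural states
(e.g. slow / fast / fast-tortuous / slow-tortuous), each state carrying a
speed distribution and a turning-angle concentration. Positions are
propagated as a correlated random walk and kept inside the arena by
reflective ("billiard") boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ArenaConfig


@dataclass
class Trajectory:
    """Time-stamped 2D positions of one animal in arena coordinates.

    ``x`` runs across the arena width (centred on the radar boresight),
    ``y`` along the length (0 at the entrance wall). ``phase`` holds the
    1-based protocol phase of each sample; ``valid`` marks samples that came
    from an actual detection rather than gap interpolation.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phase: np.ndarray
    source: str = "ground_truth"
    valid: np.ndarray | None = None
    latent_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.phase = np.asarray(self.phase, dtype=int)
        n = len(self.times)
        if not (len(self.x) == len(self.y) == len(self.phase) == n):
            raise ValueError("trajectory arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def rate(self) -> float:
        """Sampling rate [Hz], assuming uniform spacing."""
        if len(self) < 2:
            raise ValueError("need at least two samples to infer a rate")
        return 1.0 / float(np.median(np.diff(self.times)))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0

    def select_phase(self, phase: int) -> "Trajectory":
        m = self.phase == phase
        if not m.any():
            raise ValueError(f"trajectory has no samples in phase {phase}")
        return Trajectory(
            self.times[m], self.x[m], self.y[m], self.phase[m],
            source=self.source,
            valid=None if self.valid is None else self.valid[m],
            latent_states=None if self.latent_states is None
            else self.latent_states[m],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"time_s": self.times, "x_m": self.x, "y_m": self.y,
             "phase": self.phase}
        )
        if self.valid is not None:
            df["valid"] = self.valid.astype(int)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "external") -> "Trajectory":
        df = pd.read_csv(path)
        required = {"time_s", "x_m", "y_m"}
        if not required.issubset(df.columns):
            raise ValueError(f"track CSV needs columns {sorted(required)}")
        phase = df["phase"].to_numpy() if "phase" in df else np.ones(len(df), int)
        valid = df["valid"].to_numpy(bool) if "valid" in df else None
        return cls(df["time_s"].to_numpy(), df["x_m"].to_numpy(),
                   df["y_m"].to_numpy(), phase, source=source, valid=valid)


@dataclass
class MovementState:
    """One behavioural mode of the movement chain.

    ``speed_mean`` / ``speed_sd`` parameterise a (non-negative, truncated)
    normal step-speed distribution in m/s. ``kappa`` is the per-second von
    Mises concentration of the turning angle: large values give directed,
    low-sinuosity paths; values near zero give tortuous paths; ``inf`` gives
    perfectly straight motion.
    """

    name: str
    speed_mean: float
    speed_sd: float
    kappa: float

    def __post_init__(self) -> None:
        if self.speed_mean < 0 or self.speed_sd < 0:
            raise ValueError("speeds must be non-negative")
        if self.kappa < 0:
            raise ValueError("turning concentration must be non-negative")


@dataclass
class TrajectoryModel:
    """Markov switching model over movement states with per-step transitions."""

    states: list[MovementState]
    transition_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        k = len(self.states)
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition matrix shape must match state count")
        if np.any(self.transition_matrix < 0) or not np.allclose(
            self.transition_matrix.sum(axis=1), 1.0, atol=1e-8
        ):
            raise ValueError("transition matrix rows must be stochastic")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the chain (left unit eigenvector)."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def default_movement_states() -> list[MovementState]:
    """Four canonical modes: slow/fast crossed with low/high sinuosity."""
    return [
        MovementState("slow", speed_mean=0.06, speed_sd=0.03, kappa=30.0),
        MovementState("fast", speed_mean=0.80, speed_sd=0.20, kappa=30.0),
        MovementState("fast_tortuous", speed_mean=0.60, speed_sd=0.20, kappa=0.5),
        MovementState("slow_tortuous", speed_mean=0.10, speed_sd=0.05, kappa=0.3),
    ]


def switching_matrix(stationary: np.ndarray, switch_prob: float) -> np.ndarray:
    """Row-stochastic matrix with the given stationary distribution.

    Each step the chain re-draws its state from ``stationary`` with
    probability ``switch_prob`` and stays put otherwise, so ``stationary`` is
    exactly the invariant distribution and mean dwell scales as
    ``1 / switch_prob`` steps.
    """
    pi = np.asarray(stationary, float)
    if np.any(pi < 0) or pi.sum() <= 0:
        raise ValueError("stationary weights must be non-negative, not all zero")
    pi = pi / pi.sum()
    if not 0 < switch_prob <= 1:
        raise ValueError("switch_prob must be in (0, 1]")
    k = len(pi)
    P = switch_prob * np.tile(pi, (k, 1))
    P[np.diag_indices(k)] += 1.0 - switch_prob
    return P


def default_trajectory_model(
    stationary=(0.513, 0.355, 0.102, 0.030), switch_prob: float = 0.02
) -> TrajectoryModel:
    """Default four-mode model with sticky transitions (mean dwell ~1 s at 50 Hz)."""
    return TrajectoryModel(
        default_movement_states(), switching_matrix(np.asarray(stationary), switch_prob)
    )


def _fold(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold an unconstrained coordinate into [lo, hi] by specular reflection."""
    L = hi - lo
    if L <= 0:
        raise ValueError("degenerate interval")
    w = np.mod(z - lo, 2.0 * L)
    folded = lo + np.minimum(w, 2.0 * L - w)
    # keep already-in-range coordinates bit-exact
    return np.where((z >= lo) & (z <= hi), z, folded)


def simulate_trajectory(
    model: TrajectoryModel,
    arena: ArenaConfig,
    duration: float,
    rate: float = 50.0,
    seed=None,
    start: tuple[float, float] | None = None,
    heading0: float | None = None,
    t0: float = 0.0,
    initial_state: int | None = None,
) -> Trajectory:
    """Simulate a state-switching correlated random walk inside the arena.

    Returns ``ceil(duration * rate)`` samples; the latent state sequence is
    attached as ``Trajectory.latent_states`` so recovery tests can compare
    against ground truth. Reflective boundaries keep the path in-arena.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(duration * rate))
    dt = 1.0 / rate

    k = model.n_states
    # latent state sequence
    states = np.empty(n, dtype=int)
    cum = np.cumsum(model.transition_matrix, axis=1)
    u = rng.random(n)
    if initial_state is None:
        s = int(np.searchsorted(np.cumsum(model.stationary_distribution()),
                                rng.random()))
        s = min(s, k - 1)
    else:
        s = int(initial_state)
    for i in range(n):
        states[i] = s
        s = int(np.searchsorted(cum[s], u[i]))
        s = min(s, k - 1)

    means = np.array([st.speed_mean for st in model.states])
    sds = np.array([st.speed_sd for st in model.states])
    kappas = np.array([st.kappa for st in model.states])

    speeds = np.maximum(0.0, rng.normal(means[states], sds[states]))
    # per-step von Mises concentration so per-second angular variance ~ 1/kappa
    kappa_step = kappas[states] * rate
    turns = np.where(
        np.isinf(kappa_step), 0.0,
        rng.vonmises(0.0, np.where(np.isfinite(kappa_step), kappa_step, 1.0)),
    )
    if heading0 is None:
        heading0 = rng.uniform(-np.pi, np.pi)
    headings = heading0 + np.cumsum(turns)

    steps = speeds * dt
    dx = steps * np.sin(headings)
    dy = steps * np.cos(headings)
    if start is None:
        start = (0.0, 0.5)
    x = start[0] + np.concatenate([[0.0], np.cumsum(dx)[:-1]])
    y = start[1] + np.concatenate([[0.0], np.cumsum(dy)[:-1]])
    x = _fold(x, *arena.x_limits)
    y = _fold(y, *arena.y_limits)

    times = t0 + np.arange(n) / rate
    phase = np.minimum(arena.phase_of(times), arena.n_phases)
    return Trajectory(times, x, y, phase, source="ground_truth",
                      latent_states=states)


def scripted_trajectory(
    waypoints: list[tuple[float, float, float]],
    rate: float = 50.0,
    arena: ArenaConfig | None = None,
    t0: float = 0.0,
    phase: int = 2,
) -> Trajectory:
    """Deterministic piecewise trajectory holding each waypoint for its dwell.

    ``waypoints`` is a list of ``(x, y, dwell_seconds)``; the animal sits at
    each point for ``round(dwell * rate)`` samples and teleports to the next.
    Intended for hand-enumerable fixtures of the occupancy estimators.
    """
    if not waypoints:
        raise ValueError("waypoint list is empty")
    if rate <= 0:
        raise ValueError("rate must be positive")
    arena = arena or ArenaConfig()
    xs, ys = [], []
    for (wx, wy, dwell) in waypoints:
        if not (arena.x_limits[0] <= wx <= arena.x_limits[1]
                and arena.y_limits[0] <= wy <= arena.y_limits[1]):
            raise ValueError(f"waypoint ({wx}, {wy}) outside arena")
        m = max(1, int(round(dwell * rate)))
        xs.extend([wx] * m)
        ys.extend([wy] * m)
    n = len(xs)
    times = t0 + np.arange(n) / rate
    return Trajectory(times, np.array(xs), np.array(ys),
                      np.full(n, phase), source="ground_truth")
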