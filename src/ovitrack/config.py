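"""Configuration objects for the arena, the radar, and the movement model.

Coordinate convention (used everywhere in the package): the radar sits behind
the entrance-side short wall, boresight pointing down the arena. ``y`` runs
along the arena length (0 at the entrance wall, increasing toward the grid
barrier holding the conspecifics), ``x`` runs across the width and is centred
on the radar boresight, so ``x in [-width/2, +width/2]``. Azimuth angles are
measured from boresight in degrees, positive toward +x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

#: speed of light [m/s]
C = 299_792_458.0


@dataclass
class ArenaConfig:
    """Geometry and protocol of the arena (pen) test.

    The default arena is the 2 m x 7 m pen with three protocol phases
    (15 s exploration, 60 s isolation, 60 s human presence), seven 1-m
    virtual areas along the length, and an occupancy grid of 16 x 5 = 80
    zones.
    """

    length: float = 7.0
    width: float = 2.0
    #: (x, y) of the radar phase centre in arena coordinates; the radar is
    #: placed 1 m behind the entrance wall so the whole pen is in front of it.
    radar_position: tuple[float, float] = (0.0, -1.0)
    #: radar boresight heading, degrees from +y (0 = looking down the arena)
    radar_heading: float = 0.0
    phase_durations: tuple[float, ...] = (15.0, 60.0, 60.0)
    n_virtual_areas: int = 7
    grid_partitions: tuple[int, int] = (16, 5)  # (along length, along width)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.n_virtual_areas * 1.0 > self.length + 1e-9:
            raise ValueError(
                f"{self.n_virtual_areas} one-metre areas do not fit in a "
                f"{self.length} m arena"
            )
        if any(d <= 0 for d in self.phase_durations):
            raise ValueError("phase durations must be positive")
        if any(n <= 0 for n in self.grid_partitions):
            raise ValueError("grid partitions must be positive")

    @property
    def n_phases(self) -> int:
        return len(self.phase_durations)

    @property
    def total_duration(self) -> float:
        return float(sum(self.phase_durations))

    def phase_of(self, t):
        """Phase label (1-based) for time(s) ``t`` since session start."""
        import numpy as np

        edges = np.cumsum(self.phase_durations)
        return np.searchsorted(edges, np.asarray(t), side="right") + 1

    @property
    def x_limits(self) -> tuple[float, float]:
        return (-self.width / 2.0, self.width / 2.0)

    @property
    def y_limits(self) -> tuple[float, float]:
        return (0.0, self.length)


@dataclass
class RadarConfig:
    """FMCW radar parameters.

    Defaults are the indoor 77 GHz configuration: 3 GHz modulation bandwidth
    (5 cm theoretical range resolution), 256 us ramps, a 4 Tx x 8 Rx MIMO
    array giving 32 virtual channels at half-wavelength spacing, and 50
    frames per second. :meth:`outdoor` returns the 24 GHz long-range variant.
    """

    carrier_frequency: float = 77e9
    bandwidth: float = 3e9
    ramp_time: float = 256e-6
    frame_rate: float = 50.0
    n_tx: int = 4
    n_rx: int = 8
    element_spacing: float = 0.5  # fraction of wavelength
    transmitted_power: float = 0.1  # W
    field_of_view: float = 50.0  # degrees, full width
    noise_sigma: float = 0.5  # linear amplitude units
    n_range_bins: int = 176
    n_angle_bins: int = 64

    def __post_init__(self) -> None:
        if self.bandwidth >= self.carrier_frequency:
            raise ValueError("bandwidth must be below the carrier frequency")
        if self.n_tx * self.n_rx < 1:
            raise ValueError("need at least one virtual channel")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        if self.ramp_time <= 0:
            raise ValueError("ramp time must be positive")

    @classmethod
    def outdoor(cls) -> "RadarConfig":
        """The 24 GHz outdoor configuration (800 MHz bandwidth, 1 ms ramps)."""
        return cls(
            carrier_frequency=24e9,
            bandwidth=800e6,
            ramp_time=1e-3,
            n_tx=1,
            n_rx=2,
            field_of_view=58.0,
            n_range_bins=512,
        )

    @property
    def n_channels(self) -> int:
        return self.n_tx * self.n_rx

    @property
    def wavelength(self) -> float:
        return C / self.carrier_frequency

    @property
    def range_bin_width(self) -> float:
        """Range extent of one FFT bin, c / (2 B) [m]."""
        return C / (2.0 * self.bandwidth)

    @property
    def max_range(self) -> float:
        return self.n_range_bins * self.range_bin_width

    @property
    def n_fast_samples(self) -> int:
        """Samples per ramp; one-sided FFT then yields ``n_range_bins``."""
        return 2 * self.n_range_bins

    def range_axis(self):
        """Bin-centre ranges [m] for the one-sided range FFT."""
        import numpy as np

        return (np.arange(self.n_range_bins) + 0.5) * self.range_bin_width

    def sin_theta_axis(self):
        """sin(azimuth) per angle bin (fftshifted spatial-frequency axis)."""
        import numpy as np

        k = np.arange(self.n_angle_bins) - self.n_angle_bins // 2
        return k / (self.n_angle_bins * self.element_spacing)

    def angle_axis(self):
        """Bin-centre azimuths [deg]; bins outside +/-90 deg are clipped."""
        import numpy as np

        s = np.clip(self.sin_theta_axis(), -1.0, 1.0)
        return np.degrees(np.arcsin(s))


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML config file into ArenaConfig / RadarConfig objects.

    Recognised top-level keys: ``arena``, ``radar``, ``model`` (movement-model
    parameters passed through as a dict). Unknown keys are preserved.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yml", ".yaml"}:
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    out = dict(raw)
    if "arena" in raw:
        out["arena"] = ArenaConfig(**raw["arena"])
    if "radar" in raw:
        out["radar"] = RadarConfig(**raw["radar"])
    return out


def dump_config(config: dict, path: str | Path) -> None:
    """Write configs back to JSON/YAML (inverse of :func:`load_config`)."""
    path = Path(path)
    raw = {}
    for key, value in config.items():
        if isinstance(value, (ArenaConfig, RadarConfig)):
            raw[key] = asdict(value)
        else:
            raw[key] = value
    if path.suffix in {".yml", ".yaml"}:
        path.write_text(yaml.safe_dump(raw))
    else:
        path.write_text(json.dumps(raw, indent=2))
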