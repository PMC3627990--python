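"""Geometry and sensing model of the 1-D conditioning chamber.

The chamber is a narrow walking arena (14.8 cm long by default) whose floor
and ceiling carry an electric grid and whose position readout is a row of
infrared photo sensors sampled at 5 Hz.  Positions use chamber coordinates
in cm: x = 0 is the midline, the left end is negative, the right end
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChamberConfig", "DEFAULT_CHAMBER"]


@dataclass(frozen=True)
class ChamberConfig:
    """Physical geometry and sensor layout of the conditioning chamber.

    Defaults describe the reference build: 148 x 20 x 6 mm interior, 26
    IR photo sensors, 5 Hz sampling.
    """

    length: float = 14.8  # cm
    width: float = 2.0  # cm
    depth: float = 0.6  # cm
    n_sensors: int = 26
    sampling_rate: float = 5.0  # Hz

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chamber length must be positive, got {self.length}")
        if self.n_sensors < 2:
            raise ValueError(f"need at least 2 sensors, got {self.n_sensors}")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.sampling_rate}")

    @property
    def position_min(self) -> float:
        return -self.length / 2.0

    @property
    def position_max(self) -> float:
        return self.length / 2.0

    @property
    def sensor_pitch(self) -> float:
        return self.length / self.n_sensors

    @property
    def sample_dt(self) -> float:
        return 1.0 / self.sampling_rate

    def sensor_centers(self) -> np.ndarray:
        """Centers of the sensor fields, left to right.

        Sensor i covers [min + i*pitch, min + (i+1)*pitch]; its reported
        position is the field center.
        """
        i = np.arange(self.n_sensors)
        return self.position_min + (i + 0.5) * self.sensor_pitch

    def quantize(self, x: np.ndarray | float) -> np.ndarray:
        """Map true positions onto the nearest sensor center.

        The quantization error is bounded by half the sensor pitch; wall
        positions map to the outermost sensor centers.
        """
        x = np.asarray(x, dtype=float)
        idx = np.floor((x - self.position_min) / self.sensor_pitch).astype(int)
        idx = np.clip(idx, 0, self.n_sensors - 1)
        return self.position_min + (idx + 0.5) * self.sensor_pitch

    def contains(self, x: np.ndarray | float) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all((x >= self.position_min - 1e-9) & (x <= self.position_max + 1e-9)))


DEFAULT_CHAMBER = ChamberConfig()
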