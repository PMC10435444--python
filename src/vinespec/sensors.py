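"""Virtual NIR sensor definitions.

Two instrument geometries are modelled after the field setup this package
emulates: a bench-grade diode-array spectrometer (``SENSOR_1``, 1100-2100 nm
at 2 nm, 501 channels, 14 Hz) and a miniaturized micro-spectrometer
(``SENSOR_2``, 900-1860 nm at 8.2 nm resolution, 12.5 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SensorSpec:
    """Spectral sampling grid and acquisition rate of one instrument.

    The channel count is tied to the grid: ``n_channels`` must equal
    ``floor((wl_max - wl_min) / step) + 1``.
    """

    name: str
    wl_min: float
    wl_max: float
    step: float
    n_channels: int
    rate_hz: float

    def __post_init__(self) -> None:
        if not self.wl_min < self.wl_max:
            raise ValueError("wl_min must be < wl_max")
        if self.step <= 0:
            raise ValueError("step must be positive")
        expected = math.floor((self.wl_max - self.wl_min) / self.step) + 1
        if self.n_channels != expected:
            raise ValueError(
                f"n_channels={self.n_channels} inconsistent with grid "
                f"({self.wl_min}-{self.wl_max} nm at {self.step} nm -> {expected})"
            )
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def wavelengths(self) -> np.ndarray:
        """Channel centres in nm, strictly increasing."""
        return self.wl_min + self.step * np.arange(self.n_channels)

    @classmethod
    def from_range(
        cls, name: str, wl_min: float, wl_max: float, step: float, rate_hz: float
    ) -> "SensorSpec":
        n = math.floor((wl_max - wl_min) / step) + 1
        return cls(name, wl_min, wl_max, step, n, rate_hz)


#: Bench NIR spectrometer: 1100-2100 nm, 2 nm step, 501 channels, 14 Hz.
SENSOR_1 = SensorSpec.from_range("sensor1", 1100.0, 2100.0, 2.0, 14.0)

#: Miniaturized micro-spectrometer: 900-1860 nm, 8.2 nm resolution (118
#: channels), 12.5 Hz.
SENSOR_2 = SensorSpec.from_range("sensor2", 900.0, 1860.0, 8.2, 12.5)

SENSORS = {SENSOR_1.name: SENSOR_1, SENSOR_2.name: SENSOR_2}
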