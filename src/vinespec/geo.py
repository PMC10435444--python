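"""Local tangent-plane projection between lon/lat and plot metres.

At vineyard scale (a few hundred metres) an equirectangular projection about
a reference origin is accurate to well under a centimetre, which is all the
mapping and simulation layers need for metric distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6_371_008.8


@dataclass(frozen=True)
class LocalProjection:
    """Equirectangular lon/lat <-> (x, y) metres about an origin."""

    lon0: float
    lat0: float

    @property
    def _m_per_deg_lat(self) -> float:
        return EARTH_RADIUS_M * math.pi / 180.0

    @property
    def _m_per_deg_lon(self) -> float:
        return self._m_per_deg_lat * math.cos(math.radians(self.lat0))

    def to_xy(self, lon, lat):
        x = (np.asarray(lon, dtype=float) - self.lon0) * self._m_per_deg_lon
        y = (np.asarray(lat, dtype=float) - self.lat0) * self._m_per_deg_lat
        return x, y

    def to_lonlat(self, x, y):
        lon = self.lon0 + np.asarray(x, dtype=float) / self._m_per_deg_lon
        lat = self.lat0 + np.asarray(y, dtype=float) / self._m_per_deg_lat
        return lon, lat
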