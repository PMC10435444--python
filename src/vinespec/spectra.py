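"""Spectrum and geolocation containers plus plain-text stream I/O.

A stream file is one text table per vehicle pass: ``#``-prefixed
``key=value`` header lines followed by a whitespace-separated table with
columns ``timestamp lon lat`` and then one column per wavelength (nm printed
to 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

SpectrumKind = str  # one of {"raw", "dark", "white", "reflectance"}

_KINDS = ("raw", "dark", "white", "reflectance")


@dataclass
class GeoPoint:
    """WGS84 position with a GPS fix-quality label."""

    lon: float
    lat: float
    fix_quality: str = "rtk"

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"lat out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"lon out of range: {self.lon}")


@dataclass
class Spectrum:
    """One wavelength-indexed intensity or reflectance vector.

    ``wavelengths`` must be strictly increasing and the same length as
    ``values``.  ``kind`` distinguishes raw counts from references and
    calibrated reflectance; reflectance values must be finite.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: SpectrumKind = "raw"
    sensor: str = ""
    timestamp: float | None = None
    geo: GeoPoint | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values length mismatch")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown spectrum kind: {self.kind!r}")
        if self.kind == "reflectance" and not np.all(np.isfinite(self.values)):
            raise ValueError("reflectance spectrum contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    def same_grid(self, other: "Spectrum", atol: float = 1e-9) -> bool:
        return self.wavelengths.shape == other.wavelengths.shape and np.allclose(
            self.wavelengths, other.wavelengths, atol=atol
        )

    def with_values(self, values: np.ndarray, kind: SpectrumKind | None = None) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float), kind=kind or self.kind)

    def channel_nearest(self, wavelength_nm: float) -> int:
        """Index of the channel closest to the given wavelength."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))


def require_same_grid(*spectra: Spectrum) -> None:
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_grid(s):
            raise ValueError("spectra are not on a shared wavelength grid")


def write_stream(path, spectra: Sequence[Spectrum], header: dict | None = None) -> None:
    """Write spectra (with optional geo/timestamp) as one plain-text table."""
    if not spectra:
        raise ValueError("cannot write an empty stream")
    require_same_grid(*spectra)
    wl = spectra[0].wavelengths
    with open(path, "w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}={val}\n")
        cols = ["timestamp", "lon", "lat"] + [f"{w:.2f}" for w in wl]
        fh.write("\t".join(cols) + "\n")
        for s in spectra:
            ts = f"{s.timestamp:.4f}" if s.timestamp is not None else "nan"
            lon = f"{s.geo.lon:.8f}" if s.geo is not None else "nan"
            lat = f"{s.geo.lat:.8f}" if s.geo is not None else "nan"
            row = [ts, lon, lat] + [f"{v:.6g}" for v in s.values]
            fh.write("\t".join(row) + "\n")


def read_stream(path, kind: SpectrumKind = "raw") -> tuple[list[Spectrum], dict]:
    """Read a stream file back into spectra; returns (spectra, header dict)."""
    header: dict[str, str] = {}
    spectra: list[Spectrum] = []
    with open(path) as fh:
        lines = fh.readlines()
    body: list[str] = []
    for line in lines:
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                key, _, val = stripped.partition("=")
                header[key.strip()] = val.strip()
        elif line.strip():
            body.append(line)
    if not body:
        raise ValueError(f"stream file {path} has no data rows")
    columns = body[0].split()
    wl = np.array([float(c) for c in columns[3:]])
    sensor = header.get("sensor", "")
    for line in body[1:]:
        parts = line.split()
        ts = float(parts[0])
        lon, lat = float(parts[1]), float(parts[2])
        values = np.array([float(v) for v in parts[3:]])
        geo = None if np.isnan(lon) or np.isnan(lat) else GeoPoint(lon, lat)
        spectra.append(
            Spectrum(
                wavelengths=wl,
                values=values,
                kind=kind,
                sensor=sensor,
                timestamp=None if np.isnan(ts) else ts,
                geo=geo,
            )
        )
    return spectra, header


def write_single(path, spectrum: Spectrum, header: dict | None = None) -> None:
    """Write one spectrum as a two-column (wavelength, value) text file."""
    with open(path, "w") as fh:
        meta = {"kind": spectrum.kind, "sensor": spectrum.sensor}
        meta.update(header or {})
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        fh.write("wavelength_nm\tvalue\n")
        for w, v in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{w:.2f}\t{v:.6g}\n")


def read_single(path) -> Spectrum:
    header: dict[str, str] = {}
    wl: list[float] = []
    vals: list[float] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if "=" in stripped:
                    key, _, val = stripped.partition("=")
                    header[key.strip()] = val.strip()
            elif line.strip() and not line.startswith("wavelength"):
                w, v = line.split()
                wl.append(float(w))
                vals.append(float(v))
    return Spectrum(
        wavelengths=np.array(wl),
        values=np.array(vals),
        kind=header.get("kind", "raw"),
        sensor=header.get("sensor", ""),
    )
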