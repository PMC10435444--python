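"""Scatter correction and derivative spectroscopy operators.

The default pipeline — standard normal variate (SNV) followed by a
Savitzky-Golay first derivative — removes the multiplicative/additive
scatter and baseline structure that field reflectance picks up, leaving the
band-shape information the regression model needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum


@dataclass(frozen=True)
class SavgolParams:
    window: int = 7
    polyorder: int = 2
    deriv: int = 1

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("savgol window must be odd and greater than polyorder")
        if self.deriv > self.polyorder:
            raise ValueError("savgol deriv must not exceed polyorder")


@dataclass(frozen=True)
class PreprocConfig:
    """Ordered preprocessing steps; defaults suit the 118-channel micro sensor.

    For the 501-channel bench sensor a wider window (e.g. 15) smooths a
    comparable ~30 nm neighbourhood.
    """

    steps: tuple[str, ...] = ("snv", "savgol")
    savgol: SavgolParams = field(default_factory=SavgolParams)

    def __post_init__(self) -> None:
        unknown = set(self.steps) - {"snv", "savgol"}
        if unknown:
            raise ValueError(f"unknown preprocessing steps: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {"steps": list(self.steps), "savgol": asdict(self.savgol)}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocConfig":
        return cls(steps=tuple(d["steps"]), savgol=SavgolParams(**d["savgol"]))


def snv_array(X: np.ndarray) -> np.ndarray:
    """Row-wise standard normal variate with the sample (n-1) deviation."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least 2 channels")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for a zero-variance spectrum")
    return (X - mu) / sd


def snv(s: Spectrum) -> Spectrum:
    """Centre and scale one spectrum to mean 0, sample SD 1."""
    return s.with_values(snv_array(s.values[None, :])[0])


def savgol_array(X: np.ndarray, params: SavgolParams, delta_nm: float) -> np.ndarray:
    """Savitzky-Golay smoothing/derivative, scaled to per-nm units.

    Edge channels are handled by fitting the polynomial on the truncated
    terminal window, so output length equals input length and the channel
    grid stays stable for downstream wavelength indexing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < params.window:
        raise ValueError("spectrum shorter than the Savitzky-Golay window")
    return savgol_filter(
        X,
        window_length=params.window,
        polyorder=params.polyorder,
        deriv=params.deriv,
        delta=delta_nm,
        axis=1,
        mode="interp",
    )


def savgol_derivative(s: Spectrum, params: SavgolParams = SavgolParams()) -> Spectrum:
    delta = float(np.mean(np.diff(s.wavelengths)))
    return s.with_values(savgol_array(s.values[None, :], params, delta)[0])


def apply_pipeline(X: np.ndarray, wavelengths: np.ndarray, cfg: PreprocConfig) -> np.ndarray:
    """Apply the configured steps, in order, to a (n_samples, n_channels) matrix.

    The same function runs at train and predict time; the config is
    serialized into the fitted model so both paths share it bit-for-bit.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != np.asarray(wavelengths).size:
        raise ValueError("matrix width does not match the wavelength grid")
    delta = float(np.mean(np.diff(wavelengths)))
    for step in cfg.steps:
        if step == "snv":
            X = snv_array(X)
        elif step == "savgol":
            X = savgol_array(X, cfg.savgol, delta)
    return X
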