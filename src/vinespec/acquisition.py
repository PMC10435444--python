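"""Automated acquisition workflow: referencing, calibration, live filtering.

Mirrors the field software's button order as an enforced state machine —
dark reference, white reference (Spectralon panel), single-leaf spectral
signature, then streaming measurement with cosine screening — and pairs each
frame with the nearest-in-time GPS fix.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .filtering import cosine_similarity
from .spectra import GeoPoint, Spectrum, require_same_grid, write_single, write_stream

DEFAULT_THRESHOLD = 0.985  # field-calibrated cosine similarity cut
GPS_PAIR_TOLERANCE_S = 0.5


class WorkflowStateError(RuntimeError):
    """A session step ran before its prerequisite reference was captured."""


class CalibrationError(ValueError):
    """White and dark references coincide on one or more channels."""


@dataclass
class AcquisitionSession:
    """One pass worth of references plus the filtered measurement stream.

    ``accepted`` holds reflectance-calibrated frames whose cosine similarity
    to the leaf signature reached the threshold; every other frame only
    increments ``rejected_count``.
    """

    dark: Spectrum
    white: Spectrum
    signature: Spectrum
    accepted: list[Spectrum]
    rejected_count: int
    threshold: float
    unlocated_count: int = 0
    log: list[str] = field(default_factory=list)

    @property
    def total_frames(self) -> int:
        return len(self.accepted) + self.rejected_count


def compute_reflectance(sample: Spectrum, dark: Spectrum, white: Spectrum) -> Spectrum:
    """Two-point reflectance calibration R = (S - D) / (W - D), channel-wise."""
    require_same_grid(sample, dark, white)
    denom = white.values - dark.values
    bad = np.flatnonzero(denom == 0)
    if bad.size:
        wls = ", ".join(f"{white.wavelengths[i]:.1f}" for i in bad[:10])
        raise CalibrationError(
            f"white and dark references coincide on {bad.size} channel(s) at {wls} nm"
        )
    values = (sample.values - dark.values) / denom
    out = sample.with_values(values, kind="reflectance")
    out.meta = dict(sample.meta)
    return out


def top5_mean(s: Spectrum) -> float:
    """Mean of the five largest channel values — the live sanity statistic."""
    if len(s) < 5:
        raise ValueError("top5_mean needs at least 5 channels")
    largest = np.partition(s.values, -5)[-5:]
    return float(np.mean(largest))


def _pair_gps(
    timestamp: float | None,
    gps_feed: Sequence[tuple[float, GeoPoint]],
    gps_times: np.ndarray,
    tolerance_s: float,
) -> GeoPoint | None:
    if timestamp is None or gps_times.size == 0:
        return None
    i = int(np.searchsorted(gps_times, timestamp))
    best, best_dt = None, tolerance_s
    for j in (i - 1, i):
        if 0 <= j < gps_times.size:
            dt = abs(gps_times[j] - timestamp)
            if dt <= best_dt:
                best, best_dt = gps_feed[j][1], dt
    return best


def run_session(
    stream: Iterable[Spectrum],
    dark: Spectrum | None,
    white: Spectrum | None,
    signature: Spectrum | None,
    threshold: float = DEFAULT_THRESHOLD,
    gps_feed: Sequence[tuple[float, GeoPoint]] = (),
    gps_tolerance_s: float = GPS_PAIR_TOLERANCE_S,
) -> AcquisitionSession:
    """Replay a measurement session: calibrate, georeference, filter.

    The workflow order is enforced: a missing dark, white or signature
    reference aborts with a state error naming the step.  The signature may
    be given as raw counts (it is then calibrated with the session
    references) or as reflectance.  Frames beyond the GPS pairing tolerance
    are kept but flagged unlocated; acceptance is decided purely by the
    cosine screen against the signature.
    """
    for name, ref in (("dark", dark), ("white", white), ("signature", signature)):
        if ref is None:
            raise WorkflowStateError(
                f"acquisition step {name!r} was not captured before measuring"
            )
    if signature.kind == "raw":
        signature = compute_reflectance(signature, dark, white)
    gps_feed = sorted(gps_feed, key=lambda p: p[0])
    gps_times = np.array([t for t, _ in gps_feed])
    accepted: list[Spectrum] = []
    rejected = 0
    unlocated = 0
    for frame in stream:
        refl = compute_reflectance(frame, dark, white)
        geo = _pair_gps(frame.timestamp, gps_feed, gps_times, gps_tolerance_s)
        if geo is None:
            unlocated += 1
        refl.geo = geo
        if cosine_similarity(refl, signature) >= threshold:
            accepted.append(refl)
        else:
            rejected += 1
    session = AcquisitionSession(
        dark=dark,
        white=white,
        signature=signature,
        accepted=accepted,
        rejected_count=rejected,
        threshold=threshold,
        unlocated_count=unlocated,
    )
    session.log = [
        f"threshold={threshold}",
        f"accepted={len(accepted)} rejected={rejected} unlocated={unlocated}",
        f"top5_mean dark={top5_mean(dark):.6g} white={top5_mean(white):.6g} "
        f"signature={top5_mean(signature):.6g}",
    ]
    return session


def write_session(session: AcquisitionSession, out_dir, header: dict | None = None) -> None:
    """Write the per-step files and the final filtered-stream table."""
    os.makedirs(out_dir, exist_ok=True)
    write_single(os.path.join(out_dir, "dark.txt"), session.dark)
    write_single(os.path.join(out_dir, "white.txt"), session.white)
    write_single(os.path.join(out_dir, "signature.txt"), session.signature)
    hdr = dict(header or {})
    hdr.setdefault("threshold", session.threshold)
    if session.accepted:
        write_stream(os.path.join(out_dir, "accepted.txt"), session.accepted, header=hdr)
    with open(os.path.join(out_dir, "session.log"), "w") as fh:
        fh.write("\n".join(session.log) + "\n")
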