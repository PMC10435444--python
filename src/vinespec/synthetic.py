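"""Synthetic on-the-go vineyard NIR campaigns with matching stem-water-potential references.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without field data:

* two virtual sensors (see :mod:`vinespec.sensors`);
* leaf reflectance whose water-absorption bands near 978, 1454 and 1935 nm
  deepen monotonically with leaf water content, itself linked linearly to
  stem water potential (psi, MPa, negative);
* non-leaf interference frames (canopy gaps, wires, wood, irrigation pipes,
  grape berries) that fail the cosine screen against a leaf signature;
* a randomized-block field layout with three irrigation treatments
  (T0 full, T1 moderate, T2 none) and a seasonal drying trend;
* GPS tracks for a vehicle moving along the monitored row at constant speed.

Leaf optics follow a Beer-Lambert-style model: a smooth reflectance baseline
attenuated by Gaussian absorption bands, R(l) = B(l) * exp(-sum_k A_k * G(l;
mu_k, sigma_k)), with the water-band amplitudes proportional to leaf water
content W = w0 + w1 * psi.  Multiplicative/additive scatter (a*R + b) and
i.i.d. Gaussian noise are applied afterwards, which is exactly what SNV and
derivative preprocessing are meant to remove.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .geo import LocalProjection
from .sensors import SENSOR_2, SensorSpec
from .spectra import GeoPoint, Spectrum

log = logging.getLogger(__name__)

TREATMENTS = ("T0", "T1", "T2")

#: Six measurement dates across a ripening season with the per-date
#: population mean psi (MPa) used as the campaign's drying trend.
DEFAULT_DATES = (
    "2021-07-07",
    "2021-07-20",
    "2021-07-27",
    "2021-08-11",
    "2021-08-25",
    "2021-09-15",
)
DEFAULT_DATE_MEANS = (-1.13, -1.23, -1.26, -1.51, -1.68, -1.82)

#: Irrigation effect: full irrigation (T0) keeps vines wetter, rain-fed (T2)
#: drier, relative to the per-date mean.
DEFAULT_TREATMENT_OFFSETS = {"T0": 0.12, "T1": 0.0, "T2": -0.12}

#: Water absorption bands (centre nm, width nm, amplitude at W=1, exponent).
#: The amplitude responds as amp * W**exponent: the weak second overtone is
#: near-linear in water content while the strong combination band saturates,
#: so the bands are informative independently rather than perfectly collinear.
WATER_BANDS = (
    (978.0, 35.0, 0.80, 0.9),
    (1454.0, 45.0, 0.85, 1.3),
    (1935.0, 55.0, 1.60, 2.0),
)
#: Dry-matter (cellulose/lignin) bands with psi-independent amplitude.
DRY_BANDS = ((1720.0, 45.0, 0.12), (2100.0, 60.0, 0.10))

INTERFERENCE_CLASSES = ("sky_gap", "wood", "wire", "pipe", "berry")


class GenerationError(RuntimeError):
    """Raised when a synthetic object cannot satisfy its contract."""


# ---------------------------------------------------------------------------
# water-status model
# ---------------------------------------------------------------------------


@dataclass
class WaterStatusModel:
    """Per-(date, treatment) psi distributions and the psi -> leaf-water link.

    ``water_link = (w0, w1)`` maps psi (MPa, <= 0) to leaf water content
    W = w0 + w1 * psi in (0, 1); w1 > 0 so wetter (less negative) vines have
    higher W.
    """

    psi_by_date_treatment: Mapping[tuple[str, str], tuple[float, float]]
    psi_floor: float = -2.5
    psi_ceil: float = -0.05
    water_link: tuple[float, float] = (0.9, 0.25)

    def __post_init__(self) -> None:
        if self.water_link[1] <= 0:
            raise ValueError("water_link slope w1 must be positive")
        if not self.psi_floor < self.psi_ceil <= 0:
            raise ValueError("require psi_floor < psi_ceil <= 0")

    @property
    def dates(self) -> list[str]:
        return sorted({d for d, _ in self.psi_by_date_treatment})

    def water_content(self, psi) -> np.ndarray:
        w0, w1 = self.water_link
        return w0 + w1 * np.asarray(psi, dtype=float)

    def draw_psi(self, date: str, treatment: str, n: int, rng: np.random.Generator) -> np.ndarray:
        try:
            mean, sd = self.psi_by_date_treatment[(date, treatment)]
        except KeyError:
            raise KeyError(f"no psi distribution configured for date={date}, treatment={treatment}")
        return np.clip(rng.normal(mean, sd, size=n), self.psi_floor, self.psi_ceil)


def default_water_model(
    dates: Sequence[str] = DEFAULT_DATES,
    date_means: Sequence[float] = DEFAULT_DATE_MEANS,
    treatment_offsets: Mapping[str, float] = DEFAULT_TREATMENT_OFFSETS,
    sd: float = 0.10,
) -> WaterStatusModel:
    """Seasonal drying trend with irrigation offsets; group-level SD in MPa."""
    if len(dates) != len(date_means):
        raise ValueError("dates and date_means length mismatch")
    table = {
        (d, t): (m + treatment_offsets[t], sd)
        for d, m in zip(dates, date_means)
        for t in TREATMENTS
    }
    return WaterStatusModel(psi_by_date_treatment=table)


# ---------------------------------------------------------------------------
# field layout
# ---------------------------------------------------------------------------


@dataclass
class BlockSpec:
    block_id: str
    treatment: str
    polygon: Polygon  # in local plot metres
    row_y: float  # y of the monitored (middle) row
    x_start: float
    x_end: float


@dataclass
class FieldLayout:
    """Randomized-block layout: disjoint block polygons in local metres.

    Each block holds three rows of vines; only the middle row is monitored
    (edge-effect avoidance), and its 15 vines are split into three
    consecutive 5-vine groups, each carrying one psi reference.
    """

    blocks: list[BlockSpec]
    vine_spacing: float = 1.2
    row_spacing: float = 2.6
    vines_per_row: int = 15
    groups_per_block: int = 3
    projection: LocalProjection = field(
        default_factory=lambda: LocalProjection(lon0=-0.6500, lat0=41.3500)
    )

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("layout has no blocks")
        present = {b.treatment for b in self.blocks}
        missing = set(TREATMENTS) - present
        if missing:
            raise ValueError(f"layout is missing treatments: {sorted(missing)}")

    @property
    def row_length_m(self) -> float:
        return self.vine_spacing * self.vines_per_row


def default_layout(
    n_replicates: int = 4,
    seed: int = 0,
    vine_spacing: float = 1.2,
    row_spacing: float = 2.6,
    vines_per_row: int = 15,
    alley_m: float = 4.0,
) -> FieldLayout:
    """Grid of ``3 * n_replicates`` blocks with treatments shuffled per replicate.

    Replicates are columns; each column stacks the three treatments in an
    order drawn per replicate, giving the randomized-block spatial pattern
    the water-status maps are meant to resolve.
    """
    rng = np.random.default_rng(seed)
    row_len = vine_spacing * vines_per_row
    block_h = 3 * row_spacing
    blocks: list[BlockSpec] = []
    for rep in range(n_replicates):
        order = list(TREATMENTS)
        rng.shuffle(order)
        x0 = rep * (row_len + alley_m)
        for lane, treatment in enumerate(order):
            y0 = lane * (block_h + row_spacing)
            poly = box(x0, y0, x0 + row_len, y0 + block_h)
            blocks.append(
                BlockSpec(
                    block_id=f"B{rep * 3 + lane + 1:02d}",
                    treatment=treatment,
                    polygon=poly,
                    row_y=y0 + block_h / 2.0,
                    x_start=x0,
                    x_end=x0 + row_len,
                )
            )
    return FieldLayout(
        blocks=blocks,
        vine_spacing=vine_spacing,
        row_spacing=row_spacing,
        vines_per_row=vines_per_row,
    )


# ---------------------------------------------------------------------------
# scene mix
# ---------------------------------------------------------------------------


@dataclass
class SceneMix:
    """Probability that a stream frame views leaf vs. each interference class."""

    p_leaf: float = 0.7
    interference_weights: Mapping[str, float] = field(
        default_factory=lambda: {k: 0.06 for k in INTERFERENCE_CLASSES}
    )

    def __post_init__(self) -> None:
        total = self.p_leaf + sum(self.interference_weights.values())
        if not (0.0 <= self.p_leaf <= 1.0) or abs(total - 1.0) > 1e-9:
            raise ValueError("p_leaf and interference weights must sum to 1")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Per-frame labels: 'leaf' or an interference class name."""
        labels = ["leaf"] + list(self.interference_weights)
        probs = [self.p_leaf] + list(self.interference_weights.values())
        return rng.choice(labels, size=n, p=probs)


# ---------------------------------------------------------------------------
# leaf reflectance
# ---------------------------------------------------------------------------


def _gauss(wl: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - mu) / sigma) ** 2)


def _baseline(wl: np.ndarray) -> np.ndarray:
    u = (wl - 1400.0) / 500.0
    return 0.55 - 0.10 * u - 0.04 * u**2


def leaf_reflectance_batch(
    psis: np.ndarray,
    sensor: SensorSpec,
    noise_sd: float,
    rng: np.random.Generator,
    scatter: bool | tuple[float, float] = True,
    water_link: tuple[float, float] = (0.9, 0.25),
    psi_floor: float = -2.5,
) -> np.ndarray:
    """Vectorised leaf model: one reflectance row per psi value."""
    psis = np.atleast_1d(np.asarray(psis, dtype=float))
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if np.any(psis > 0) or np.any(psis < psi_floor):
        raise ValueError(f"psi must lie in [{psi_floor}, 0] MPa")
    wl = sensor.wavelengths
    w0, w1 = water_link
    W = w0 + w1 * psis  # leaf water content, higher when wetter
    absorb = np.zeros((psis.size, wl.size))
    for mu, sigma, amp, expo in WATER_BANDS:
        if mu < wl[0] - 3 * sigma or mu > wl[-1] + 3 * sigma:
            log.debug("water band at %.0f nm outside %s range; skipped", mu, sensor.name)
            continue
        absorb += np.outer(amp * W**expo, _gauss(wl, mu, sigma))
    for mu, sigma, amp in DRY_BANDS:
        if mu < wl[0] - 3 * sigma or mu > wl[-1] + 3 * sigma:
            log.debug("dry-matter band at %.0f nm outside %s range; skipped", mu, sensor.name)
            continue
        absorb += amp * _gauss(wl, mu, sigma)[None, :]
    refl = _baseline(wl)[None, :] * np.exp(-absorb)
    if scatter is True:
        a = rng.uniform(0.9, 1.1, size=psis.size)
        b = rng.uniform(-0.02, 0.02, size=psis.size)
    elif scatter is False:
        a = np.ones(psis.size)
        b = np.zeros(psis.size)
    else:
        a = np.full(psis.size, float(scatter[0]))
        b = np.full(psis.size, float(scatter[1]))
    refl = a[:, None] * refl + b[:, None]
    if noise_sd > 0:
        refl = refl + rng.normal(0.0, noise_sd, size=refl.shape)
    return refl


def make_leaf_reflectance(
    psi: float,
    sensor: SensorSpec = SENSOR_2,
    noise_sd: float = 0.005,
    rng_seed: int | np.random.Generator = 0,
    scatter: bool | tuple[float, float] = True,
    water_link: tuple[float, float] = (0.9, 0.25),
    psi_floor: float = -2.5,
) -> Spectrum:
    """Synthesize one leaf reflectance spectrum for a vine at the given psi.

    The depth of the water bands (978 / 1454 / 1935 nm) increases with leaf
    water content, hence decreases with water stress; identical seeds yield
    bit-identical spectra.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    values = leaf_reflectance_batch(
        np.array([psi]), sensor, noise_sd, rng, scatter=scatter,
        water_link=water_link, psi_floor=psi_floor,
    )[0]
    return Spectrum(
        wavelengths=sensor.wavelengths,
        values=values,
        kind="reflectance",
        sensor=sensor.name,
        meta={"psi": float(psi), "material": "leaf"},
    )


# ---------------------------------------------------------------------------
# interference
# ---------------------------------------------------------------------------


def _interference_template(kind: str, wl: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stylized non-leaf material spectra; each call adds small jitter."""
    u = (wl - 1400.0) / 500.0
    j = rng.normal(0.0, 0.01)
    if kind == "sky_gap":
        # open canopy gap: bright, nearly flat, no water dips
        return 0.92 + 0.02 * u + j + rng.normal(0, 0.003, wl.size)
    if kind == "wood":
        # cordon/trunk: rising baseline, broad lignocellulose band, no 978 nm
        base = 0.42 + 0.10 * u + j
        ab = 0.55 * _gauss(wl, 1720.0, 90.0) + 0.45 * _gauss(wl, 1935.0, 120.0)
        return base * np.exp(-ab) + rng.normal(0, 0.004, wl.size)
    if kind == "wire":
        # trellis wire: dark metallic reflector with a linear tilt
        return 0.16 + 0.12 * (wl - wl[0]) / (wl[-1] - wl[0]) + j + rng.normal(0, 0.004, wl.size)
    if kind == "pipe":
        # polyethylene irrigation pipe: bright with sharp C-H overtones
        base = 0.68 + j
        ab = 0.45 * _gauss(wl, 1215.0, 28.0) + 0.60 * _gauss(wl, 1730.0, 30.0)
        return base * np.exp(-ab) + rng.normal(0, 0.004, wl.size)
    if kind == "berry":
        # grape berry: dark, steep red-edge tail, water bands broadened/shifted
        base = 0.10 + 0.07 * (wl - wl[0]) / (wl[-1] - wl[0]) + j
        ab = 0.25 * _gauss(wl, 1454.0, 140.0) + 1.60 * _gauss(wl, 1935.0, 110.0)
        return base * np.exp(-ab) + rng.normal(0, 0.004, wl.size)
    raise KeyError(f"unknown interference class: {kind!r}")


def reference_leaf_signature(sensor: SensorSpec, psi: float = -1.0) -> Spectrum:
    """Noise-free, scatter-free leaf spectrum used as the generation-time check."""
    return make_leaf_reflectance(psi, sensor, noise_sd=0.0, rng_seed=0, scatter=False)


def make_interference(
    kind: str,
    sensor: SensorSpec = SENSOR_2,
    rng_seed: int | np.random.Generator = 0,
    threshold: float = 0.985,
    signature: Spectrum | None = None,
    max_attempts: int = 5,
) -> Spectrum:
    """Synthesize a non-leaf frame guaranteed to fail the cosine screen.

    The template is validated at generation against a default leaf signature;
    if the cosine similarity is not below ``threshold`` the template is
    re-jittered, up to ``max_attempts`` times.
    """
    if kind not in INTERFERENCE_CLASSES:
        raise KeyError(f"unknown interference class: {kind!r}")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    wl = sensor.wavelengths
    sig = signature if signature is not None else reference_leaf_signature(sensor)
    sig_v = sig.values
    for _ in range(max_attempts):
        values = _interference_template(kind, wl, rng)
        cos = float(
            values @ sig_v / (np.linalg.norm(values) * np.linalg.norm(sig_v))
        )
        if cos < threshold:
            return Spectrum(
                wavelengths=wl,
                values=values,
                kind="reflectance",
                sensor=sensor.name,
                meta={"material": kind, "cosine_vs_signature": cos},
            )
    raise GenerationError(
        f"interference class {kind!r} could not reach cosine < {threshold} "
        f"vs the leaf signature after {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# pass and campaign simulation
# ---------------------------------------------------------------------------


@dataclass
class PassResult:
    """Everything one vehicle pass produces: references, signature, stream, GPS, truth."""

    sensor: SensorSpec
    date: str
    dark: Spectrum
    white: Spectrum
    signature_raw: Spectrum
    frames: list[Spectrum]  # raw counts, with timestamps, no geo (GPS is a feed)
    gps_feed: list[tuple[float, GeoPoint]]
    references: pd.DataFrame  # date, block_id, treatment, vine_group, psi_mpa, lon, lat
    frame_truth: pd.DataFrame  # material label and block per frame
    seed: int


def _lamp_counts(wl: np.ndarray) -> np.ndarray:
    # tungsten-halogen-like smooth envelope over the NIR window
    return 400.0 + 3400.0 * np.exp(-0.5 * ((wl - 1500.0) / 700.0) ** 2)


def _to_raw(refl: np.ndarray, dark_mean: np.ndarray, white_mean: np.ndarray) -> np.ndarray:
    return dark_mean + refl * (white_mean - dark_mean)


def simulate_pass(
    layout: FieldLayout,
    model: WaterStatusModel,
    mix: SceneMix,
    sensor: SensorSpec = SENSOR_2,
    date: str = DEFAULT_DATES[0],
    speed_kmh: float = 3.0,
    rng_seed: int = 0,
    noise_sd: float = 0.005,
    leaf_jitter_mpa: float = 0.03,
) -> PassResult:
    """Simulate one on-the-go pass over every monitored row on one date.

    Per block the monitored row contributes ``row_length / speed * rate``
    frames; each frame views leaf with probability ``mix.p_leaf`` (psi taken
    from its 5-vine group's reference value plus leaf-level jitter) or an
    interference class.  Three psi references per block are drawn from the
    (date, treatment) distribution.  GPS points run along the traversed row
    at 20 Hz, inside the block polygon.
    """
    if speed_kmh <= 0:
        raise ValueError("speed_kmh must be positive")
    if date not in model.dates:
        raise KeyError(f"date {date!r} absent from the water-status model")
    rng = np.random.default_rng(rng_seed)
    wl = sensor.wavelengths
    speed = speed_kmh / 3.6  # m/s
    dark_mean = np.full(wl.size, 400.0)
    white_mean = _lamp_counts(wl)
    dark = Spectrum(wl, dark_mean + rng.normal(0, 2.0, wl.size), kind="dark", sensor=sensor.name)
    white = Spectrum(wl, white_mean + rng.normal(0, 4.0, wl.size), kind="white", sensor=sensor.name)

    # stationary leaf signature: healthy mid-canopy leaf under the same optics
    sig_psi = model.psi_by_date_treatment[(date, "T1")][0]
    sig_refl = leaf_reflectance_batch(
        np.array([sig_psi]), sensor, noise_sd=0.002, rng=rng, scatter=(1.0, 0.0),
        water_link=model.water_link, psi_floor=model.psi_floor,
    )[0]
    signature_raw = Spectrum(
        wl, _to_raw(sig_refl, dark_mean, white_mean), kind="raw", sensor=sensor.name
    )

    frames: list[Spectrum] = []
    gps_feed: list[tuple[float, GeoPoint]] = []
    ref_rows: list[dict] = []
    truth_rows: list[dict] = []
    proj = layout.projection
    row_len = layout.row_length_m
    n_frames_row = int(round(row_len / speed * sensor.rate_hz))
    turn_gap_s = 8.0  # headland turn between rows
    t = 0.0
    for blk in layout.blocks:
        group_psi = model.draw_psi(date, blk.treatment, layout.groups_per_block, rng)
        # reference vines sit mid-group along the monitored row
        group_len = row_len / layout.groups_per_block
        for g, psi in enumerate(group_psi):
            gx = blk.x_start + (g + 0.5) * group_len
            lon, lat = proj.to_lonlat(gx, blk.row_y)
            ref_rows.append(
                dict(
                    date=date,
                    block_id=blk.block_id,
                    treatment=blk.treatment,
                    vine_group=g + 1,
                    psi_mpa=float(psi),
                    lon=float(lon),
                    lat=float(lat),
                )
            )
        labels = mix.draw(n_frames_row, rng)
        xs = blk.x_start + (np.arange(n_frames_row) + 0.5) * (row_len / n_frames_row)
        times = t + np.arange(n_frames_row) / sensor.rate_hz
        seg = np.minimum(
            (xs - blk.x_start) // group_len, layout.groups_per_block - 1
        ).astype(int)
        leaf_mask = labels == "leaf"
        leaf_psis = np.clip(
            group_psi[seg[leaf_mask]] + rng.normal(0, leaf_jitter_mpa, leaf_mask.sum()),
            model.psi_floor,
            model.psi_ceil,
        )
        refl = np.empty((n_frames_row, wl.size))
        if leaf_mask.any():
            refl[leaf_mask] = leaf_reflectance_batch(
                leaf_psis, sensor, noise_sd, rng,
                water_link=model.water_link, psi_floor=model.psi_floor,
            )
        for i in np.flatnonzero(~leaf_mask):
            refl[i] = make_interference(labels[i], sensor, rng_seed=rng).values
        raw = _to_raw(refl, dark_mean, white_mean)
        for i in range(n_frames_row):
            frames.append(
                Spectrum(wl, raw[i], kind="raw", sensor=sensor.name, timestamp=float(times[i]))
            )
            truth_rows.append(
                dict(timestamp=float(times[i]), material=labels[i], block_id=blk.block_id)
            )
        # 20 Hz GPS along the row, inside the block polygon
        n_gps = int(round(row_len / speed * 20.0))
        gps_t = t + np.arange(n_gps) / 20.0
        gps_x = blk.x_start + (gps_t - t) * speed
        lon, lat = proj.to_lonlat(gps_x, np.full(n_gps, blk.row_y))
        for ti, lo, la in zip(gps_t, lon, lat):
            gps_feed.append((float(ti), GeoPoint(float(lo), float(la))))
        t = float(times[-1]) + 1.0 / sensor.rate_hz + turn_gap_s

    return PassResult(
        sensor=sensor,
        date=date,
        dark=dark,
        white=white,
        signature_raw=signature_raw,
        frames=frames,
        gps_feed=gps_feed,
        references=pd.DataFrame(ref_rows),
        frame_truth=pd.DataFrame(truth_rows),
        seed=int(rng_seed),
    )


@dataclass
class Campaign:
    """A season of passes (one per date) plus the generator manifest."""

    passes: list[PassResult]
    layout: FieldLayout
    model: WaterStatusModel
    mix: SceneMix
    sensor: SensorSpec
    manifest: dict

    @property
    def references(self) -> pd.DataFrame:
        return pd.concat([p.references for p in self.passes], ignore_index=True)

    def checksum(self) -> str:
        """SHA-256 over every stream frame and reference row (determinism probe)."""
        h = hashlib.sha256()
        for p in self.passes:
            for s in p.frames:
                h.update(s.values.tobytes())
            h.update(p.references.to_csv(index=False).encode())
        return h.hexdigest()


def simulate_campaign(
    dates: Sequence[str] | None = None,
    layout: FieldLayout | None = None,
    model: WaterStatusModel | None = None,
    mix: SceneMix | None = None,
    sensor: SensorSpec = SENSOR_2,
    speed_kmh: float = 3.0,
    seed: int = 0,
    noise_sd: float = 0.005,
) -> Campaign:
    """Simulate a multi-date campaign; defaults reproduce the study layout.

    With the default layout (12 blocks) and six dates this yields
    6 x 12 x 3 = 216 psi references.  Identical seeds reproduce the campaign
    bit-for-bit (see :meth:`Campaign.checksum`).
    """
    model = model if model is not None else default_water_model()
    dates = list(dates) if dates is not None else model.dates
    if len(dates) < 2:
        raise ValueError("a campaign needs at least two dates")
    layout = layout if layout is not None else default_layout(seed=seed)
    mix = mix if mix is not None else SceneMix()
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(dates))]
    passes = [
        simulate_pass(
            layout, model, mix, sensor=sensor, date=d, speed_kmh=speed_kmh,
            rng_seed=cs, noise_sd=noise_sd,
        )
        for d, cs in zip(sorted(dates), child_seeds)
    ]
    manifest = {
        "seed": seed,
        "sensor": sensor.name,
        "speed_kmh": speed_kmh,
        "noise_sd": noise_sd,
        "dates": ",".join(sorted(dates)),
        "n_blocks": len(layout.blocks),
        "groups_per_block": layout.groups_per_block,
        "p_leaf": mix.p_leaf,
        "psi_floor": model.psi_floor,
        "psi_ceil": model.psi_ceil,
        "water_link_w0": model.water_link[0],
        "water_link_w1": model.water_link[1],
        "pass_seeds": ",".join(str(c) for c in child_seeds),
    }
    return Campaign(passes, layout, model, mix, sensor, manifest)


def layout_to_geojson(layout: FieldLayout) -> dict:
    """Block polygons as GeoJSON (lon/lat) with block_id/treatment properties."""
    feats = []
    proj = layout.projection
    for b in layout.blocks:
        ring = []
        for x, y in b.polygon.exterior.coords:
            lon, lat = proj.to_lonlat(x, y)
            ring.append([float(lon), float(lat)])
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "block_id": b.block_id,
                    "treatment": b.treatment,
                    "row_y_m": b.row_y,
                    "x_start_m": b.x_start,
                    "x_end_m": b.x_end,
                },
            }
        )
    return {
        "type": "FeatureCollection",
        "features": feats,
        "properties": {
            "origin_lon": proj.lon0,
            "origin_lat": proj.lat0,
            "vine_spacing_m": layout.vine_spacing,
            "row_spacing_m": layout.row_spacing,
            "vines_per_row": layout.vines_per_row,
        },
    }


def layout_from_geojson(doc: Mapping) -> FieldLayout:
    props = doc.get("properties", {})
    proj = LocalProjection(lon0=props["origin_lon"], lat0=props["origin_lat"])
    blocks = []
    for feat in doc["features"]:
        fp = feat["properties"]
        ring = feat["geometry"]["coordinates"][0]
        xy = [proj.to_xy(lon, lat) for lon, lat in ring]
        poly = Polygon([(float(x), float(y)) for x, y in xy])
        blocks.append(
            BlockSpec(
                block_id=fp["block_id"],
                treatment=fp["treatment"],
                polygon=poly,
                row_y=float(fp["row_y_m"]),
                x_start=float(fp["x_start_m"]),
                x_end=float(fp["x_end_m"]),
            )
        )
    return FieldLayout(
        blocks=blocks,
        vine_spacing=float(props.get("vine_spacing_m", 1.2)),
        row_spacing=float(props.get("row_spacing_m", 2.6)),
        vines_per_row=int(props.get("vines_per_row", 15)),
        projection=proj,
    )


def write_manifest(path, manifest: Mapping) -> None:
    with open(path, "w") as fh:
        for key, val in manifest.items():
            fh.write(f"{key}={val}\n")


def read_manifest(path) -> dict:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                key, _, val = line.strip().partition("=")
                out[key] = val
    return out
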