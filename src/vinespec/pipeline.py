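"""End-to-end orchestration: simulate -> acquire -> filter -> model -> map.

Each stage is runnable standalone from the previous stage's outputs (see
:mod:`vinespec.cli`); this module holds the in-memory plumbing they share.
The modelling sample unit is the block-averaged accepted spectrum of one
date, paired with each of the block's three per-group psi references.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import acquisition, chemometrics, filtering, mapping
from .preprocessing import PreprocConfig, SavgolParams
from .sensors import SENSORS, SENSOR_2, SensorSpec
from .synthetic import Campaign, FieldLayout, PassResult, simulate_campaign


@dataclass
class SampleTable:
    """Flat modelling dataset: one row per (block, date, vine group)."""

    X: np.ndarray  # raw block-mean reflectance, (n, p)
    y: np.ndarray  # psi references, MPa
    dates: np.ndarray
    block_ids: np.ndarray
    treatments: np.ndarray
    x_m: np.ndarray  # group positions, local metres
    y_m: np.ndarray
    wavelengths: np.ndarray

    @property
    def n(self) -> int:
        return self.y.size

    def subset(self, idx: np.ndarray) -> "SampleTable":
        return SampleTable(
            self.X[idx], self.y[idx], self.dates[idx], self.block_ids[idx],
            self.treatments[idx], self.x_m[idx], self.y_m[idx], self.wavelengths,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "date": self.dates,
                "block_id": self.block_ids,
                "treatment": self.treatments,
                "psi_mpa": self.y,
                "x_m": self.x_m,
                "y_m": self.y_m,
            }
        )
        spec = pd.DataFrame(self.X, columns=[f"R_{w:.2f}" for w in self.wavelengths])
        return pd.concat([df, spec], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleTable":
        spec_cols = [c for c in df.columns if c.startswith("R_")]
        wl = np.array([float(c[2:]) for c in spec_cols])
        return cls(
            X=df[spec_cols].to_numpy(float),
            y=df["psi_mpa"].to_numpy(float),
            dates=df["date"].to_numpy(str),
            block_ids=df["block_id"].to_numpy(str),
            treatments=df["treatment"].to_numpy(str),
            x_m=df["x_m"].to_numpy(float),
            y_m=df["y_m"].to_numpy(float),
            wavelengths=wl,
        )


@dataclass
class FilterStats:
    total: int = 0
    accepted: int = 0
    rejected: int = 0
    dropped_outside: int = 0


def process_pass(
    p: PassResult,
    layout: FieldLayout,
    threshold: float = acquisition.DEFAULT_THRESHOLD,
) -> tuple[list[dict], FilterStats]:
    """Acquisition replay + filtering + block averaging for one pass.

    Returns one record per (block, vine group): the block-mean spectrum
    paired with that group's psi reference, plus filter bookkeeping.
    """
    session = acquisition.run_session(
        p.frames, p.dark, p.white, p.signature_raw,
        threshold=threshold, gps_feed=p.gps_feed,
    )
    assignments, dropped = filtering.assign_blocks(session.accepted, layout)
    stats = FilterStats(
        total=session.total_frames,
        accepted=len(session.accepted),
        rejected=session.rejected_count,
        dropped_outside=dropped,
    )
    proj = layout.projection
    records: list[dict] = []
    by_block = {a.block_id: a for a in assignments}
    for _, ref in p.references.iterrows():
        a = by_block[ref.block_id]
        if not a.spectra:
            raise RuntimeError(f"block {ref.block_id} collected no accepted spectra")
        mean_spec = filtering.block_average(a)
        gx, gy = proj.to_xy(ref.lon, ref.lat)
        records.append(
            dict(
                date=ref.date,
                block_id=ref.block_id,
                treatment=ref.treatment,
                vine_group=int(ref.vine_group),
                psi_mpa=float(ref.psi_mpa),
                x_m=float(gx),
                y_m=float(gy),
                spectrum=mean_spec.values,
            )
        )
    return records, stats


def campaign_to_samples(
    campaign: Campaign, threshold: float = acquisition.DEFAULT_THRESHOLD
) -> tuple[SampleTable, FilterStats]:
    """Run acquisition and filtering over every pass of a campaign."""
    records: list[dict] = []
    totals = FilterStats()
    for p in campaign.passes:
        recs, stats = process_pass(p, campaign.layout, threshold)
        records.extend(recs)
        totals.total += stats.total
        totals.accepted += stats.accepted
        totals.rejected += stats.rejected
        totals.dropped_outside += stats.dropped_outside
    wl = campaign.sensor.wavelengths
    table = SampleTable(
        X=np.vstack([r["spectrum"] for r in records]),
        y=np.array([r["psi_mpa"] for r in records]),
        dates=np.array([r["date"] for r in records]),
        block_ids=np.array([r["block_id"] for r in records]),
        treatments=np.array([r["treatment"] for r in records]),
        x_m=np.array([r["x_m"] for r in records]),
        y_m=np.array([r["y_m"] for r in records]),
        wavelengths=wl,
    )
    return table, totals


def external_validation(
    table: SampleTable,
    preproc: PreprocConfig | None = None,
    per_date: int = 7,
    rng_seed: int = 0,
    k: int = 10,
    a_max: int = 20,
) -> tuple[chemometrics.PLSModel, chemometrics.ModelMetrics]:
    """Per-date external split, train on the remainder, score the held-out set."""
    train_idx, val_idx = chemometrics.external_split(
        table.dates, table.y, per_date=per_date, rng_seed=rng_seed
    )
    train, val = table.subset(train_idx), table.subset(val_idx)
    model, cv, metrics = chemometrics.train_model(
        train.X, train.y, table.wavelengths, preproc=preproc, k=k, a_max=a_max
    )
    y_pred = chemometrics.predict(model, val.X, table.wavelengths)
    metrics.r2p, metrics.rmsep = chemometrics.evaluate(val.y, y_pred)
    return model, metrics


def build_maps(
    table: SampleTable,
    model: chemometrics.PLSModel,
    date: str,
    n_classes: int = 3,
    scheme: str = "quantile",
    cell_size: float = 2.0,
    smoothing: float = 300.0,
    projection=None,
) -> tuple[mapping.MapGrid, mapping.MapGrid, mapping.MapAgreement]:
    """Predicted vs reference water-status maps for one date.

    Predictions come from the block-mean spectra evaluated at the group
    positions; the reference map interpolates the pressure-bomb psi values
    at the same points, so the two surfaces share one grid.
    """
    sel = table.dates == date
    if not sel.any():
        raise KeyError(f"no samples for date {date!r}")
    sub = table.subset(np.flatnonzero(sel))
    pts = np.column_stack([sub.x_m, sub.y_m])
    y_pred = chemometrics.predict(model, sub.X, table.wavelengths)
    pred_grid = mapping.spline_interpolate(
        pts, y_pred, smoothing=smoothing, cell_size=cell_size, projection=projection
    )
    ref_grid = mapping.spline_interpolate(
        pts, sub.y, grid=pred_grid.spec, smoothing=smoothing, projection=projection
    )
    mapping.classify_pair(pred_grid, ref_grid, n_classes=n_classes, scheme=scheme)
    agreement = mapping.compare_maps(pred_grid, ref_grid)
    return pred_grid, ref_grid, agreement


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; round-trips through JSON."""

    seed: int = 0
    sensor: str = SENSOR_2.name
    threshold: float = acquisition.DEFAULT_THRESHOLD
    noise_sd: float = 0.005
    speed_kmh: float = 3.0
    savgol_window: int = 7
    savgol_polyorder: int = 2
    savgol_deriv: int = 1
    preproc_steps: tuple[str, ...] = ("snv", "savgol")
    cv_folds: int = 10
    a_max: int = 20
    per_date_validation: int = 7
    map_classes: int = 3  # low/medium/high stress zones for irrigation decisions
    map_scheme: str = "quantile"
    map_cell_m: float = 2.0
    # spline penalty sized so the surface departs from the point data by about
    # the reference method's ~0.1 MPa sampling noise instead of chasing it
    map_smoothing: float = 300.0

    def preproc(self) -> PreprocConfig:
        return PreprocConfig(
            steps=tuple(self.preproc_steps),
            savgol=SavgolParams(self.savgol_window, self.savgol_polyorder, self.savgol_deriv),
        )

    def sensor_spec(self) -> SensorSpec:
        return SENSORS[self.sensor]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["preproc_steps"] = tuple(d.get("preproc_steps", ("snv", "savgol")))
        return cls(**d)

    def checksum(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass
class RunResult:
    config: RunConfig
    table: SampleTable
    filter_stats: FilterStats
    model: chemometrics.PLSModel
    cv: chemometrics.CVResult
    metrics: chemometrics.ModelMetrics
    vip: chemometrics.VIPResult
    map_date: str
    map_agreement: mapping.MapAgreement
    log: list[str] = field(default_factory=list)


def run_all(config: RunConfig, out_dir: str | None = None) -> RunResult:
    """Full pipeline on a simulated campaign; optionally writes artifacts."""
    log: list[str] = [f"config checksum {config.checksum()}"]
    campaign = simulate_campaign(
        sensor=config.sensor_spec(), seed=config.seed,
        noise_sd=config.noise_sd, speed_kmh=config.speed_kmh,
    )
    log.append(
        f"simulated {len(campaign.passes)} passes, "
        f"{len(campaign.references)} psi references"
    )
    table, stats = campaign_to_samples(campaign, threshold=config.threshold)
    log.append(
        f"filtered {stats.total} frames: {stats.accepted} accepted, "
        f"{stats.rejected} rejected, {stats.dropped_outside} outside blocks"
    )
    model, cv, metrics = chemometrics.train_model(
        table.X, table.y, table.wavelengths, preproc=config.preproc(),
        k=config.cv_folds, a_max=config.a_max,
    )
    vip = chemometrics.vip_scores(model)
    log.append(
        f"calibration: {cv.chosen_lv} LV, R2c={metrics.r2c:.3f} "
        f"RMSEC={metrics.rmsec:.3f} MPa, R2cv={metrics.r2cv:.3f} "
        f"RMSECV={metrics.rmsecv:.3f} MPa"
    )
    _, ext_metrics = external_validation(
        table, preproc=config.preproc(), per_date=config.per_date_validation,
        rng_seed=config.seed, k=config.cv_folds, a_max=config.a_max,
    )
    metrics.r2p, metrics.rmsep = ext_metrics.r2p, ext_metrics.rmsep
    log.append(f"external validation: R2p={metrics.r2p:.3f} RMSEP={metrics.rmsep:.3f} MPa")
    map_date = sorted(set(table.dates))[-1]
    pred_grid, ref_grid, agreement = build_maps(
        table, model, map_date, n_classes=config.map_classes,
        scheme=config.map_scheme, cell_size=config.map_cell_m,
        smoothing=config.map_smoothing,
        projection=campaign.layout.projection,
    )
    log.append(
        f"map {map_date}: r={agreement.pearson_r:.3f} RMSD={agreement.rmsd_mpa:.3f} MPa "
        f"class agreement={agreement.class_agreement:.3f} over {agreement.n_cells} cells"
    )
    result = RunResult(
        config=config, table=table, filter_stats=stats, model=model, cv=cv,
        metrics=metrics, vip=vip, map_date=map_date, map_agreement=agreement, log=log,
    )
    if out_dir is not None:
        _write_run(result, campaign, pred_grid, ref_grid, out_dir)
    return result


def _write_run(result: RunResult, campaign, pred_grid, ref_grid, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    cfg_tag = result.config.checksum()
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        fh.write(result.config.to_json())
    from .synthetic import write_manifest

    manifest = dict(campaign.manifest)
    manifest["config_checksum"] = cfg_tag
    write_manifest(os.path.join(out_dir, "manifest.txt"), manifest)
    result.table.to_frame().to_csv(os.path.join(out_dir, "samples.csv"), index=False)
    provenance = {
        "config_checksum": cfg_tag,
        "seed": result.config.seed,
        "data_checksum": chemometrics.data_checksum(result.table.X, result.table.y),
    }
    with open(os.path.join(out_dir, "model.json"), "w") as fh:
        fh.write(chemometrics.model_to_json(result.model, result.metrics, provenance))
    vip_df = pd.DataFrame(
        {"wavelength_nm": result.model.wavelengths, "vip": result.vip.scores}
    )
    vip_df.to_csv(os.path.join(out_dir, "vip.csv"), index=False)
    mapping.write_geojson(os.path.join(out_dir, f"map_predicted_{result.map_date}.geojson"), pred_grid)
    mapping.write_geojson(os.path.join(out_dir, f"map_reference_{result.map_date}.geojson"), ref_grid)
    mapping.write_raster_csv(os.path.join(out_dir, f"map_predicted_{result.map_date}.csv"), pred_grid)
    with open(os.path.join(out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(result.log) + "\n")
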