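"""Vineyard water-status maps: spline interpolation and zone classification.

Point psi values (predicted per block or measured per vine group) are
interpolated into a continuous surface with a thin-plate spline — the
smoothest surface in the bending-energy sense, exact at the data points when
the smoothing penalty is zero and reproducing affine trends for any penalty —
then classified into at most five zones to support irrigation decisions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator
from shapely.geometry import MultiPoint

from .geo import LocalProjection

MAX_CLASSES = 5


@dataclass
class GridSpec:
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    cell_size: float = 2.0  # m; below the 2.60 m row spacing

    @property
    def shape(self) -> tuple[int, int]:
        nx = int(np.ceil((self.x_max - self.x_min) / self.cell_size))
        ny = int(np.ceil((self.y_max - self.y_min) / self.cell_size))
        return ny, nx

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape
        xs = self.x_min + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.y_min + (np.arange(ny) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class MapGrid:
    """Interpolated psi surface with an in-plot mask and optional classes."""

    spec: GridSpec
    values: np.ndarray  # MPa per cell, (ny, nx)
    mask: np.ndarray  # True where the cell is inside the plot
    class_breaks: np.ndarray | None = None  # ascending internal breaks, MPa
    class_id: np.ndarray | None = None  # 0 = most negative (most stressed)
    projection: LocalProjection | None = None

    def same_spec(self, other: "MapGrid") -> bool:
        a, b = self.spec, other.spec
        return (
            self.values.shape == other.values.shape
            and np.isclose(a.cell_size, b.cell_size)
            and np.allclose([a.x_min, a.y_min], [b.x_min, b.y_min])
        )

    @property
    def n_classes(self) -> int:
        return 0 if self.class_breaks is None else self.class_breaks.size + 1


def spline_interpolate(
    points: np.ndarray,
    values: np.ndarray,
    grid: GridSpec | None = None,
    smoothing: float = 0.0,
    mask_buffer_m: float = 2.6,
    cell_size: float = 2.0,
    projection: LocalProjection | None = None,
) -> MapGrid:
    """Thin-plate-spline surface through (x, y, psi) points on a regular grid.

    ``smoothing`` is the spline penalty: 0 gives exact interpolation at the
    data points, larger values trade fidelity for smoothness.  Cells outside
    the convex hull of the points, buffered by one row spacing, are masked.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    values = np.asarray(values, dtype=float).ravel()
    if points.shape[0] != values.size:
        raise ValueError("points and values disagree on length")
    if points.shape[0] < 3:
        raise ValueError("need at least three points to fit a surface")
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    if smoothing == 0.0:
        uniq = np.unique(points, axis=0)
        rank = np.linalg.matrix_rank(np.column_stack([uniq, np.ones(len(uniq))]))
        if uniq.shape[0] < points.shape[0] or rank < 3:
            raise ValueError(
                "singular spline system (collinear or duplicate points); "
                "use smoothing > 0 or deduplicate the points"
            )
    # degree-1 polynomial tail -> constants and planes are reproduced exactly
    try:
        rbf = RBFInterpolator(
            points, values, kernel="thin_plate_spline", smoothing=smoothing, degree=1
        )
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular spline system (collinear or duplicate points); "
            "use smoothing > 0 or deduplicate the points"
        ) from exc
    if grid is None:
        pad = mask_buffer_m
        grid = GridSpec(
            points[:, 0].min() - pad,
            points[:, 1].min() - pad,
            points[:, 0].max() + pad,
            points[:, 1].max() + pad,
            cell_size=cell_size,
        )
    gx, gy = grid.cell_centres()
    flat = np.column_stack([gx.ravel(), gy.ravel()])
    surface = rbf(flat).reshape(gx.shape)
    hull = MultiPoint([tuple(p) for p in points]).convex_hull.buffer(mask_buffer_m)
    from shapely import contains_xy

    mask = contains_xy(hull, flat[:, 0], flat[:, 1]).reshape(gx.shape)
    vals = np.where(mask, surface, np.nan)
    return MapGrid(spec=grid, values=vals, mask=mask, projection=projection)


def classify(
    grid: MapGrid, n_classes: int = 5, scheme: str = "quantile"
) -> MapGrid:
    """Assign each unmasked cell to one of at most five ordered zones.

    ``quantile`` puts (nearly) equal cell counts in each class;
    ``equal_interval`` splits the observed psi range evenly.  Class 0 is the
    most negative (most stressed) zone; classification is order-preserving.
    """
    if not 1 <= n_classes <= MAX_CLASSES:
        raise ValueError(f"n_classes must lie in [1, {MAX_CLASSES}]")
    vals = grid.values[grid.mask]
    if vals.size < n_classes:
        raise ValueError("fewer unmasked cells than classes")
    if scheme == "quantile":
        qs = np.arange(1, n_classes) / n_classes
        breaks = np.quantile(vals, qs)
    elif scheme == "equal_interval":
        breaks = np.linspace(vals.min(), vals.max(), n_classes + 1)[1:-1]
    else:
        raise ValueError(f"unknown classification scheme: {scheme!r}")
    class_id = np.full(grid.values.shape, -1, dtype=int)
    class_id[grid.mask] = np.searchsorted(breaks, grid.values[grid.mask], side="right")
    grid.class_breaks = np.asarray(breaks, dtype=float)
    grid.class_id = class_id
    return grid


def classify_pair(
    a: MapGrid, b: MapGrid, n_classes: int = 3, scheme: str = "quantile"
) -> tuple[MapGrid, MapGrid]:
    """Classify two surfaces with one shared legend.

    Breaks are computed over the pooled unmasked cells of both grids, so the
    class maps are directly comparable — classifying each surface against
    its own breaks would make the class-agreement statistic meaningless.
    """
    if not 1 <= n_classes <= MAX_CLASSES:
        raise ValueError(f"n_classes must lie in [1, {MAX_CLASSES}]")
    pooled = np.concatenate([a.values[a.mask], b.values[b.mask]])
    if scheme == "quantile":
        breaks = np.quantile(pooled, np.arange(1, n_classes) / n_classes)
    elif scheme == "equal_interval":
        breaks = np.linspace(pooled.min(), pooled.max(), n_classes + 1)[1:-1]
    else:
        raise ValueError(f"unknown classification scheme: {scheme!r}")
    for g in (a, b):
        cid = np.full(g.values.shape, -1, dtype=int)
        cid[g.mask] = np.searchsorted(breaks, g.values[g.mask], side="right")
        g.class_breaks = np.asarray(breaks, dtype=float)
        g.class_id = cid
    return a, b


def class_labels(grid: MapGrid) -> list[str]:
    """Legend entries ordered from most to least negative psi."""
    if grid.class_breaks is None:
        return []
    edges = [-np.inf, *grid.class_breaks, np.inf]
    return [
        f"class {i}: {edges[i]:.2f} to {edges[i + 1]:.2f} MPa"
        for i in range(len(edges) - 1)
    ]


@dataclass
class MapAgreement:
    pearson_r: float
    rmsd_mpa: float
    class_agreement: float | None
    n_cells: int


def compare_maps(predicted: MapGrid, reference: MapGrid) -> MapAgreement:
    """Cell-wise agreement between two surfaces on the same grid spec."""
    if not predicted.same_spec(reference):
        raise ValueError("map grids do not share a grid spec")
    both = predicted.mask & reference.mask
    a = predicted.values[both]
    b = reference.values[both]
    if a.size < 2:
        raise ValueError("no overlapping unmasked cells to compare")
    if np.std(a) == 0 or np.std(b) == 0:
        r = 1.0 if np.allclose(a, b) else float("nan")
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    rmsd = float(np.sqrt(np.mean((a - b) ** 2)))
    agree = None
    if predicted.class_id is not None and reference.class_id is not None:
        agree = float(np.mean(predicted.class_id[both] == reference.class_id[both]))
    return MapAgreement(pearson_r=r, rmsd_mpa=rmsd, class_agreement=agree, n_cells=int(a.size))


def map_to_geojson(grid: MapGrid) -> dict:
    """GeoJSON FeatureCollection of cell polygons with psi and class properties.

    Cells are emitted in lon/lat when the grid carries a projection,
    otherwise in local plot metres.
    """
    feats = []
    ny, nx = grid.values.shape
    cs = grid.spec.cell_size
    for iy in range(ny):
        for ix in range(nx):
            if not grid.mask[iy, ix]:
                continue
            x0 = grid.spec.x_min + ix * cs
            y0 = grid.spec.y_min + iy * cs
            corners = [(x0, y0), (x0 + cs, y0), (x0 + cs, y0 + cs), (x0, y0 + cs), (x0, y0)]
            if grid.projection is not None:
                corners = [tuple(map(float, grid.projection.to_lonlat(x, y))) for x, y in corners]
            props = {"psi_mpa": round(float(grid.values[iy, ix]), 4)}
            if grid.class_id is not None:
                props["class"] = int(grid.class_id[iy, ix])
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [corners]},
                    "properties": props,
                }
            )
    return {"type": "FeatureCollection", "features": feats}


def write_geojson(path, grid: MapGrid) -> None:
    with open(path, "w") as fh:
        json.dump(map_to_geojson(grid), fh)


def write_raster_csv(path, grid: MapGrid) -> None:
    """Plain CSV raster: x, y (cell centres, m), psi, class (-1 if masked)."""
    gx, gy = grid.spec.cell_centres()
    with open(path, "w") as fh:
        fh.write("x_m,y_m,psi_mpa,class\n")
        ny, nx = grid.values.shape
        for iy in range(ny):
            for ix in range(nx):
                psi = grid.values[iy, ix]
                cid = -1 if grid.class_id is None else int(grid.class_id[iy, ix])
                psi_s = "" if np.isnan(psi) else f"{psi:.4f}"
                fh.write(f"{gx[iy, ix]:.2f},{gy[iy, ix]:.2f},{psi_s},{cid}\n")
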