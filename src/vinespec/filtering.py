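"""Cosine-similarity screening, block allocation, and per-block averaging.

On-the-go frames are compared against a single leaf spectral signature;
only frames at least as similar as the threshold (0.985 in the field
protocol) count as true leaf spectra.  Accepted frames are then allocated to
replication blocks by point-in-polygon on their GPS fix and averaged per
block into the sample spectrum that carries the chemometric signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, TYPE_CHECKING

import numpy as np
from shapely.geometry import Point

from .spectra import Spectrum, require_same_grid

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import FieldLayout


@dataclass(frozen=True)
class FilterConfig:
    method: str = "cosine"
    threshold: float = 0.985

    def __post_init__(self) -> None:
        if self.method != "cosine":
            raise ValueError(f"unsupported filter method: {self.method!r}")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0, 1]")


@dataclass
class BlockAssignment:
    block_id: str
    treatment: str
    spectra: list[Spectrum] = field(default_factory=list)
    n_rejected: int = 0


def cosine_similarity(a: Spectrum, b: Spectrum) -> float:
    """dot(a, b) / (|a| |b|); scale-invariant, in [-1, 1]."""
    require_same_grid(a, b)
    na = np.linalg.norm(a.values)
    nb = np.linalg.norm(b.values)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero-norm spectrum")
    return float(np.clip(a.values @ b.values / (na * nb), -1.0, 1.0))


def filter_stream(
    spectra: Sequence[Spectrum],
    signature: Spectrum,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[Spectrum], list[Spectrum]]:
    """Partition a stream into (accepted, rejected) by cosine vs the signature.

    Order is preserved; a frame exactly at the threshold is accepted.
    """
    accepted: list[Spectrum] = []
    rejected: list[Spectrum] = []
    for s in spectra:
        (accepted if cosine_similarity(s, signature) >= cfg.threshold else rejected).append(s)
    return accepted, rejected


def assign_blocks(
    spectra: Sequence[Spectrum],
    layout: "FieldLayout",
) -> tuple[list[BlockAssignment], int]:
    """Point-in-polygon allocation of located spectra to replication blocks.

    Returns the per-block assignments and the count of spectra dropped
    because they fell outside every block polygon (or carried no GPS fix).
    Block polygons live in the layout's local metric frame; GPS fixes are
    projected into it first.
    """
    assignments = [BlockAssignment(b.block_id, b.treatment) for b in layout.blocks]
    prepared = [(a, b.polygon) for a, b in zip(assignments, layout.blocks)]
    dropped = 0
    proj = layout.projection
    for s in spectra:
        if s.geo is None:
            dropped += 1
            continue
        x, y = proj.to_xy(s.geo.lon, s.geo.lat)
        pt = Point(float(x), float(y))
        for assignment, poly in prepared:
            # boundary-inclusive: frames on a block edge still belong to it
            if poly.intersects(pt):
                assignment.spectra.append(s)
                break
        else:
            dropped += 1
    return assignments, dropped


def block_average(assignment: BlockAssignment) -> Spectrum:
    """Channel-wise mean of a block's accepted spectra."""
    if not assignment.spectra:
        raise ValueError(f"block {assignment.block_id!r} has no accepted spectra")
    require_same_grid(*assignment.spectra)
    stack = np.vstack([s.values for s in assignment.spectra])
    first = assignment.spectra[0]
    out = first.with_values(stack.mean(axis=0), kind="reflectance")
    out.meta = {
        "block_id": assignment.block_id,
        "treatment": assignment.treatment,
        "n_averaged": len(assignment.spectra),
    }
    out.timestamp = None
    out.geo = None
    return out
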