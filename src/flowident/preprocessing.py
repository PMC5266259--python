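"""Denoising of event data by reproducible digital gating.

Bacterial FCM samples contain (in)organic debris and instrument noise on top
of the stained cells. Cells are recovered by a fixed polygon gate drawn in a
transformed bivariate space — conventionally arcsinh(FL1) vs arcsinh(FL3)
for SYBR-Green-stained samples, where the nucleic-acid signal separates cells
from the low-fluorescence debris corner. The same gate is applied to every
replicate of a culture (and to every sample of a gradient) before replicates
are pooled.

Boundary convention: events exactly on a polygon edge count as INSIDE, fixed
so that gating is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import yaml
from shapely.geometry import Polygon

from .fcs_io import EventMatrix, concat_events

__all__ = [
    "PolygonGate",
    "PopulationSample",
    "apply_gate",
    "cell_count",
    "default_gate",
    "load_gates",
    "pool_replicates",
    "transform_arcsinh",
]

#: EventMatrix.meta key recording which channels already hold arcsinh values.
ARCSINH_META_KEY = "arcsinh_channels"


def transform_arcsinh(events: EventMatrix, channels) -> EventMatrix:
    """Replace the listed channels by arcsinh(x) (cofactor 1).

    The transform is monotone and order-preserving per channel; other
    channels are untouched. A channel can be transformed once only — the
    result records the transformed channels in ``meta`` and a second request
    is refused.
    """
    channels = list(channels)
    already = set(events.meta.get(ARCSINH_META_KEY, ()))
    dup = sorted(already.intersection(channels))
    if dup:
        raise ValueError(f"channels already arcsinh-transformed: {dup}")
    idx = [events.index(ch) for ch in channels]
    values = events.values.copy()
    values[:, idx] = np.arcsinh(values[:, idx])
    meta = dict(events.meta)
    meta[ARCSINH_META_KEY] = tuple(sorted(already.union(channels)))
    return EventMatrix(list(events.channels), values, meta)


@dataclass
class PolygonGate:
    """A simple polygon in a transformed bivariate channel space.

    ``vertices`` are expressed in TRANSFORMED coordinates: when
    ``transform == "arcsinh"`` the gate channels of each event are
    arcsinh-transformed before the point-in-polygon test (the event's stored
    values are never modified).
    """

    channel_x: str
    channel_y: str
    vertices: np.ndarray
    transform: str = "arcsinh"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise ValueError("a polygon gate needs at least 3 vertices")
        if self.channel_x == self.channel_y:
            raise ValueError("gate channels must differ")
        if self.transform not in ("arcsinh", "identity"):
            raise ValueError(f"unknown gate transform {self.transform!r}")
        poly = Polygon(self.vertices)
        if not poly.is_valid or not poly.is_simple:
            raise ValueError("gate polygon must be simple (non-self-intersecting)")
        if poly.area <= 0:
            raise ValueError("degenerate gate polygon (zero area)")
        self._polygon = poly


def default_gate(
    threshold: float = 1.0,
    upper: float = 20.0,
    channel_x: str = "FL1-H",
    channel_y: str = "FL3-H",
) -> PolygonGate:
    """Axis-aligned rectangle covering [threshold, upper]^2 in arcsinh space.

    With the default threshold of 1 (raw intensity ~1.18) the gate keeps
    stained cells and drops the low-FL1/low-FL3 debris corner; per-culture
    polygons are a configuration input, this is only a sensible fallback.
    ``upper`` = 20 in arcsinh space corresponds to raw ~2.4e8, far beyond any
    detector range.
    """
    t, u = float(threshold), float(upper)
    return PolygonGate(
        channel_x=channel_x,
        channel_y=channel_y,
        vertices=np.array([[t, t], [u, t], [u, u], [t, u]]),
        transform="arcsinh",
    )


def apply_gate(events: EventMatrix, gate: PolygonGate):
    """Partition events into (inside, outside) the gate.

    Every input event lands in exactly one part and order is preserved
    within each; edge and vertex hits count as inside. Returned matrices
    carry the ORIGINAL (untransformed) values.
    """
    x = events.column(gate.channel_x)
    y = events.column(gate.channel_y)
    if gate.transform == "arcsinh":
        x, y = np.arcsinh(x), np.arcsinh(y)
    # intersects == inside-or-on-boundary for a point vs a polygon
    mask = shapely.intersects_xy(gate._polygon, x, y)
    return events.take(mask), events.take(~mask)


@dataclass
class PopulationSample:
    """One taxon's replicate measurements plus its pooled, gated event pool."""

    taxon_id: str
    replicates: list
    gate: PolygonGate
    pooled: EventMatrix
    meta: dict = field(default_factory=dict)


def pool_replicates(replicates, gate: PolygonGate, taxon_id: str = "sample") -> PopulationSample:
    """Gate each replicate with the SAME gate, then concatenate the survivors.

    Pooling after gating matches how axenic-culture replicates are combined
    before any community is subsampled; per-replicate gated counts are kept
    in ``meta['replicate_gated_counts']``.
    """
    replicates = list(replicates)
    if not replicates:
        raise ValueError("need at least one replicate")
    panel = replicates[0].channels
    for i, rep in enumerate(replicates[1:], start=1):
        if rep.channels != panel:
            differing = sorted(set(panel).symmetric_difference(rep.channels)) or "order"
            raise ValueError(
                f"replicate {i} panel mismatch (differing channels: {differing})"
            )
    gated, counts = [], []
    for rep in replicates:
        inside, _ = apply_gate(rep, gate)
        gated.append(inside)
        counts.append(inside.n_events)
    pooled = concat_events(gated)
    pooled.meta["replicate_gated_counts"] = tuple(counts)
    return PopulationSample(
        taxon_id=taxon_id,
        replicates=replicates,
        gate=gate,
        pooled=pooled,
        meta={"replicate_gated_counts": tuple(counts)},
    )


def cell_count(sample: PopulationSample) -> int:
    """Number of gated cells in the pooled sample.

    Conversion to a density (count / acquired volume) is the caller's
    arithmetic.
    """
    return sample.pooled.n_events


def load_gates(path) -> dict:
    """Load per-taxon gate definitions from a YAML mapping.

    Layout: ``taxon_id: {channel_x, channel_y, transform, vertices: [[x, y], ...]}``.
    A ``default`` entry applies to taxa without their own gate.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gates = {}
    for taxon, spec in raw.items():
        gates[taxon] = PolygonGate(
            channel_x=spec["channel_x"],
            channel_y=spec["channel_y"],
            vertices=np.asarray(spec["vertices"], dtype=float),
            transform=spec.get("transform", "arcsinh"),
        )
    return gates
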