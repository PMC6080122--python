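"""Consensus (Parkes) error grid zone assignment, type 1 diabetes variant.

The zone-transition polylines ship as a versioned CSV data file
(``data/ceg_type1_vertices.csv``) so the grid is auditable and swappable.
Coordinates follow the published technical digitization of the type 1 grid;
segments are linear between vertices and end exactly at the 550 mg/dL chart
boundary. Points falling exactly on a transition line are assigned the
lower-risk zone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .metrics import MetricConfig, round_half_up
from .study_model import PairedObservation

#: Inclusive axis domain of the grid, mg/dL.
DOMAIN_MAX = 550.0


class CEGZone(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"


#: Clinical risk order, least to most severe.
ZONE_ORDER = [CEGZone.A, CEGZone.B, CEGZone.C, CEGZone.D, CEGZone.E]

_UPPER = [("DE_upper", CEGZone.E), ("CD_upper", CEGZone.D), ("BC_upper", CEGZone.C), ("AB_upper", CEGZone.B)]
_LOWER = [("CD_lower", CEGZone.D), ("BC_lower", CEGZone.C), ("AB_lower", CEGZone.B)]


@dataclass(frozen=True)
class ZoneBoundarySet:
    """Vertex polylines for each zone transition; x = reference, y = CGM."""

    boundaries: dict[str, list[tuple[float, float]]]

    def __post_init__(self):
        for name, verts in self.boundaries.items():
            xs = [v[0] for v in verts]
            if any(b < a for a, b in zip(xs, xs[1:])):
                raise ValueError(f"boundary {name}: x-coordinates not monotone")


def load_default_boundaries() -> ZoneBoundarySet:
    with resources.files("cgmeval.data").joinpath("ceg_type1_vertices.csv").open() as fh:
        df = pd.read_csv(fh)
    boundaries: dict[str, list[tuple[float, float]]] = {}
    for name, grp in df.groupby("transition", sort=False):
        boundaries[name] = list(zip(grp["reference_mgdl"].astype(float), grp["cgm_mgdl"].astype(float)))
    return ZoneBoundarySet(boundaries)


_DEFAULT: ZoneBoundarySet | None = None


def _default() -> ZoneBoundarySet:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_default_boundaries()
    return _DEFAULT


def ceg_zones(
    ref: np.ndarray, cgm: np.ndarray, boundaries: ZoneBoundarySet | None = None
) -> np.ndarray:
    """Vectorized zone assignment; returns an array of zone letters.

    Both inputs must lie in ``[0, 550]`` mg/dL; out-of-range values are
    rejected (never clamped).
    """
    b = (boundaries or _default()).boundaries
    x = np.asarray(ref, dtype=float)
    y = np.asarray(cgm, dtype=float)
    if x.shape != y.shape:
        raise ValueError("ref and cgm must have the same shape")
    bad = (x < 0) | (x > DOMAIN_MAX) | (y < 0) | (y > DOMAIN_MAX) | ~np.isfinite(x) | ~np.isfinite(y)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} point(s) outside the [0, {DOMAIN_MAX:g}] mg/dL grid domain"
        )

    zone = np.full(x.shape, "A", dtype="U1")
    unassigned = np.ones(x.shape, dtype=bool)

    # Above-diagonal transitions, most severe first. Upper polylines end at
    # y = 550, so np.interp's right-fill (550) makes the strict ">" test
    # correctly unreachable past the last vertex.
    for name, z in _UPPER:
        verts = b[name]
        xs = np.array([v[0] for v in verts])
        ys = np.array([v[1] for v in verts])
        outer = unassigned & (y > np.interp(x, xs, ys))
        zone[outer] = z.value
        unassigned &= ~outer

    # Below-diagonal transitions. The first vertex is the foot of a vertical
    # segment; queries at or left of it lie on/inside the boundary and stay
    # in the lower-risk zone.
    for name, z in _LOWER:
        verts = b[name]
        x0 = verts[0][0]
        xs = np.array([v[0] for v in verts[1:]])
        ys = np.array([v[1] for v in verts[1:]])
        outer = unassigned & (x > x0) & (y < np.interp(x, xs, ys))
        zone[outer] = z.value
        unassigned &= ~outer

    return zone


def ceg_zone(ref: float, cgm: float, boundaries: ZoneBoundarySet | None = None) -> CEGZone:
    """Zone of a single (reference, CGM) pair."""
    return CEGZone(str(ceg_zones(np.array([ref]), np.array([cgm]), boundaries)[0]))


@dataclass(frozen=True)
class CEGSummary:
    """Zone counts and one-decimal percentages with an explicit denominator."""

    n_total: int
    counts: dict[str, int]
    percents: dict[str, float | None]


def ceg_summary(
    pairs: list[PairedObservation],
    boundaries: ZoneBoundarySet | None = None,
    cfg: MetricConfig | None = None,
) -> CEGSummary:
    cfg = cfg or MetricConfig()
    counts = {z.value: 0 for z in ZONE_ORDER}
    if pairs:
        zones = ceg_zones(
            np.array([p.ref.value for p in pairs]),
            np.array([p.cgm_value for p in pairs]),
            boundaries,
        )
        letters, n = np.unique(zones, return_counts=True)
        for z, c in zip(letters, n):
            counts[str(z)] = int(c)
    total = len(pairs)
    percents = {
        z: (round_half_up(100.0 * c / total, cfg.round_digits) if total else None)
        for z, c in counts.items()
    }
    return CEGSummary(n_total=total, counts=counts, percents=percents)


__all__ = [
    "DOMAIN_MAX",
    "CEGZone",
    "ZONE_ORDER",
    "ZoneBoundarySet",
    "CEGSummary",
    "load_default_boundaries",
    "ceg_zone",
    "ceg_zones",
    "ceg_summary",
]
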