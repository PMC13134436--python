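"""AHA 17-segment bookkeeping and coronary-territory aggregation.

Two territory schemes are supported:

* ``AHA_STANDARD`` — the conventional segment-to-artery mapping of the AHA
  17-segment model (LAD 7 segments, LCX 5, RCA 5).
* ``GEOMETRIC_SECTOR`` — polar-map sectors: a 150° LAD sector centred on the
  anterior wall (always including the apex), then clockwise a 105° LCX and a
  105° RCA sector.  Angles are measured clockwise from the anterior wall as
  drawn on the standard polar display (anterior 0° → lateral 90° → inferior
  180° → septal 270°); each segment is assigned by its centroid angle.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SchemeKind",
    "TerritoryScheme",
    "SegmentValues",
    "TERRITORIES",
    "SEGMENT_CENTROID_DEG",
    "territory_map",
    "aggregate",
]

TERRITORIES = ("LAD", "LCX", "RCA")

SEGMENTS = tuple(range(1, 18))

#: Conventional AHA segment-to-artery assignment.
AHA_STANDARD_MAP = {
    "LAD": frozenset({1, 2, 7, 8, 13, 14, 17}),
    "LCX": frozenset({5, 6, 11, 12, 16}),
    "RCA": frozenset({3, 4, 9, 10, 15}),
}

#: Polar-map centroid angle of each segment, degrees clockwise from anterior.
#: Basal (1–6) and mid (7–12) rings are 60°-wide, apical ring (13–16) 90°.
SEGMENT_CENTROID_DEG = {
    1: 0.0, 2: 300.0, 3: 240.0, 4: 180.0, 5: 120.0, 6: 60.0,
    7: 0.0, 8: 300.0, 9: 240.0, 10: 180.0, 11: 120.0, 12: 60.0,
    13: 0.0, 14: 270.0, 15: 180.0, 16: 90.0,
    17: 0.0,  # apex; force-assigned to LAD under the sector scheme
}


class SchemeKind(str, enum.Enum):
    AHA_STANDARD = "aha"
    GEOMETRIC_SECTOR = "geometric"


@dataclass(frozen=True)
class TerritoryScheme:
    kind: SchemeKind
    #: sector widths (degrees) for (LAD, LCX, RCA); ignored for AHA_STANDARD
    sector_widths: tuple[float, float, float] = (150.0, 105.0, 105.0)
    #: clockwise angle at which the LAD sector begins (its centre minus half
    #: its width); the default centres LAD on the anterior wall (0°)
    lad_start_deg: float = -75.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.kind is SchemeKind.GEOMETRIC_SECTOR:
            if not np.isclose(sum(self.sector_widths), 360.0):
                raise ValueError("sector widths must sum to 360 degrees")
            if any(w <= 0 for w in self.sector_widths):
                raise ValueError("sector widths must be positive")

    @classmethod
    def aha(cls) -> "TerritoryScheme":
        return cls(kind=SchemeKind.AHA_STANDARD)

    @classmethod
    def geometric(cls) -> "TerritoryScheme":
        return cls(kind=SchemeKind.GEOMETRIC_SECTOR)


@dataclass(frozen=True)
class SegmentValues:
    """One value per AHA segment, indexed 1–17."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (17,):
            raise ValueError("exactly 17 segment values required")

    def __getitem__(self, segment: int) -> float:
        if not 1 <= segment <= 17:
            raise KeyError(f"segment number out of range: {segment}")
        return float(self.values[segment - 1])


def territory_map(scheme: TerritoryScheme) -> dict[int, str]:
    """Segment → territory assignment under the given scheme."""
    if scheme.kind is SchemeKind.AHA_STANDARD:
        out = {}
        for terr, segs in AHA_STANDARD_MAP.items():
            for s in segs:
                out[s] = terr
        return {s: out[s] for s in SEGMENTS}
    scheme.validate()
    widths = scheme.sector_widths
    edges = np.cumsum([scheme.lad_start_deg, *widths])  # LAD, LCX, RCA bounds
    out = {}
    for seg in SEGMENTS:
        if seg == 17:
            out[seg] = "LAD"  # apex belongs to the LAD sector by definition
            continue
        ang = SEGMENT_CENTROID_DEG[seg]
        # reduce into [lad_start, lad_start + 360)
        rel = (ang - edges[0]) % 360.0 + edges[0]
        for ti, terr in enumerate(TERRITORIES):
            if edges[ti] <= rel < edges[ti + 1]:
                out[seg] = terr
                break
    return out


def aggregate(
    values: SegmentValues | np.ndarray, scheme: TerritoryScheme
) -> dict[str, float]:
    """Territory and global summaries as unweighted means of member segments.

    Returns a dict with keys 'LAD', 'LCX', 'RCA' and 'GLOBAL'; the global
    value is the mean of all 17 segments and is scheme-independent.
    """
    if not isinstance(values, SegmentValues):
        values = SegmentValues(values)
    mapping = territory_map(scheme)
    out: dict[str, float] = {}
    for terr in TERRITORIES:
        members = [s for s in SEGMENTS if mapping[s] == terr]
        out[terr] = float(np.mean([values[s] for s in members]))
    out["GLOBAL"] = float(np.mean(values.values))
    return out
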