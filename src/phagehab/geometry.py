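"""Parametric model of the two-layer etched hexagon-array microhabitat device.

The device is a honeycomb of hexagonal micro-chambers (etched 10 μm deep)
joined by narrow corridors, sandwiched between two parallel flow channels.
Each boundary row of chambers is coupled to its adjacent channel through
100 nm deep nanoslits: permeable to medium, nutrients and virions, but too
shallow for bacteria to cross.  One channel carries plain growth medium, the
other medium loaded with phage, so a virion gradient forms across the array.

The published description fixes the etch depths, the total etched chamber
area (~40 mm²) and the inlet-well volume (4×10⁻² μl), but not the number of
hexagons or the corridor dimensions; the :func:`reference_layout` preset is an
explicit reconstruction consistent with those constraints (see package docs).

Units: positions in mm, areas in mm², lateral dimensions in μm, chamber and
corridor depths in μm, nanoslit depth in nm, volumes in μl.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import networkx as nx

__all__ = [
    "Chamber",
    "Corridor",
    "Nanoslit",
    "Channel",
    "Inlet",
    "DeviceLayout",
    "CorridorSpec",
    "NanoslitSpec",
    "build_hex_array",
    "reference_layout",
    "medium_volume",
    "inoculum_count",
    "nearest_power_of_ten",
]

PHAGE_FEED = "phage-feed"
PLAIN_FEED = "plain-feed"

#: Default total etched chamber area (mm²) and depths from the device recipe.
DEFAULT_TARGET_AREA_MM2 = 40.0
DEFAULT_CHAMBER_DEPTH_UM = 10.0
DEFAULT_NANOSLIT_DEPTH_NM = 100.0
DEFAULT_INLET_VOLUME_UL = 4e-2


class InvalidParameterError(ValueError):
    """Raised for non-positive or otherwise unphysical geometry parameters."""


@dataclass(frozen=True)
class Chamber:
    id: int
    row: int
    col: int
    x_mm: float
    y_mm: float
    area_mm2: float
    depth_um: float


@dataclass(frozen=True)
class Corridor:
    a: int
    b: int
    width_um: float
    length_um: float
    depth_um: float


@dataclass(frozen=True)
class Nanoslit:
    chamber: int
    channel: str
    depth_nm: float
    width_um: float
    length_um: float


@dataclass(frozen=True)
class Channel:
    id: str
    role: str  # PHAGE_FEED or PLAIN_FEED
    y_mm: float


@dataclass(frozen=True)
class Inlet:
    chamber: int
    well_volume_ul: float


@dataclass(frozen=True)
class CorridorSpec:
    width_um: float = 5.0
    length_um: float = 80.0
    depth_um: float = DEFAULT_CHAMBER_DEPTH_UM

    def validate(self) -> None:
        if min(self.width_um, self.length_um, self.depth_um) <= 0:
            raise InvalidParameterError("corridor dimensions must be positive")


@dataclass(frozen=True)
class NanoslitSpec:
    width_um: float = 300.0
    length_um: float = 5.0
    depth_nm: float = DEFAULT_NANOSLIT_DEPTH_NM

    def validate(self) -> None:
        if min(self.width_um, self.length_um, self.depth_nm) <= 0:
            raise InvalidParameterError("nanoslit dimensions must be positive")


@dataclass
class DeviceLayout:
    chambers: list[Chamber]
    corridors: list[Corridor]
    nanoslits: list[Nanoslit]
    channels: list[Channel]
    inlet: Inlet
    rows: int = 0
    cols: int = 0
    meta: dict = field(default_factory=dict)

    # -- graph views ------------------------------------------------------
    def graph(self) -> nx.Graph:
        """Chamber graph: nodes are chamber ids, edges are corridors."""
        g = nx.Graph()
        g.add_nodes_from(c.id for c in self.chambers)
        g.add_edges_from((c.a, c.b) for c in self.corridors)
        return g

    def chamber_by_id(self, cid: int) -> Chamber:
        return self._index()[cid]

    def _index(self) -> dict[int, Chamber]:
        return {c.id: c for c in self.chambers}

    @property
    def n_chambers(self) -> int:
        return len(self.chambers)

    def total_area_mm2(self) -> float:
        return sum(c.area_mm2 for c in self.chambers)

    def validate(self) -> None:
        """Check all layout invariants; raises ``InvalidParameterError``."""
        if not self.chambers:
            raise InvalidParameterError("layout has no chambers")
        ids = {c.id for c in self.chambers}
        if len(ids) != len(self.chambers):
            raise InvalidParameterError("duplicate chamber ids")
        for c in self.chambers:
            if c.area_mm2 <= 0 or c.depth_um <= 0:
                raise InvalidParameterError(f"chamber {c.id}: non-positive area/depth")
        for cor in self.corridors:
            if cor.a not in ids or cor.b not in ids:
                raise InvalidParameterError("corridor references unknown chamber")
            if min(cor.width_um, cor.length_um, cor.depth_um) <= 0:
                raise InvalidParameterError("corridor with non-positive dimension")
        channel_ids = {ch.id for ch in self.channels}
        for slit in self.nanoslits:
            if slit.chamber not in ids:
                raise InvalidParameterError("nanoslit references unknown chamber")
            if slit.channel not in channel_ids:
                raise InvalidParameterError("nanoslit references unknown channel")
            if min(slit.width_um, slit.length_um, slit.depth_nm) <= 0:
                raise InvalidParameterError("nanoslit with non-positive dimension")
        if self.inlet.chamber not in ids:
            raise InvalidParameterError("inlet references unknown chamber")
        if self.inlet.well_volume_ul <= 0:
            raise InvalidParameterError("inlet volume must be positive")
        if not nx.is_connected(self.graph()):
            raise InvalidParameterError("chamber graph is not connected")

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "units": {
                "position": "mm",
                "area": "mm2",
                "chamber_depth": "um",
                "corridor": "um",
                "nanoslit_depth": "nm",
                "volume": "ul",
            },
            "rows": self.rows,
            "cols": self.cols,
            "meta": self.meta,
            "chambers": [asdict(c) for c in self.chambers],
            "corridors": [asdict(c) for c in self.corridors],
            "nanoslits": [asdict(s) for s in self.nanoslits],
            "channels": [asdict(ch) for ch in self.channels],
            "inlet": asdict(self.inlet),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DeviceLayout":
        doc = json.loads(text)
        layout = cls(
            chambers=[Chamber(**c) for c in doc["chambers"]],
            corridors=[Corridor(**c) for c in doc["corridors"]],
            nanoslits=[Nanoslit(**s) for s in doc["nanoslits"]],
            channels=[Channel(**ch) for ch in doc["channels"]],
            inlet=Inlet(**doc["inlet"]),
            rows=doc.get("rows", 0),
            cols=doc.get("cols", 0),
            meta=doc.get("meta", {}),
        )
        layout.validate()
        return layout


def _hex_side_for_area(target_area_mm2: float, n_chambers: int) -> float:
    # regular hexagon area = (3*sqrt(3)/2) * side^2
    per = target_area_mm2 / n_chambers
    return math.sqrt(2.0 * per / (3.0 * math.sqrt(3.0)))


def build_hex_array(
    rows: int,
    cols: int,
    hex_side_mm: float | None = None,
    corridor: CorridorSpec | None = None,
    nanoslit: NanoslitSpec | None = None,
    depth_um: float = DEFAULT_CHAMBER_DEPTH_UM,
    target_area_mm2: float | None = None,
    inlet_volume_ul: float = DEFAULT_INLET_VOLUME_UL,
) -> DeviceLayout:
    """Build a rows×cols honeycomb of hexagonal chambers between two channels.

    Row 0 sits next to the phage-feed channel, row ``rows-1`` next to the
    plain-feed channel; those boundary rows carry nanoslits.  The chamber
    nearest the array centroid is marked as the inlet.  Exactly one of
    ``hex_side_mm`` / ``target_area_mm2`` sets the chamber size (the latter
    distributes the target etched area over all chambers); with neither,
    the default target area of 40 mm² applies.
    """
    if rows < 1 or cols < 1:
        raise InvalidParameterError("rows and cols must be >= 1")
    if depth_um <= 0 or inlet_volume_ul <= 0:
        raise InvalidParameterError("depth and inlet volume must be positive")
    corridor = corridor or CorridorSpec()
    nanoslit = nanoslit or NanoslitSpec()
    corridor.validate()
    nanoslit.validate()

    n = rows * cols
    if hex_side_mm is None:
        area_target = DEFAULT_TARGET_AREA_MM2 if target_area_mm2 is None else target_area_mm2
        if area_target <= 0:
            raise InvalidParameterError("target area must be positive")
        side = _hex_side_for_area(area_target, n)
    else:
        if hex_side_mm <= 0:
            raise InvalidParameterError("hexagon side must be positive")
        if target_area_mm2 is not None:
            raise InvalidParameterError("give hex_side_mm or target_area_mm2, not both")
        side = hex_side_mm
    area = 1.5 * math.sqrt(3.0) * side * side

    pitch_x = math.sqrt(3.0) * side          # center distance within a row
    pitch_y = 1.5 * side                     # row spacing for a honeycomb
    chambers = []
    for r in range(rows):
        x_off = 0.5 * pitch_x if (r % 2) else 0.0
        for c in range(cols):
            chambers.append(
                Chamber(
                    id=r * cols + c,
                    row=r,
                    col=c,
                    x_mm=c * pitch_x + x_off,
                    y_mm=r * pitch_y,
                    area_mm2=area,
                    depth_um=depth_um,
                )
            )

    corridors = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                corridors.append(Corridor(i, i + 1, corridor.width_um, corridor.length_um, corridor.depth_um))
            if r + 1 < rows:
                corridors.append(Corridor(i, i + cols, corridor.width_um, corridor.length_um, corridor.depth_um))

    channels = [
        Channel(id="bottom", role=PHAGE_FEED, y_mm=-pitch_y),
        Channel(id="top", role=PLAIN_FEED, y_mm=rows * pitch_y),
    ]
    slits = []
    for c in range(cols):
        slits.append(Nanoslit(c, "bottom", nanoslit.depth_nm, nanoslit.width_um, nanoslit.length_um))
        slits.append(
            Nanoslit((rows - 1) * cols + c, "top", nanoslit.depth_nm, nanoslit.width_um, nanoslit.length_um)
        )
    if rows == 1:
        # a single row borders both channels; dedupe identical chamber/channel pairs
        seen = set()
        slits = [s for s in slits if (s.chamber, s.channel) not in seen and not seen.add((s.chamber, s.channel))]

    # inlet: chamber closest to the array centroid
    cx = sum(ch.x_mm for ch in chambers) / n
    cy = sum(ch.y_mm for ch in chambers) / n
    inlet_chamber = min(chambers, key=lambda ch: (ch.x_mm - cx) ** 2 + (ch.y_mm - cy) ** 2)

    layout = DeviceLayout(
        chambers=chambers,
        corridors=corridors,
        nanoslits=slits,
        channels=channels,
        inlet=Inlet(chamber=inlet_chamber.id, well_volume_ul=inlet_volume_ul),
        rows=rows,
        cols=cols,
        meta={"hex_side_mm": side, "pitch_x_mm": pitch_x, "pitch_y_mm": pitch_y},
    )
    layout.validate()
    return layout


def reference_layout() -> DeviceLayout:
    """Device preset reconstructing the published array.

    6 rows × 75 columns of hexagons sized so the total etched chamber area is
    40 mm²; narrow corridors (5 μm wide, 80 μm long, 10 μm deep) and 100 nm
    deep nanoslits.  Chamber count and lateral dimensions are not published;
    this preset is an informed reconstruction whose corridor constriction is
    set so the 20 h pre-run yields a steep, still-evolving gradient spanning
    several decades across the array (see docs/methods.md).
    """
    return build_hex_array(rows=6, cols=75, target_area_mm2=DEFAULT_TARGET_AREA_MM2)


def medium_volume(layout: DeviceLayout) -> float:
    """Total medium volume held by the chamber array, in μl.

    Σ area·depth over chambers; 1 mm² × 1 μm = 10⁻³ μl.  The inlet-well
    volume is a separate property of the inlet and is not included.
    """
    return sum(c.area_mm2 * c.depth_um for c in layout.chambers) * 1e-3


def nearest_power_of_ten(x: float) -> float:
    """Nearest power of ten on the log scale (round half away from zero)."""
    if x <= 0:
        raise InvalidParameterError("nearest_power_of_ten requires x > 0")
    e = math.log10(x)
    k = math.floor(e + 0.5) if e >= 0 else math.ceil(e - 0.5)
    return 10.0 ** k


def inoculum_count(concentration_per_ml: float, volume_ul: float) -> tuple[float, float]:
    """Expected cells inoculated from a suspension into a well.

    Returns ``(count, rounded)`` where ``rounded`` is the nearest power of
    ten (0 for a zero count).  E.g. 2×10⁸ cells/ml in a 4×10⁻² μl well gives
    8×10³ cells, i.e. ~10⁴.
    """
    if concentration_per_ml < 0 or volume_ul < 0:
        raise InvalidParameterError("concentration and volume must be non-negative")
    count = concentration_per_ml * volume_ul * 1e-3  # μl -> ml
    rounded = nearest_power_of_ten(count) if count > 0 else 0.0
    return count, rounded
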