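"""Arena configuration: zone geometry, adjacency and coordinate-to-zone mapping.

The multivariate concentric square field (MCSF) is a square arena divided
into functionally distinct zones (open center, central circle, corridors,
dark corner room shelter, hurdle, slope, bridge entrance and illuminated
bridge).  This module is the single authority for mapping a tracked 2-D
coordinate to a zone.

Conventions
-----------
* Origin at the arena's lower-left corner, x to the right, y up, units cm.
* Zone geometries are closed sets; a point lying on a boundary shared by
  several zones is assigned to the deepest (most nested) zone containing
  it, ties broken by config order.  This makes ``locate_zone`` total and
  deterministic.
* Nested zones (the central circle inside the center) are modeled as
  children; a point inside the child is reported as the child, never the
  parent, and the parent's time is not double-counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from shapely.geometry import Point, Polygon, box

from .errors import ConfigError, FormatError

UNASSIGNED = "unassigned"

_ROLE_TAGS = {"risk", "shelter", "corridor", "transit"}


# ---------------------------------------------------------------------------
# geometry primitives

@dataclass(frozen=True)
class Rect:
    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x, y):
        return (self.x0 <= x) & (x <= self.x1) & (self.y0 <= y) & (y <= self.y1)

    def as_shapely(self) -> Polygon:
        return box(self.x0, self.y0, self.x1, self.y1)

    def centroid(self):
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def to_dict(self):
        return {"rect": [self.x0, self.y0, self.x1, self.y1]}


@dataclass(frozen=True)
class Circle:
    cx: float
    cy: float
    r: float

    def contains(self, x, y):
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.r ** 2

    def as_shapely(self) -> Polygon:
        return Point(self.cx, self.cy).buffer(self.r, quad_segs=256)

    def centroid(self):
        return (self.cx, self.cy)

    def to_dict(self):
        return {"circle": [self.cx, self.cy, self.r]}


@dataclass(frozen=True)
class Poly:
    points: tuple

    def contains(self, x, y):
        poly = self.as_shapely()
        if np.isscalar(x):
            return poly.covers(Point(x, y))
        return np.array([poly.covers(Point(xi, yi)) for xi, yi in zip(x, y)])

    def as_shapely(self) -> Polygon:
        return Polygon(self.points)

    def centroid(self):
        c = self.as_shapely().centroid
        return (c.x, c.y)

    def to_dict(self):
        return {"polygon": [list(p) for p in self.points]}


def _parse_geometry(spec: Mapping, where: str):
    if not isinstance(spec, Mapping) or len(spec) != 1:
        raise FormatError(f"{where}: geometry must be a single-key mapping "
                          "(rect/circle/polygon)")
    kind, vals = next(iter(spec.items()))
    try:
        if kind == "rect":
            x0, y0, x1, y1 = map(float, vals)
            if not (x1 > x0 and y1 > y0):
                raise ConfigError(f"{where}: rect has non-positive extent")
            return Rect(x0, y0, x1, y1)
        if kind == "circle":
            cx, cy, r = map(float, vals)
            if r <= 0:
                raise ConfigError(f"{where}: circle radius must be > 0")
            return Circle(cx, cy, r)
        if kind == "polygon":
            pts = tuple(tuple(map(float, p)) for p in vals)
            if len(pts) < 3:
                raise ConfigError(f"{where}: polygon needs >= 3 points")
            return Poly(pts)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{where}: malformed geometry values: {exc}") from exc
    raise FormatError(f"{where}: unknown geometry kind {kind!r}")


# ---------------------------------------------------------------------------
# zones and arena

@dataclass(frozen=True)
class ZoneDef:
    """One named zone of the arena."""

    zone_id: str
    display_name: str
    geometry: object
    parent_zone: str | None = None
    light_lux: tuple | None = None
    role_tags: frozenset = frozenset()

    def to_dict(self):
        d = {"zone_id": self.zone_id, "display_name": self.display_name,
             "geometry": self.geometry.to_dict()}
        if self.parent_zone:
            d["parent_zone"] = self.parent_zone
        if self.light_lux is not None:
            d["light_lux"] = list(self.light_lux)
        if self.role_tags:
            d["role_tags"] = sorted(self.role_tags)
        return d


@dataclass(frozen=True)
class ArenaConfig:
    """Validated arena: zone collection, adjacency graph, session metadata."""

    arena_size: tuple
    zones: tuple  # ordered ZoneDefs, config order preserved
    adjacency: frozenset  # of frozenset pairs
    session_duration: float
    aggregates: Mapping[str, tuple] = field(default_factory=dict)
    version: int = 1

    # -- lookups ----------------------------------------------------------
    @property
    def zone_ids(self) -> tuple:
        return tuple(z.zone_id for z in self.zones)

    def zone(self, zone_id: str) -> ZoneDef:
        for z in self.zones:
            if z.zone_id == zone_id:
                return z
        raise KeyError(zone_id)

    def depth(self, zone_id: str) -> int:
        d, z = 0, self.zone(zone_id)
        while z.parent_zone:
            d += 1
            z = self.zone(z.parent_zone)
        return d

    def children(self, zone_id: str) -> tuple:
        return tuple(z.zone_id for z in self.zones if z.parent_zone == zone_id)

    def neighbors(self, zone_id: str) -> tuple:
        out = []
        for pair in self.adjacency:
            if zone_id in pair:
                (other,) = set(pair) - {zone_id}
                out.append(other)
        return tuple(sorted(out))

    def precedence(self) -> tuple:
        """Zones ordered deepest-first, config order within a depth."""
        order = {z.zone_id: i for i, z in enumerate(self.zones)}
        return tuple(sorted(self.zone_ids,
                            key=lambda zid: (-self.depth(zid), order[zid])))

    # -- point location ---------------------------------------------------
    def locate(self, x: float, y: float) -> str:
        if not (math.isfinite(x) and math.isfinite(y)):
            return UNASSIGNED
        for zid in self.precedence():
            if self.zone(zid).geometry.contains(x, y):
                return zid
        return UNASSIGNED

    def locate_array(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized zone assignment; returns int codes into ``zone_ids``,
        -1 for unassigned/non-finite."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        code = {zid: i for i, zid in enumerate(self.zone_ids)}
        out = np.full(x.shape, -1, dtype=np.int64)
        undecided = np.isfinite(x) & np.isfinite(y)
        for zid in self.precedence():
            if not undecided.any():
                break
            mask = undecided & self.zone(zid).geometry.contains(x, y)
            out[mask] = code[zid]
            undecided &= ~mask
        return out

    # -- serialization ----------------------------------------------------
    def to_dict(self):
        return {
            "version": self.version,
            "arena_size": list(self.arena_size),
            "session_duration": self.session_duration,
            "zones": [z.to_dict() for z in self.zones],
            "adjacency": sorted(sorted(p) for p in self.adjacency),
            "aggregates": {k: list(v) for k, v in self.aggregates.items()},
        }

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# validation and loading

def _validate(cfg: ArenaConfig) -> None:
    problems = []
    ids = [z.zone_id for z in cfg.zones]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        problems.append(f"duplicate zone_id(s): {dupes}")
    w, h = cfg.arena_size
    if not (w > 0 and h > 0):
        problems.append("arena_size must be positive")
    if not cfg.session_duration > 0:
        problems.append("session_duration must be > 0")
    bounds = box(0, 0, w, h)
    shapes = {}
    for z in cfg.zones:
        shapes[z.zone_id] = z.geometry.as_shapely()
        if not bounds.buffer(1e-9).covers(shapes[z.zone_id]):
            problems.append(f"zone {z.zone_id!r} extends outside arena bounds")
        bad_tags = set(z.role_tags) - _ROLE_TAGS
        if bad_tags:
            problems.append(f"zone {z.zone_id!r} has unknown role tags {sorted(bad_tags)}")
        if {"risk", "shelter"} <= set(z.role_tags):
            problems.append(f"zone {z.zone_id!r} tagged both risk and shelter")
        if z.parent_zone:
            if z.parent_zone not in ids:
                problems.append(f"zone {z.zone_id!r} has unknown parent {z.parent_zone!r}")
            else:
                parent = next(s for s in cfg.zones if s.zone_id == z.parent_zone)
                if not parent.geometry.as_shapely().buffer(1e-9).covers(shapes[z.zone_id]):
                    problems.append(
                        f"zone {z.zone_id!r} is not contained in parent {z.parent_zone!r}")
    for pair in cfg.adjacency:
        for zid in pair:
            if zid not in ids:
                problems.append(f"adjacency references unknown zone {zid!r}")
        if len(pair) != 2:
            problems.append(f"adjacency pair {sorted(pair)} is not a pair of distinct zones")
    for name, members in cfg.aggregates.items():
        for zid in members:
            if zid not in ids:
                problems.append(f"aggregate {name!r} references unknown zone {zid!r}")
    # shelter access: a shelter zone must have exactly one non-shelter
    # neighbor (in the MCSF the corridor A is the only access to the DCR)
    for z in cfg.zones:
        if "shelter" in z.role_tags:
            nb = [n for n in cfg.neighbors(z.zone_id)
                  if "shelter" not in cfg.zone(n).role_tags]
            if len(nb) != 1:
                problems.append(
                    f"shelter zone {z.zone_id!r} must have exactly one "
                    f"non-shelter neighbor (found {nb})")
    if problems:
        raise ConfigError("invalid arena config:\n  - " + "\n  - ".join(problems))


def arena_from_dict(raw: Mapping) -> ArenaConfig:
    if not isinstance(raw, Mapping):
        raise FormatError("arena config must be a mapping")
    for key in ("arena_size", "zones", "session_duration"):
        if key not in raw:
            raise FormatError(f"arena config missing required key {key!r}")
    try:
        size = tuple(float(v) for v in raw["arena_size"])
    except (TypeError, ValueError) as exc:
        raise FormatError(f"bad 'arena_size': {exc}") from exc
    zones = []
    for i, zraw in enumerate(raw["zones"]):
        if "zone_id" not in zraw:
            raise FormatError(f"zones[{i}] missing 'zone_id'")
        zid = str(zraw["zone_id"])
        geom = _parse_geometry(zraw.get("geometry"), f"zone {zid!r}")
        lux = zraw.get("light_lux")
        zones.append(ZoneDef(
            zone_id=zid,
            display_name=str(zraw.get("display_name", zid)),
            geometry=geom,
            parent_zone=zraw.get("parent_zone"),
            light_lux=tuple(float(v) for v in lux) if lux is not None else None,
            role_tags=frozenset(zraw.get("role_tags", ())),
        ))
    adjacency = frozenset(frozenset(map(str, pair)) for pair in raw.get("adjacency", ()))
    aggregates = {str(k): tuple(map(str, v))
                  for k, v in (raw.get("aggregates") or {}).items()}
    cfg = ArenaConfig(
        arena_size=size,
        zones=tuple(zones),
        adjacency=adjacency,
        session_duration=float(raw["session_duration"]),
        aggregates=aggregates,
        version=int(raw.get("version", 1)),
    )
    _validate(cfg)
    return cfg


def load_arena_config(path=None) -> ArenaConfig:
    """Load and validate an arena config; ``None`` loads the bundled default."""
    if path is None:
        text = resources.files("mcsf.data").joinpath("mcsf_default.yaml").read_text()
    else:
        text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FormatError(f"could not parse arena config: {exc}") from exc
    return arena_from_dict(raw)


def locate_zone(point: Sequence[float], arena: ArenaConfig) -> str:
    """Map an (x, y) coordinate in cm to the deepest containing zone id,
    or ``"unassigned"`` for points in no zone (including out-of-arena)."""
    x, y = point
    return arena.locate(float(x), float(y))
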