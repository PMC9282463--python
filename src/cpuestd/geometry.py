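"""Synthetic study-area geometry.

The survey domain is an analytic stand-in for a deep-shelf fishing ground
with a small number of muddy depressions ("pits"): a bounding polygon in
decimal degrees, a smooth positive depth surface built as a base shelf depth
plus Gaussian-bump depressions, a meridian splitting the domain into a
western and an eastern side, and three nested management zones (A: ban,
B and C: buffers) centred on the deepest pit.  Only the depth-CPUE
relationship matters downstream, so cartographic realism is not attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon, box, mapping


@dataclass(frozen=True)
class Pit:
    """One Gaussian depression of the depth surface.

    ``amplitude`` is the extra depth (m) at the pit centre; ``sigma_lon`` /
    ``sigma_lat`` control its horizontal extent in degrees.
    """

    lon: float
    lat: float
    amplitude: float
    sigma_lon: float = 0.12
    sigma_lat: float = 0.08


@dataclass(frozen=True)
class GeometryConfig:
    lon_min: float = 14.7
    lon_max: float = 16.1
    lat_min: float = 42.7
    lat_max: float = 43.6
    base_depth: float = 130.0
    max_depth: float = 270.0
    split_lon: float = 15.4
    pits: tuple[Pit, ...] = (
        Pit(15.12, 43.17, 138.0, 0.16, 0.11),   # deepest pit, ~max_depth
        Pit(15.55, 43.05, 110.0, 0.13, 0.09),
        Pit(14.95, 42.95, 80.0, 0.11, 0.08),
    )
    # radii (degrees) of the ban zone and the two buffer rings around the
    # deepest pit centre
    zone_a_radius: float = 0.14
    zone_b_radius: float = 0.24
    zone_c_radius: float = 0.34


class StudyGeometry:
    """Bounding polygon, analytic depth surface, split line and zones A/B/C."""

    def __init__(self, config: GeometryConfig, polygon: Polygon,
                 zones: dict[str, Polygon]):
        self.config = config
        self.polygon = polygon
        self.zones = zones
        self.split_lon = config.split_lon

    # -- depth surface -------------------------------------------------
    def depth(self, lon, lat):
        """Depth (m, positive down) of the analytic surface."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        d = np.full(np.broadcast(lon, lat).shape, self.config.base_depth)
        for p in self.config.pits:
            d = d + p.amplitude * np.exp(
                -0.5 * (((lon - p.lon) / p.sigma_lon) ** 2
                        + ((lat - p.lat) / p.sigma_lat) ** 2))
        return d

    def contains(self, lon: float, lat: float) -> bool:
        return self.polygon.covers(Point(lon, lat))

    def is_western(self, lon) -> np.ndarray:
        return np.asarray(lon, dtype=float) < self.split_lon

    def zone_of(self, lon: float, lat: float) -> str | None:
        """Zone id ('A', 'B' or 'C') of a point, or None if outside all zones."""
        pt = Point(lon, lat)
        for name in ("A", "B", "C"):
            if self.zones[name].covers(pt):
                return name
        return None

    # -- serialization -------------------------------------------------
    def to_geojson(self) -> dict:
        feats = [{"type": "Feature",
                  "properties": {"name": "study_area"},
                  "geometry": mapping(self.polygon)}]
        for name, poly in self.zones.items():
            feats.append({"type": "Feature",
                          "properties": {"name": f"zone_{name}"},
                          "geometry": mapping(poly)})
        return {"type": "FeatureCollection", "features": feats}

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)


def make_study_geometry(config: GeometryConfig | None = None) -> StudyGeometry:
    """Build the synthetic study area from its configuration.

    Raises ``ValueError`` if the bounding box is empty or if the analytic
    surface exceeds ``config.max_depth`` anywhere on a fine lattice.
    """
    config = config or GeometryConfig()
    if config.lon_max <= config.lon_min or config.lat_max <= config.lat_min:
        raise ValueError("empty bounding polygon")
    polygon = box(config.lon_min, config.lat_min, config.lon_max, config.lat_max)

    geom = StudyGeometry(config, polygon, zones={})

    # validate the depth surface against the configured maximum
    lon = np.linspace(config.lon_min, config.lon_max, 200)
    lat = np.linspace(config.lat_min, config.lat_max, 200)
    LON, LAT = np.meshgrid(lon, lat)
    dmax = float(geom.depth(LON, LAT).max())
    if dmax > config.max_depth + 1e-9:
        raise ValueError(
            f"depth surface reaches {dmax:.1f} m, exceeding the configured "
            f"maximum of {config.max_depth:.1f} m")

    # zones: disc A around the deepest pit, annuli B and C outside it,
    # all clipped to the study polygon
    if config.pits:
        deepest = max(config.pits, key=lambda p: p.amplitude)
        centre = Point(deepest.lon, deepest.lat)
    else:
        centre = polygon.centroid
    disc_a = centre.buffer(config.zone_a_radius, quad_segs=32)
    disc_b = centre.buffer(config.zone_b_radius, quad_segs=32)
    disc_c = centre.buffer(config.zone_c_radius, quad_segs=32)
    zones = {
        "A": disc_a.intersection(polygon),
        "B": disc_b.difference(disc_a).intersection(polygon),
        "C": disc_c.difference(disc_b).intersection(polygon),
    }
    geom.zones = zones
    return geom
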