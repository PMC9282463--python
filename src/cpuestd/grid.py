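"""Informed prediction grid and standardized indices.

The study area is tessellated into constant-area square cells (default
2 x 2 nautical miles) in a local Lambert azimuthal equal-area frame
centred on the polygon centroid — "2 x 2 nm" is an area statement, and
plain latitude/longitude squares are not equal-area.  Each cell carries
its centre coordinates, mean depth (by quadrature over the analytic
surface), the fishery-management level of its centre at a per-survey
reference date, kriged environmental values per survey/year, and domain
membership (autumn surveys cover only the western side).

Predictions are made per cell at sunrise (standardizing the daily
temporal domain) and averaged arithmetically over the in-domain cells;
the index standard error combines the per-cell delta-method standard
errors under an independence approximation, SE = sqrt(sum SE_i^2) / n.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping

from . import kriging
from .environment import PARAMS, EnvField
from .gam import predict

NM_TO_KM = 1.852
EARTH_RADIUS_KM = 6371.0088

#: reference dates for resolving management levels on the grid
SURVEY_REFERENCE = {"spring": (5, 1), "autumn": (10, 1)}
#: representative week used when a model includes the week covariate
SURVEY_MID_WEEK = {"spring": 18, "autumn": 41}


class LocalEqualArea:
    """Spherical Lambert azimuthal equal-area projection (km)."""

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = np.radians(lon0)
        self.lat0 = np.radians(lat0)

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float)) - self.lon0
        phi = np.radians(np.asarray(lat, dtype=float))
        s0, c0 = np.sin(self.lat0), np.cos(self.lat0)
        kp = np.sqrt(2.0 / (1.0 + s0 * np.sin(phi)
                            + c0 * np.cos(phi) * np.cos(lam)))
        x = EARTH_RADIUS_KM * kp * np.cos(phi) * np.sin(lam)
        y = EARTH_RADIUS_KM * kp * (c0 * np.sin(phi)
                                    - s0 * np.cos(phi) * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        rho = np.sqrt(x ** 2 + y ** 2)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        s0, c0 = np.sin(self.lat0), np.cos(self.lat0)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(
                rho > 0,
                np.arcsin(np.clip(np.cos(c) * s0
                                  + y * np.sin(c) * c0 / np.where(rho > 0, rho, 1.0),
                                  -1.0, 1.0)),
                self.lat0)
            lam = np.where(
                rho > 0,
                np.arctan2(x * np.sin(c),
                           rho * c0 * np.cos(c) - y * s0 * np.sin(c)),
                0.0)
        return np.degrees(self.lon0 + lam), np.degrees(phi)


@dataclass
class GridCell:
    cell_id: int
    lon: float                  # centre, decimal degrees
    lat: float
    polygon: Polygon            # in decimal degrees
    area_nm2: float             # nominal constant cell area
    clipped_area_nm2: float     # area of cell intersected with the domain
    western: bool
    mean_depth: float = np.nan


def build_grid(geometry, cell_size_nm: float = 2.0) -> list[GridCell]:
    """Tessellate the study polygon into equal-area square cells."""
    if cell_size_nm <= 0:
        raise ValueError("cell size must be positive")
    cen = geometry.polygon.centroid
    proj = LocalEqualArea(cen.x, cen.y)
    # project the polygon boundary
    bx, by = geometry.polygon.exterior.xy
    px, py = proj.forward(np.asarray(bx), np.asarray(by))
    poly_xy = Polygon(zip(px, py))
    size = cell_size_nm * NM_TO_KM
    x0, y0, x1, y1 = poly_xy.bounds
    nx = int(np.ceil((x1 - x0) / size))
    ny = int(np.ceil((y1 - y0) / size))
    cells = []
    cid = 0
    for iy in range(ny):
        for ix in range(nx):
            cx0, cy0 = x0 + ix * size, y0 + iy * size
            sq = Polygon([(cx0, cy0), (cx0 + size, cy0),
                          (cx0 + size, cy0 + size), (cx0, cy0 + size)])
            inter = sq.intersection(poly_xy)
            # discard empty and numerical-sliver intersections
            if inter.is_empty or inter.area < 1e-9 * sq.area:
                continue
            ccx, ccy = cx0 + size / 2.0, cy0 + size / 2.0
            lon_c, lat_c = proj.inverse(ccx, ccy)
            xs, ys = sq.exterior.xy
            lons, lats = proj.inverse(np.asarray(xs), np.asarray(ys))
            cells.append(GridCell(
                cell_id=cid,
                lon=float(lon_c), lat=float(lat_c),
                polygon=Polygon(zip(lons, lats)),
                area_nm2=cell_size_nm ** 2,
                clipped_area_nm2=float(inter.area / NM_TO_KM ** 2),
                western=bool(float(lon_c) < geometry.split_lon)))
            cid += 1
    return cells


def cell_mean_depth(geometry, cell: GridCell, n: int = 6) -> float:
    """Mean depth of a cell by quadrature over the analytic surface,
    restricted to points inside the study polygon."""
    lon0, lat0, lon1, lat1 = cell.polygon.bounds
    gl = np.linspace(lon0, lon1, n + 2)[1:-1]
    gt = np.linspace(lat0, lat1, n + 2)[1:-1]
    LON, LAT = np.meshgrid(gl, gt)
    from shapely.geometry import Point
    inside = np.array([geometry.polygon.covers(Point(lo, la))
                       for lo, la in zip(LON.ravel(), LAT.ravel())])
    lons, lats = LON.ravel()[inside], LAT.ravel()[inside]
    if lons.size == 0:
        lons, lats = np.array([cell.lon]), np.array([cell.lat])
    return float(np.mean(geometry.depth(lons, lats)))


def assign_cell_attributes(cells: list[GridCell], geometry, timeline,
                           survey: str, year: int) -> pd.DataFrame:
    """Informed grid rows for one survey/year (no environment yet).

    Mean depth is by quadrature; the fishery level is resolved at the
    cell centre on the survey's reference date (default Y outside all
    zones); the autumn domain is restricted to western cells.
    """
    month, day = SURVEY_REFERENCE[survey]
    when = date(int(year), month, day)
    rows = []
    for c in cells:
        if np.isnan(c.mean_depth):
            c.mean_depth = cell_mean_depth(geometry, c)
        level = timeline.resolve(when, c.lon, c.lat, geometry)
        in_domain = c.western if survey == "autumn" else True
        rows.append({
            "cell_id": c.cell_id, "lon": c.lon, "lat": c.lat,
            "depth": c.mean_depth, "fishery": level,
            "western": c.western, "in_domain": in_domain,
            "survey": survey, "year": int(year),
            "week": SURVEY_MID_WEEK[survey],
        })
    return pd.DataFrame(rows)


def krige_environment(stations: pd.DataFrame, cells: list[GridCell],
                      param: str, geometry,
                      nugget: float = 0.0) -> np.ndarray:
    """Per-cell values of one environmental parameter by ordinary kriging
    of the station table (variogram fitted to the stations)."""
    if stations[["lon", "lat"]].duplicated().any():
        stations = stations.copy()  # duplicates handled inside kriging
    cen = geometry.polygon.centroid
    proj = LocalEqualArea(cen.x, cen.y)
    sx, sy = proj.forward(stations["lon"].to_numpy(),
                          stations["lat"].to_numpy())
    tx, ty = proj.forward(np.array([c.lon for c in cells]),
                          np.array([c.lat for c in cells]))
    vals, _vg = kriging.krige_field(
        np.column_stack([sx, sy]), stations[param].to_numpy(dtype=float),
        np.column_stack([tx, ty]), nugget=nugget)
    return vals


def proxy_fill(env_fields: dict, required: list[tuple],
               params: tuple = PARAMS) -> dict:
    """Complete the (survey, year) -> EnvField map by donor proxying.

    A missing parameter layer borrows the same season's nearest following
    year that has it (e.g. a spring with no oxygen data uses the next
    spring's oxygen field; a cancelled spring borrows everything from the
    next spring).  Observed layers are never overwritten; filled layers
    carry provenance in ``EnvField.proxy_of``.  Raises ``KeyError``
    listing the gap when no donor exists.
    """
    out = dict(env_fields)
    for survey, year in required:
        have = out.get((survey, year))
        missing = [p for p in params
                   if have is None or not have.has(p)]
        if not missing:
            continue
        surfaces = dict(have.surfaces) if have is not None else {}
        stations = have.stations if have is not None else None
        proxy_of = dict(have.proxy_of) if have is not None else {}
        for p in missing:
            donor = None
            for dy in sorted(y2 for (s2, y2) in env_fields
                             if s2 == survey and y2 > year):
                cand = env_fields[(survey, dy)]
                if cand.has(p) and p not in cand.proxy_of:
                    donor = cand
                    break
            if donor is None:
                raise KeyError(
                    f"no donor layer for ({survey}, {year}, {p})")
            surfaces[p] = donor.surfaces[p]
            proxy_of[p] = (donor.survey, donor.year)
            if stations is None:
                stations = donor.stations.copy()
        out[(survey, year)] = EnvField(survey, year, surfaces,
                                       stations if stations is not None
                                       else pd.DataFrame(),
                                       proxy_of=proxy_of)
    return out


def standardized_index(fitted, informed_grid: pd.DataFrame,
                       tod: str = "sunrise") -> dict:
    """Mean per-cell prediction over the in-domain cells, with an SE.

    The index is the arithmetic mean of per-cell response-scale
    predictions at the standardizing time-of-day; its standard error is
    sqrt(sum SE_i^2)/n over cells (independence approximation on the
    delta-method per-cell SEs).
    """
    rows = informed_grid[informed_grid["in_domain"]].copy()
    if len(rows) == 0:
        raise ValueError("no in-domain cells")
    needed = [s.covariate for s in fitted.spec.smooths]
    needed += [s.by for s in fitted.spec.smooths if s.by]
    needed += list(fitted.spec.factors)
    needed = [c for c in dict.fromkeys(needed) if c != "tod"]
    for c in needed:
        if c not in rows.columns:
            raise ValueError(f"grid attribute {c!r} missing for all cells")
        if rows[c].isna().any():
            bad = rows.loc[rows[c].isna(), "cell_id"].iloc[0]
            raise ValueError(
                f"grid attribute {c!r} missing (cell {bad})")
    rows["tod"] = tod
    mu, se = predict(fitted, rows, with_se=True)
    n = len(rows)
    return {
        "survey": rows["survey"].iloc[0],
        "year": int(rows["year"].iloc[0]),
        "response": fitted.spec.response,
        "mean": float(np.mean(mu)),
        "se": float(np.sqrt(np.sum(se ** 2)) / n),
        "n_cells": int(n),
        "cell_mean": mu,
        "cell_se": se,
        "cell_id": rows["cell_id"].to_numpy(),
    }


def compare_observed_predicted(observed: float, index_mean: float,
                               denominator: str = "predicted") -> float:
    """Signed percent difference between a standardized index and the
    observed mean CPUE; by default as a percentage of the predicted value."""
    if index_mean <= 0:
        raise ValueError("index mean must be positive")
    den = index_mean if denominator == "predicted" else observed
    return 100.0 * (index_mean - observed) / den


def grid_to_geojson(cells: list[GridCell], informed: pd.DataFrame | None = None
                    ) -> dict:
    feats = []
    attrs = (informed.set_index("cell_id").to_dict("index")
             if informed is not None else {})
    for c in cells:
        props = {"cell_id": c.cell_id, "lon": c.lon, "lat": c.lat,
                 "area_nm2": c.area_nm2, "mean_depth": c.mean_depth,
                 "western": c.western}
        extra = attrs.get(c.cell_id, {})
        props.update({k: v for k, v in extra.items()
                      if isinstance(v, (int, float, str, bool))})
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(c.polygon)})
    return {"type": "FeatureCollection", "features": feats}


def render_prediction_map(cells: list[GridCell], informed: pd.DataFrame,
                          column: str, path, title: str | None = None
                          ) -> None:
    """Render one per-cell attribute (e.g. a predicted index) to an image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import Polygon as MplPolygon

    vals = informed.set_index("cell_id")[column]
    patches, colors = [], []
    for c in cells:
        if c.cell_id not in vals.index:
            continue
        xy = np.asarray(c.polygon.exterior.coords)
        patches.append(MplPolygon(xy, closed=True))
        colors.append(vals.loc[c.cell_id])
    fig, ax = plt.subplots(figsize=(7, 5))
    pc = PatchCollection(patches, cmap="viridis")
    pc.set_array(np.asarray(colors, dtype=float))
    ax.add_collection(pc)
    ax.autoscale_view()
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title(title or column)
    fig.colorbar(pc, ax=ax, label=column)
    fig.savefig(path, dpi=120)
    plt.close(fig)
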