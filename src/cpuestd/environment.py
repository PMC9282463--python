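"""Synthetic bottom-environment fields (BT, Sal, Oxy) and CTD station tables.

Each parameter surface is a deterministic smooth trend (spatial gradients,
seasonal and annual offsets, an optional depth association) plus a
spatially correlated stochastic component with an exponential (Matérn-1/2)
variogram.  The correlated component is realised by random Fourier
features, which gives a single consistent callable surface at arbitrary
query points: frequencies are drawn from the spectral density of the
exponential kernel in two dimensions (a bivariate Student-t with one
degree of freedom), so the feature expansion has the target covariance
``sill * exp(-r / range)`` in expectation.

Oxygen is expressed as % saturation and kept within a configured band so
that documented low-oxygen scenarios (down to hypoxic, < 40 %) can be
emulated on either side of the behaviourally relevant 85 % mark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PARAMS = ("BT", "Sal", "Oxy")


@dataclass(frozen=True)
class ParamTrend:
    """Deterministic trend of one environmental parameter."""

    base: float
    autumn_offset: float = 0.0
    year_slope: float = 0.0          # per year, centred on year_ref
    year_offsets: dict = field(default_factory=dict)
    grad_lon: float = 0.0            # per degree longitude
    grad_lat: float = 0.0            # per degree latitude
    depth_coef: float = 0.0          # per 100 m of extra depth over the shelf
    sill: float = 0.0                # variance of the correlated noise
    vrange: float = 0.15             # exponential variogram range (degrees)
    year_ref: int = 2015


@dataclass(frozen=True)
class EnvConfig:
    trends: dict = field(default_factory=lambda: {
        # bottom temperature, deg C
        "BT": ParamTrend(base=11.6, autumn_offset=0.6, grad_lat=-0.3,
                         sill=0.36, vrange=0.18),
        # bottom salinity, PSU
        "Sal": ParamTrend(base=38.55, autumn_offset=0.05, year_slope=0.01,
                          grad_lon=0.04, sill=0.02, vrange=0.20),
        # bottom dissolved-oxygen saturation, %
        # 2012 carries a positive offset emulating a dense-water renewal
        "Oxy": ParamTrend(base=82.0, autumn_offset=-3.0, depth_coef=-4.0,
                          year_offsets={2012: 9.0}, grad_lat=1.5,
                          sill=12.0, vrange=0.22),
    })
    oxy_min: float = 40.0
    oxy_max: float = 120.0
    n_fourier_features: int = 600


class _GaussianFieldRFF:
    """Stationary Gaussian field with covariance sill*exp(-r/range),
    realised by random Fourier features (consistent at any query point)."""

    def __init__(self, sill: float, vrange: float, rng: np.random.Generator,
                 n_features: int = 600):
        self.sill = sill
        m = n_features
        z = rng.standard_normal((m, 2))
        g = rng.chisquare(1, size=m)
        g = np.maximum(g, 1e-12)
        self.freq = z / (vrange * np.sqrt(g)[:, None])
        self.phase = rng.uniform(0.0, 2.0 * np.pi, size=m)
        self.amp = np.sqrt(2.0 * sill / m)

    def __call__(self, lon, lat):
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        shape = np.broadcast(lon, lat).shape
        pts = np.column_stack([np.broadcast_to(lon, shape).ravel(),
                               np.broadcast_to(lat, shape).ravel()])
        vals = self.amp * np.cos(pts @ self.freq.T + self.phase).sum(axis=1)
        return vals.reshape(shape)


class EnvField:
    """Callable surfaces and a sampled station table for one survey/year.

    Parameters may be missing (e.g. oxygen never measured in one survey);
    ``proxy_of`` records, per parameter, the (survey, year) donor layer a
    value was proxy-filled from, so observed layers are never silently
    overwritten.
    """

    def __init__(self, survey: str, year: int, surfaces: dict,
                 stations: pd.DataFrame, proxy_of: dict | None = None):
        self.survey = survey
        self.year = year
        self.surfaces = surfaces
        self.stations = stations
        #: param -> (survey, year) donor, for proxy-filled parameters only
        self.proxy_of = dict(proxy_of or {})

    @property
    def params(self) -> tuple:
        return tuple(sorted(self.surfaces))

    def has(self, param: str) -> bool:
        return param in self.surfaces

    def value(self, param: str, lon, lat):
        if param not in self.surfaces:
            raise KeyError(
                f"parameter {param!r} missing for {self.survey} {self.year}")
        return self.surfaces[param](lon, lat)

    def drop_param(self, param: str) -> None:
        self.surfaces.pop(param, None)
        if param in self.stations.columns:
            self.stations = self.stations.drop(columns=[param])


def trend_value(trend: ParamTrend, geometry, survey: str, year: int,
                lon, lat, clip: tuple | None = None):
    """Deterministic trend surface of one parameter."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    v = (trend.base
         + (trend.autumn_offset if survey == "autumn" else 0.0)
         + trend.year_slope * (year - trend.year_ref)
         + trend.year_offsets.get(year, 0.0)
         + trend.grad_lon * (lon - geometry.polygon.centroid.x)
         + trend.grad_lat * (lat - geometry.polygon.centroid.y)
         + trend.depth_coef
         * (geometry.depth(lon, lat) - geometry.config.base_depth) / 100.0)
    if clip is not None:
        v = np.clip(v, *clip)
    return v


def random_points_in_polygon(geometry, n: int, rng: np.random.Generator,
                             depth_band: tuple | None = None,
                             within=None) -> np.ndarray:
    """Uniform rejection sampling of n (lon, lat) points inside the polygon
    (optionally inside a sub-region), restricted to a depth band."""
    region = geometry.polygon if within is None else within
    lon_min, lat_min, lon_max, lat_max = region.bounds
    out = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 200_000:
            raise RuntimeError("eligible sampling region appears empty")
        lon = rng.uniform(lon_min, lon_max)
        lat = rng.uniform(lat_min, lat_max)
        if within is not None:
            from shapely.geometry import Point
            if not region.covers(Point(lon, lat)):
                continue
        elif not geometry.contains(lon, lat):
            continue
        if depth_band is not None:
            d = float(geometry.depth(lon, lat))
            if not (depth_band[0] <= d <= depth_band[1]):
                continue
        out.append((lon, lat))
    return np.array(out)


def sample_environment(geometry, survey: str, year: int, n_stations: int = 20,
                       noise: float = 1.0, seed: int = 0,
                       config: EnvConfig | None = None) -> EnvField:
    """Generate the environmental field and CTD-like station table.

    ``noise`` scales the variogram sill of the correlated component
    (0 gives the pure trend).  Reproducible under ``seed``.
    """
    if n_stations < 4:
        raise ValueError("n_stations must be >= 4")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    config = config or EnvConfig()
    rng = np.random.default_rng(seed)

    surfaces = {}
    for param in PARAMS:
        trend = config.trends[param]
        fluct = None
        if noise > 0 and trend.sill > 0:
            fluct = _GaussianFieldRFF(noise * trend.sill, trend.vrange, rng,
                                      config.n_fourier_features)
        clip = (config.oxy_min, config.oxy_max) if param == "Oxy" else None

        def surface(lon, lat, _t=trend, _f=fluct, _c=clip):
            v = trend_value(_t, geometry, survey, year, lon, lat)
            if _f is not None:
                v = v + _f(lon, lat)
            if _c is not None:
                v = np.clip(v, *_c)
            return v

        surfaces[param] = surface

    pts = random_points_in_polygon(geometry, n_stations, rng)
    stations = pd.DataFrame({"lon": pts[:, 0], "lat": pts[:, 1]})
    for param in PARAMS:
        stations[param] = surfaces[param](pts[:, 0], pts[:, 1])
    return EnvField(survey, year, surfaces, stations)
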