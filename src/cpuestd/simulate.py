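"""Haul-level survey simulator.

Hauls are placed uniformly over the in-polygon region with bottom depth in
the trawlable 100-270 m band, assigned a sunrise/sunset time-of-day, a week
number inside the survey season window (spring: April-May, autumn:
September-November), and environmental values read off the survey/year
environmental field at the haul position.  Biomass and density CPUE are
drawn from Gamma distributions with mean exp(eta) given by the generating
effects; catch weight and count are then back-computed from a drawn swept
area.  The catch count is stored as a float: survey counts are routinely
raised by catch-subsampling factors and need not be integers, and this
keeps count / swept_area an exact inverse of the draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .effects import TrueEffects
from .environment import EnvConfig, random_points_in_polygon, sample_environment

DEPTH_BAND = (100.0, 270.0)
SEASON_WEEKS = {"spring": (14, 22), "autumn": (36, 48)}


@dataclass(frozen=True)
class SurveyPlan:
    """Which survey/year combinations to generate and at what effort.

    The default effort mirrors the real two-series design: 56 modelled
    spring hauls (2013-2019, no 2018) plus 36 autumn hauls (2015-2019),
    with spring 2018 generated-then-withheld (cancelled survey) and spring
    2012 lacking oxygen measurements (so its hauls drop in filtering).
    """

    spring_years: tuple = (2012, 2013, 2014, 2015, 2016, 2017, 2018, 2019)
    autumn_years: tuple = (2015, 2016, 2017, 2018, 2019)
    hauls_per_spring: int | dict = field(default_factory=lambda: {
        2012: 10, 2013: 9, 2014: 9, 2015: 9, 2016: 10, 2017: 9,
        2018: 10, 2019: 10})
    hauls_per_autumn: int | dict = field(default_factory=lambda: {
        2015: 7, 2016: 7, 2017: 8, 2018: 7, 2019: 7})
    #: spring 2018 is generated and then withheld (cancelled survey)
    withheld: tuple = (("spring", 2018),)
    #: spring 2012 hauls lack oxygen-saturation measurements
    oxy_missing: tuple = (("spring", 2012),)
    n_stations: int = 20
    env_noise: float = 1.0

    def combos(self):
        for y in self.spring_years:
            yield ("spring", y)
        for y in self.autumn_years:
            yield ("autumn", y)

    def n_hauls(self, survey: str, year: int) -> int:
        per = (self.hauls_per_spring if survey == "spring"
               else self.hauls_per_autumn)
        return per[year] if isinstance(per, dict) else int(per)


def week_to_date(year: int, week: int) -> date:
    """Mid-week calendar date of an ISO-like week number."""
    return date(year, 1, 1) + timedelta(days=7 * (int(week) - 1) + 3)


#: default share of hauls allocated to each management zone (None = rest of
#: the domain); the survey designs allocate effort across regimes, so the
#: ban and buffer zones are deliberately represented
ZONE_WEIGHTS = {"A": 0.25, "B": 0.2, "C": 0.15, None: 0.4}


def simulate_hauls(geometry, env, timeline, effects: TrueEffects,
                   n_hauls: int, survey: str, year: int, seed: int = 0,
                   season_weeks: dict | None = None,
                   zone_weights: dict | str = "default") -> pd.DataFrame:
    """Simulate one survey's haul records for one year.

    Haul positions are allocated across the management zones with
    ``zone_weights`` (pass ``None`` for fully uniform placement) and drawn
    uniformly within each zone, restricted to the trawlable depth band.
    Returns a table with one row per haul: covariates, catch weight (kg),
    catch count, swept area (km^2) and resolved fishery level.
    """
    if n_hauls < 1:
        raise ValueError("n_hauls must be >= 1")
    season_weeks = season_weeks or SEASON_WEEKS
    rng = np.random.default_rng(seed)

    if zone_weights == "default":
        zone_weights = ZONE_WEIGHTS
    if zone_weights is None:
        pts = random_points_in_polygon(geometry, n_hauls, rng,
                                       depth_band=DEPTH_BAND)
    else:
        zones = list(zone_weights)
        w = np.array([zone_weights[z] for z in zones], dtype=float)
        picks = rng.choice(len(zones), size=n_hauls, p=w / w.sum())
        chunks = []
        for i, z in enumerate(zones):
            m = int((picks == i).sum())
            if m == 0:
                continue
            within = geometry.zones[z] if z is not None else None
            chunks.append(random_points_in_polygon(
                geometry, m, rng, depth_band=DEPTH_BAND, within=within))
        pts = np.vstack(chunks)
        rng.shuffle(pts, axis=0)
    lon, lat = pts[:, 0], pts[:, 1]
    depth = geometry.depth(lon, lat)

    wlo, whi = season_weeks[survey]
    week = rng.integers(wlo, whi + 1, size=n_hauls)
    tod = rng.choice(["sunrise", "sunset"], size=n_hauls)
    dates = [week_to_date(year, w) for w in week]
    fishery = [timeline.resolve(d, x, y, geometry)
               for d, x, y in zip(dates, lon, lat)]

    bt = np.asarray(env.value("BT", lon, lat), dtype=float)
    sal = np.asarray(env.value("Sal", lon, lat), dtype=float)
    oxy = np.asarray(env.value("Oxy", lon, lat), dtype=float)

    swept = rng.uniform(0.05, 0.08, size=n_hauls)  # ~1 h tow, km^2

    shape = effects.gamma_shape
    eta_b = effects.linear_predictor("biomass", lat, depth, bt, oxy, sal,
                                     week, year, tod, fishery)
    eta_d = effects.linear_predictor("density", lat, depth, bt, oxy, sal,
                                     week, year, tod, fishery)
    cpue_b = rng.gamma(shape, np.exp(eta_b) / shape)
    cpue_d = rng.gamma(shape, np.exp(eta_d) / shape)

    return pd.DataFrame({
        "survey": survey,
        "year": int(year),
        "week": week.astype(int),
        "date": [d.isoformat() for d in dates],
        "tod": tod,
        "lon": lon,
        "lat": lat,
        "depth": depth,
        "BT": bt,
        "Sal": sal,
        "Oxy": oxy,
        "catch_weight": cpue_b * swept,
        "catch_count": cpue_d * swept,
        "swept_area": swept,
        "fishery": fishery,
    })


def simulate_survey_series(geometry, timeline, effects: TrueEffects,
                           plan: SurveyPlan | None = None, seed: int = 0,
                           env_config: EnvConfig | None = None):
    """Generate the full two-series synthetic dataset.

    Returns ``(hauls, env_fields)`` where ``hauls`` is the concatenated haul
    table (with the withheld survey removed and configured missingness
    applied) and ``env_fields`` maps (survey, year) to its environmental
    field.  Emulating the real archive, a withheld survey contributes no
    environmental layer and an oxygen-missing survey loses its Oxy layer
    (both are later proxy-filled on the prediction grid).  Sub-seeds for
    each survey/year are derived deterministically from ``seed``.
    """
    plan = plan or SurveyPlan()
    env_config = env_config or EnvConfig()
    rng = np.random.default_rng(seed)
    env_fields = {}
    tables = []
    for survey, year in plan.combos():
        env_seed = int(rng.integers(0, 2**31 - 1))
        haul_seed = int(rng.integers(0, 2**31 - 1))
        env = sample_environment(geometry, survey, year,
                                 n_stations=plan.n_stations,
                                 noise=plan.env_noise, seed=env_seed,
                                 config=env_config)
        tab = simulate_hauls(geometry, env, timeline, effects,
                             plan.n_hauls(survey, year),
                             survey, year, seed=haul_seed)
        if (survey, year) in plan.oxy_missing:
            tab["Oxy"] = np.nan
            env.drop_param("Oxy")
        if (survey, year) not in plan.withheld:
            tables.append(tab)
            env_fields[(survey, year)] = env
    hauls = pd.concat(tables, ignore_index=True)
    return hauls, env_fields
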