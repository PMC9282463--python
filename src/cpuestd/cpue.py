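"""CPUE indices and record filtering.

Biomass index = catch weight / swept area (kg/km^2); density index =
catch count / swept area (N/km^2).  Before modelling, haul records are
filtered once against the full candidate covariate set: a row is dropped
iff any modelled covariate is missing or either CPUE index equals zero
(the Gamma family has no support at zero).  Dropping a covariate from a
later candidate model never resurrects rows, because filtering is done
once against the full set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: covariates of the full candidate model, checked for missingness
MODEL_COVARIATES = ("survey", "year", "week", "tod", "lat", "lon", "depth",
                    "BT", "Sal", "Oxy", "fishery")


@dataclass
class FilterReport:
    """Row-removal bookkeeping: totals by reason and by survey/year."""

    n_input: int = 0
    n_retained: int = 0
    removed_missing_covariate: int = 0
    removed_zero_cpue: int = 0
    by_survey_year: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["by_survey_year"] = {f"{k[0]}_{k[1]}": v
                               for k, v in self.by_survey_year.items()}
        return json.dumps(d, indent=2)


def compute_indices(hauls: pd.DataFrame) -> pd.DataFrame:
    """Augment haul records with biomass and density CPUE, row order kept.

    Raises ``ValueError`` naming the offending haul if a swept area is not
    positive.
    """
    bad = ~(hauls["swept_area"] > 0)
    if bad.any():
        idx = hauls.index[bad][0]
        raise ValueError(f"non-positive swept area for haul {idx}")
    out = hauls.copy()
    out["biomass_index"] = out["catch_weight"] / out["swept_area"]
    out["density_index"] = out["catch_count"] / out["swept_area"]
    return out


def filter_records(table: pd.DataFrame,
                   covariates: tuple = MODEL_COVARIATES
                   ) -> tuple[pd.DataFrame, FilterReport]:
    """Drop rows with any missing modelled covariate or a zero CPUE.

    Returns the retained table (original order) and a ``FilterReport``.
    Idempotent: re-filtering a filtered table is the identity.
    """
    report = FilterReport(n_input=len(table))
    cols = [c for c in covariates if c in table.columns]
    missing = table[cols].isna().any(axis=1)
    zero = (table["biomass_index"] == 0) | (table["density_index"] == 0)

    report.removed_missing_covariate = int(missing.sum())
    # a row missing a covariate AND with a zero CPUE counts once, as missing
    report.removed_zero_cpue = int((zero & ~missing).sum())

    drop = missing | zero
    if "survey" in table.columns and "year" in table.columns:
        for (survey, year), grp in table[drop].groupby(["survey", "year"]):
            report.by_survey_year[(str(survey), int(year))] = len(grp)
    retained = table[~drop].copy()
    report.n_retained = len(retained)
    return retained, report


def summarize_indices(table: pd.DataFrame) -> dict:
    """Per-index maxima and means, as reported in survey summaries."""
    return {
        "max_biomass_index": float(table["biomass_index"].max()),
        "max_density_index": float(table["density_index"].max()),
        "mean_biomass_index": float(table["biomass_index"].mean()),
        "mean_density_index": float(table["density_index"].mean()),
        "n_hauls": int(len(table)),
    }
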