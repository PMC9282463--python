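"""End-to-end pipeline: generate -> filter -> select -> fit -> grid -> predict.

One flat configuration drives the whole cascade; both responses (biomass
and density) always run as paired analyses.  Every artifact lands in the
configured output directory and is listed, with a content hash, in
``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cpue import compute_indices, filter_records, summarize_indices
from .effects import TrueEffects
from .environment import PARAMS
from .gam import ModelSpec, fit_gam, summary_frames
from .geometry import GeometryConfig, make_study_geometry
from .grid import (assign_cell_attributes, build_grid, grid_to_geojson,
                   krige_environment, proxy_fill, standardized_index)
from .management import make_management_timeline
from .selection import (candidate_models, compare_models_aic,
                        repeated_kfold_cv, retention_rule, rmse_compare,
                        vif_backward)
from .simulate import SurveyPlan, simulate_survey_series

RESPONSES = ("biomass_index", "density_index")


class StageError(RuntimeError):
    """Failure of a named pipeline stage, with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "results/pipeline"
    cv_k: int = 10
    cv_repeats: int = 10
    alpha: float = 0.05
    retention_threshold: float = 0.80
    cell_size_nm: float = 2.0
    vif_threshold: float = 3.0
    make_maps: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__annotations__}
        return cls(**known)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _spec_from_retained(base: ModelSpec, retained: set[str]) -> ModelSpec:
    smooths = []
    for s in base.smooths:
        if s.by is None:
            if s.covariate in retained:
                smooths.append(s)
        else:
            if any(t.startswith(f"{s.covariate}:{s.by}") for t in retained):
                smooths.append(s)
    factors = []
    for f in base.factors:
        if any(t.startswith(f) and ":" not in t for t in retained):
            factors.append(f)
    return ModelSpec(base.response, smooths=tuple(smooths),
                     factors=tuple(factors))


def stage_simulate(cfg: PipelineConfig, out: Path):
    geometry = make_study_geometry(GeometryConfig())
    timeline = make_management_timeline()
    effects = TrueEffects()
    plan = SurveyPlan()
    hauls, env_fields = simulate_survey_series(
        geometry, timeline, effects, plan, seed=cfg.seed)
    table = compute_indices(hauls)
    _write_csv(table, out / "hauls.csv")
    stations = []
    for (survey, year), env in env_fields.items():
        st = env.stations.copy()
        st.insert(0, "survey", survey)
        st.insert(1, "year", year)
        stations.append(st)
    _write_csv(pd.concat(stations, ignore_index=True), out / "stations.csv")
    (out / "geometry.geojson").parent.mkdir(parents=True, exist_ok=True)
    geometry.write_geojson(out / "geometry.geojson")
    return geometry, timeline, effects, plan, table, env_fields


def stage_filter(table: pd.DataFrame, out: Path):
    filtered, report = filter_records(table)
    _write_csv(filtered, out / "hauls_filtered.csv")
    (out / "filter_report.json").write_text(report.to_json())
    _write_json(summarize_indices(filtered), out / "cpue_summary.json")
    return filtered, report


def stage_select(cfg: PipelineConfig, filtered: pd.DataFrame, out: Path):
    """VIF screen, candidate CV, AIC comparison, retention, RMSE contest."""
    continuous = ["lat", "lon", "depth", "BT", "Sal", "Oxy", "week", "year"]
    vif_retained, vif_trace = vif_backward(filtered, continuous,
                                           threshold=cfg.vif_threshold)
    _write_json({"retained": vif_retained, "trace": vif_trace},
                out / "vif_trace.json")

    rng = np.random.default_rng(cfg.seed + 1)
    results = {}
    for resp in RESPONSES:
        cands = candidate_models(resp)
        cv = {}
        for name, spec in cands.items():
            cv[name] = repeated_kfold_cv(
                spec, filtered, k=cfg.cv_k, repeats=cfg.cv_repeats,
                alpha=cfg.alpha, seed=int(rng.integers(0, 2**31 - 1)),
                candidate=name)
        comparison = compare_models_aic(cv, alpha=cfg.alpha, response=resp)
        winner = comparison.selected
        retained = retention_rule(cv[winner],
                                  threshold=cfg.retention_threshold)
        final_spec = _spec_from_retained(cands[winner], retained)
        contest = rmse_compare(cands["modINITIAL"], final_spec, filtered,
                               k=cfg.cv_k, repeats=cfg.cv_repeats,
                               seed=int(rng.integers(0, 2**31 - 1)))
        results[resp] = {
            "cv": cv, "comparison": comparison, "winner": winner,
            "retained": retained, "final_spec": final_spec,
            "rmse": contest,
        }
        tag = resp.split("_")[0]
        _write_json({
            "mean_aic": comparison.mean_aic,
            "levene": {"stat": comparison.levene_stat,
                       "p": comparison.levene_p,
                       "homoscedastic": comparison.homoscedastic},
            "anova": {"stat": comparison.anova_stat, "p": comparison.anova_p},
            "selected": winner,
            "rationale": comparison.rationale,
            "significance_counts": cv["modINITIAL"].pvalue_counts,
            "n_fits": cv["modINITIAL"].n_fits,
            "retained_terms": sorted(retained),
            "final_formula": final_spec.to_formula(),
            "rmse_initial_mean": contest["mean_a"],
            "rmse_final_mean": contest["mean_b"],
            "rmse_winner": "final" if contest["winner"] == "B" else "initial",
        }, out / f"selection_{tag}.json")
        if not comparison.pairwise.empty:
            _write_csv(comparison.pairwise, out / f"tukey_{tag}.csv")
    return results


def stage_fit(selection_results: dict, filtered: pd.DataFrame, out: Path):
    fits = {}
    for resp, res in selection_results.items():
        fit = fit_gam(res["final_spec"], filtered)
        fits[resp] = fit
        tag = resp.split("_")[0]
        par, smo = summary_frames(fit)
        _write_csv(par, out / f"final_parametric_{tag}.csv")
        _write_csv(smo, out / f"final_smooth_{tag}.csv")
        _write_json({
            "formula": fit.spec.to_formula(),
            "aic": fit.aic, "edf_total": fit.edf_total,
            "deviance_explained": fit.deviance_explained,
            "adj_r2": fit.adj_r2, "gamma_shape": fit.shape, "n": fit.n,
        }, out / f"final_fit_{tag}.json")
    return fits


def stage_predict(cfg: PipelineConfig, geometry, timeline, plan,
                  env_fields: dict, fits: dict, filtered: pd.DataFrame,
                  out: Path):
    cells = build_grid(geometry, cell_size_nm=cfg.cell_size_nm)
    combos = list(plan.combos())
    try:
        env_full = proxy_fill(env_fields, combos)
    except KeyError as e:
        raise StageError("predict", "E_KRIGE_INPUT", str(e))

    indices = []
    grids = {}
    for survey, year in combos:
        grid = assign_cell_attributes(cells, geometry, timeline, survey, year)
        env = env_full[(survey, year)]
        if env.stations.empty:
            raise StageError("predict", "E_KRIGE_INPUT",
                             f"no stations for {survey} {year}")
        for param in PARAMS:
            st = env.stations
            if param in st.columns and param not in env.proxy_of:
                grid[param] = krige_environment(st, cells, param, geometry)
            else:
                # proxy layer: evaluate the donor surface at cell centres
                grid[param] = env.value(param,
                                        grid["lon"].to_numpy(),
                                        grid["lat"].to_numpy())
            grid[f"{param}_proxy"] = param in env.proxy_of
        grids[(survey, year)] = grid
        for resp, fit in fits.items():
            idx = standardized_index(fit, grid, tod="sunrise")
            if cfg.make_maps:
                from .grid import render_prediction_map
                g = grid[grid["in_domain"]].copy()
                g["predicted"] = idx["cell_mean"]
                render_prediction_map(
                    cells, g, "predicted",
                    out / f"map_{resp.split('_')[0]}_{survey}_{year}.png",
                    title=f"{resp} {survey} {year}")
            obs = filtered[(filtered["survey"] == survey)
                           & (filtered["year"] == year)][resp]
            indices.append({
                "survey": survey, "year": year, "response": resp,
                "mean": idx["mean"], "se": idx["se"],
                "n_cells": idx["n_cells"],
                "observed_mean": float(obs.mean()) if len(obs) else np.nan,
                "n_hauls": int(len(obs)),
            })
    index_df = pd.DataFrame(indices)
    _write_csv(index_df, out / "standardized_indices.csv")
    some = next(iter(grids.values()))
    _write_json(grid_to_geojson(cells, some), out / "grid.geojson")
    for (survey, year), grid in grids.items():
        _write_csv(grid, out / f"grid_{survey}_{year}.csv")
    return index_df, grids


def _manifest(out: Path, cfg: PipelineConfig) -> None:
    entries = []
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries.append({
                "path": str(p.relative_to(out)),
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
                "bytes": p.stat().st_size,
            })
    _write_json({"version": __version__, "config": asdict(cfg),
                 "files": entries}, out / "manifest.json")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order and return the in-memory results bundle."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        geometry, timeline, effects, plan, table, env_fields = \
            stage_simulate(cfg, out)
    except ValueError as e:
        raise StageError("simulate", "E_VALIDATION", str(e))
    filtered, report = stage_filter(table, out)
    selection = stage_select(cfg, filtered, out)
    try:
        fits = stage_fit(selection, filtered, out)
    except RuntimeError as e:
        raise StageError("fit", "E_CONVERGENCE", str(e))
    index_df, grids = stage_predict(cfg, geometry, timeline, plan,
                                    env_fields, fits, filtered, out)
    _manifest(out, cfg)
    return {
        "geometry": geometry, "timeline": timeline, "plan": plan,
        "hauls": table, "filtered": filtered, "filter_report": report,
        "selection": selection, "fits": fits, "indices": index_df,
        "grids": grids,
    }
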