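"""Model/covariate selection cascade.

Stages, in pipeline order:

1. ``vif_backward`` — backward variance-inflation-factor screen on the
   continuous covariates (drop the worst until all VIF < 3).
2. ``candidate_models`` — the four candidate additive models: the full
   model with environmental and management terms (modINITIAL), the model
   with neither (modNOEM), environment-only removed (modNOE) and
   management-only removed (modNOM).
3. ``repeated_kfold_cv`` — k-fold cross validation repeated R times;
   each of the k*R training fits contributes an AIC value, per-term
   p-values and a held-out RMSE.
4. ``compare_models_aic`` — Levene's homogeneity test on the AIC
   distributions, one-way ANOVA + Tukey HSD under homoscedasticity
   (Welch ANOVA + Games-Howell otherwise), winner = the lowest-mean-AIC
   candidate if it beats every other pairwise, else the candidate with
   fewest covariates.
5. ``retention_rule`` — a term is kept iff it was significant (p < alpha)
   in at least a fraction ``threshold`` of the fits; a factor-by-smooth
   interaction is kept iff any of its level smooths passes, and the parent
   factor's intercepts are kept whenever the interaction is.
6. ``rmse_compare`` — head-to-head held-out RMSE of two specs on shared
   partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gam import ModelSpec, SmoothTerm, fit_gam, predict, term_pvalues

CANDIDATE_ORDER = ("modNOEM", "modNOE", "modNOM", "modINITIAL")


def rmse(errors) -> float:
    """Root mean squared error of a residual vector."""
    e = np.asarray(errors, dtype=float)
    return float(np.sqrt(np.mean(e ** 2)))


# ---------------------------------------------------------------- VIF --

def _vif_one(X: pd.DataFrame, col: str) -> float:
    others = X.drop(columns=[col])
    A = np.column_stack([np.ones(len(X)), others.to_numpy(dtype=float)])
    b = X[col].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = b - A @ coef
    tss = float(np.sum((b - b.mean()) ** 2))
    if tss <= 0:
        return np.inf
    r2 = 1.0 - float(np.sum(resid ** 2)) / tss
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_backward(data: pd.DataFrame, covariates: list[str],
                 threshold: float = 3.0) -> tuple[list[str], list[dict]]:
    """Iteratively drop the highest-VIF covariate until all VIF < threshold.

    Returns (retained covariates, trace); the trace records each round's
    VIFs.  Ties (including several infinite VIFs under perfect
    collinearity) break alphabetically.
    """
    covs = list(covariates)
    if len(covs) < 2:
        raise ValueError("need at least 2 continuous covariates")
    if len(data) <= len(covs):
        raise ValueError("need more rows than covariates")
    trace = []
    while len(covs) >= 2:
        vifs = {c: _vif_one(data[covs], c) for c in covs}
        trace.append(dict(vifs))
        worst = max(vifs.values())
        if worst < threshold:
            break
        # drop the single worst; alphabetical tie-break for equal/infinite
        drop = sorted([c for c, v in vifs.items() if v == worst])[0]
        covs.remove(drop)
    return covs, trace


# ---------------------------------------------------- candidate models --

def candidate_models(response: str) -> dict[str, ModelSpec]:
    """The four candidate specs sharing Gamma/log, k<=6 bases.

    modINITIAL: s(lat)+s(depth)+s(BT)+s(Oxy)+s(Sal)+s(week)
                +s(year, by=fishery)+fishery+tod
    modNOEM:    s(lat)+s(depth)+s(week)+s(year)+tod
    modNOE:     s(lat)+s(depth)+s(week)+s(year, by=fishery)+fishery+tod
    modNOM:     s(lat)+s(depth)+s(BT)+s(Oxy)+s(Sal)+s(week)+s(year)+tod
    """
    s = SmoothTerm
    return {
        "modINITIAL": ModelSpec(response, smooths=(
            s("lat"), s("depth"), s("BT"), s("Oxy"), s("Sal"), s("week"),
            s("year", by="fishery")), factors=("fishery", "tod")),
        "modNOEM": ModelSpec(response, smooths=(
            s("lat"), s("depth"), s("week"), s("year")), factors=("tod",)),
        "modNOE": ModelSpec(response, smooths=(
            s("lat"), s("depth"), s("week"), s("year", by="fishery")),
            factors=("fishery", "tod")),
        "modNOM": ModelSpec(response, smooths=(
            s("lat"), s("depth"), s("BT"), s("Oxy"), s("Sal"), s("week"),
            s("year")), factors=("tod",)),
    }


def final_model(response: str) -> ModelSpec:
    """The refined model after retention: no BT, no week."""
    s = SmoothTerm
    return ModelSpec(response, smooths=(
        s("lat"), s("depth"), s("Oxy"), s("Sal"),
        s("year", by="fishery")), factors=("fishery", "tod"))


# ----------------------------------------------------------------- CV --

@dataclass
class CVResult:
    candidate: str
    aic: np.ndarray                       # length k * repeats
    pvalue_counts: dict = field(default_factory=dict)  # term -> #(p<alpha)
    n_fits: int = 0
    rmse: np.ndarray = None               # held-out RMSE per fit
    alpha: float = 0.05

    def significant_fraction(self, term: str) -> float:
        return self.pvalue_counts.get(term, 0) / self.n_fits


def _partition(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(idx, k)]


def _partition_with_levels(data: pd.DataFrame, k: int,
                           rng: np.random.Generator,
                           factor_cols: list[str],
                           max_retries: int = 50) -> list[np.ndarray]:
    """Random k-fold partition whose every training set keeps all factor
    levels; redraws the partition a bounded number of times."""
    n = len(data)
    for _ in range(max_retries):
        folds = _partition(n, k, rng)
        ok = True
        for f in folds:
            train = data.drop(data.index[f])
            for c in factor_cols:
                if train[c].nunique() < data[c].nunique():
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return folds
    raise RuntimeError(
        "could not draw a k-fold partition keeping all factor levels in "
        f"every training set within {max_retries} tries")


def repeated_kfold_cv(spec: ModelSpec, data: pd.DataFrame, k: int = 10,
                      repeats: int = 10, alpha: float = 0.05,
                      seed: int = 0, candidate: str = "") -> CVResult:
    """k-fold CV repeated ``repeats`` times.

    Each training fit (on the k-1 retained folds) records its AIC, which
    terms had p < alpha, and the RMSE of its response-scale predictions on
    the held-out fold.  Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    factor_cols = [f for f in spec.factors]
    factor_cols += [s.by for s in spec.smooths if s.by]
    data = data.reset_index(drop=True)
    n = len(data)
    for c in set(factor_cols):
        counts = data[c].value_counts()
        if (counts < k).any():
            lvl = counts.idxmin()
            raise ValueError(
                f"factor {c!r} level {lvl!r} occurs in fewer than k={k} rows")

    aics, rmses = [], []
    counts: dict[str, int] = {}
    n_fits = 0
    for _rep in range(repeats):
        folds = _partition_with_levels(data, k, rng, sorted(set(factor_cols)))
        for f in folds:
            train = data.drop(index=f)
            test = data.loc[f]
            fit = fit_gam(spec, train)
            aics.append(fit.aic)
            mu = predict(fit, test)
            rmses.append(rmse(test[spec.response].to_numpy(dtype=float) - mu))
            for term, p in term_pvalues(fit).items():
                counts[term] = counts.get(term, 0) + (p < alpha)
            n_fits += 1
    return CVResult(candidate=candidate or spec.to_formula(),
                    aic=np.asarray(aics), pvalue_counts=counts,
                    n_fits=n_fits, rmse=np.asarray(rmses), alpha=alpha)


# ------------------------------------------------------- AIC comparison --

@dataclass
class ModelComparison:
    mean_aic: dict
    levene_stat: float
    levene_p: float
    homoscedastic: bool
    anova_stat: float
    anova_p: float
    pairwise: pd.DataFrame
    selected: str
    rationale: str


def _n_covariates(name: str, response: str) -> int:
    return candidate_models(response)[name].n_covariates


def compare_models_aic(cv_results: dict[str, CVResult], alpha: float = 0.05,
                       response: str = "biomass_index") -> ModelComparison:
    """Levene -> (ANOVA + Tukey | Welch + Games-Howell) -> winner.

    The lowest-mean-AIC candidate wins if its mean differs significantly
    from every other candidate's; otherwise the candidate with fewest
    covariates wins (deterministic order for ties).
    """
    names = [n for n in CANDIDATE_ORDER if n in cv_results]
    names += [n for n in cv_results if n not in names]
    vecs = [np.asarray(cv_results[n].aic, dtype=float) for n in names]
    lengths = {len(v) for v in vecs}
    if len(lengths) != 1:
        raise ValueError("AIC vectors must have equal length")
    mean_aic = {n: float(v.mean()) for n, v in zip(names, vecs)}

    # degenerate case: (numerically) identical distributions
    spread = max(float(v.std()) for v in vecs)
    if spread < 1e-12 and max(mean_aic.values()) - min(mean_aic.values()) < 1e-12:
        selected = _simplest(names, cv_results)
        return ModelComparison(mean_aic, np.nan, 1.0, True, np.nan, 1.0,
                               pd.DataFrame(), selected,
                               "identical AIC distributions; simplest chosen")

    lev_stat, lev_p = stats.levene(*vecs, center="median")
    homo = lev_p > alpha
    if homo:
        a_stat, a_p = stats.f_oneway(*vecs)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        values = np.concatenate(vecs)
        groups = np.concatenate([[n] * len(v) for n, v in zip(names, vecs)])
        tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
        pairwise = pd.DataFrame(tk.summary().data[1:],
                                columns=tk.summary().data[0])
        pairwise["reject"] = pairwise["reject"].astype(bool)
        pairwise = pairwise.rename(columns={"p-adj": "p"})
        method = "ANOVA+Tukey"
    else:
        import pingouin as pg
        df = pd.DataFrame({
            "aic": np.concatenate(vecs),
            "model": np.concatenate([[n] * len(v)
                                     for n, v in zip(names, vecs)])})
        wa = pg.welch_anova(data=df, dv="aic", between="model")
        a_stat, a_p = float(wa["F"].iloc[0]), float(wa["p_unc"].iloc[0])
        gh = pg.pairwise_gameshowell(data=df, dv="aic", between="model")
        pairwise = gh.rename(columns={"A": "group1", "B": "group2",
                                      "pval": "p"})
        pairwise["reject"] = pairwise["p"] < alpha
        method = "Welch+Games-Howell"

    best = min(mean_aic, key=mean_aic.get)
    beats_all = True
    if a_p >= alpha:
        beats_all = False
    else:
        for _, row in pairwise.iterrows():
            if best in (row["group1"], row["group2"]) and not row["reject"]:
                beats_all = False
                break
    if beats_all:
        selected, rationale = best, f"lowest mean AIC, all pairs significant ({method})"
    else:
        selected = _simplest(names, cv_results)
        rationale = f"no clear AIC separation ({method}); simplest chosen"
    return ModelComparison(mean_aic, float(lev_stat), float(lev_p), homo,
                           float(a_stat), float(a_p), pairwise, selected,
                           rationale)


def _simplest(names: list[str], cv_results: dict[str, CVResult]) -> str:
    def key(n):
        try:
            ncov = _n_covariates(n, "biomass_index")
        except KeyError:
            ncov = 99
        order = (CANDIDATE_ORDER.index(n) if n in CANDIDATE_ORDER
                 else len(CANDIDATE_ORDER))
        return (ncov, order)
    return sorted(names, key=key)[0]


# ------------------------------------------------------- retention rule --

def retention_rule(cv_result: CVResult, threshold: float = 0.80,
                   terms: list[str] | None = None) -> set[str]:
    """Terms significant in at least ``threshold`` of the CV fits.

    Keys follow the fit summaries: plain smooths by covariate name
    ('Oxy'), by-smooth levels as 'year:fisheryY', factor coefficients as
    'fisheryL'.  A by-factor interaction is retained (all levels) iff ANY
    level passes; the parent factor's coefficients are retained whenever
    its interaction is.
    """
    counts = cv_result.pvalue_counts
    total = cv_result.n_fits
    terms = list(terms or counts.keys())
    retained: set[str] = set()

    # group by-smooth levels into interactions: 'x:flev' -> parent 'f'
    def split_by(term):
        if ":" in term:
            cov, bylev = term.split(":", 1)
            return cov, bylev
        return None

    interactions: dict[tuple, list[str]] = {}
    for t in terms:
        sb = split_by(t)
        if sb is not None:
            cov = sb[0]
            # strip the level suffix by matching against other terms
            interactions.setdefault(cov, []).append(t)

    for t in terms:
        if split_by(t) is None:
            if counts.get(t, 0) / total >= threshold:
                retained.add(t)
    for cov, levels in interactions.items():
        if any(counts.get(t, 0) / total >= threshold for t in levels):
            retained.update(levels)
            # retain the parent factor's coefficient terms
            suffixes = [t.split(":", 1)[1] for t in levels]
            prefix = _common_prefix(suffixes)
            for t in terms:
                if split_by(t) is None and t.startswith(prefix):
                    retained.add(t)
    return retained


def _common_prefix(strings: list[str]) -> str:
    s1, s2 = min(strings), max(strings)
    for i, c in enumerate(s1):
        if c != s2[i]:
            return s1[:i]
    return s1


# -------------------------------------------------------- RMSE contest --

def rmse_compare(spec_a: ModelSpec, spec_b: ModelSpec, data: pd.DataFrame,
                 k: int = 10, repeats: int = 10, seed: int = 0) -> dict:
    """Held-out RMSE of two specs on identical partitions; lower mean wins."""
    rng = np.random.default_rng(seed)
    data = data.reset_index(drop=True)
    factor_cols = sorted({f for s in (spec_a, spec_b)
                          for f in list(s.factors)
                          + [sm.by for sm in s.smooths if sm.by]})
    out = {"A": [], "B": []}
    for _rep in range(repeats):
        folds = _partition_with_levels(data, k, rng, factor_cols)
        for f in folds:
            train = data.drop(index=f)
            test = data.loc[f]
            for tag, spec in (("A", spec_a), ("B", spec_b)):
                fit = fit_gam(spec, train)
                mu = predict(fit, test)
                out[tag].append(rmse(
                    test[spec.response].to_numpy(dtype=float) - mu))
    mean_a, mean_b = np.mean(out["A"]), np.mean(out["B"])
    return {"rmse_a": np.asarray(out["A"]), "rmse_b": np.asarray(out["B"]),
            "mean_a": float(mean_a), "mean_b": float(mean_b),
            "winner": "A" if mean_a <= mean_b else "B"}
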