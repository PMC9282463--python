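"""Gamma additive models with log link.

The model class covers everything the standardization needs: an intercept,
treatment-coded factor terms, penalized cubic-regression-spline smooths,
and factor-by-smooth interactions (one separately penalized smooth per
factor level, each centered within its level so the factor's own
intercepts stay identifiable).

Fitting is penalized iteratively reweighted least squares with
step-halving.  For the Gamma family with log link the Fisher weights are
constant, so each inner step is a single penalized least-squares solve on
the working response.  Smoothing parameters are chosen by minimizing the
restricted marginal likelihood (REML) of the converged working Gaussian
model over log smoothing parameters (L-BFGS-B, started from heavy
smoothing); generalized cross validation is available as an alternative,
and fixed smoothing parameters can be supplied.  The Gamma shape
parameter is estimated by maximum likelihood after the mean fit, and
enters the AIC as one extra parameter:
AIC = -2*loglik + 2*(total edf + 1).

Coefficient covariance is the Bayesian posterior covariance
phi * (X'X + S)^(-1) with the Pearson estimate of the dispersion phi;
smooth-term tests are Wald-type on the evaluated smooth with a
rank-truncated pseudo-inverse of its covariance (rank set by the rounded
edf), parametric terms use t-tests on n - edf residual degrees of freedom.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

from .basis import crs_design, crs_knots, crs_penalty

#: canonical factor-level orders (first level = reference)
FACTOR_LEVELS = {
    "fishery": ("Y", "L", "N"),
    "tod": ("sunrise", "sunset"),
    "survey": ("spring", "autumn"),
}

#: field-standard display symbols used in table output
DISPLAY_NAMES = {"lat": "Y", "lon": "X", "depth": "D", "year": "Yr",
                 "week": "week", "BT": "BT", "Sal": "Sal", "Oxy": "Oxy",
                 "tod": "ToD", "fishery": "Fishery"}

MAX_ETA = 30.0


@dataclass(frozen=True)
class SmoothTerm:
    covariate: str
    k: int = 6
    by: str | None = None

    def __post_init__(self):
        if self.k < 3:
            raise ValueError("basis dimension k must be >= 3")

    def label(self) -> str:
        if self.by:
            return f"s({self.covariate},by={self.by})"
        return f"s({self.covariate})"


@dataclass(frozen=True)
class ModelSpec:
    """A candidate Gamma/log additive model."""

    response: str
    smooths: tuple = ()
    factors: tuple = ()
    intercept: bool = True
    family: str = "gamma"
    link: str = "log"

    def __post_init__(self):
        labels = [s.label() for s in self.smooths] + list(self.factors)
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate terms in model spec")

    @property
    def n_covariates(self) -> int:
        """Distinct covariates (smooth + factor), the simplicity measure."""
        names = {s.covariate for s in self.smooths}
        names |= {s.by for s in self.smooths if s.by}
        names |= set(self.factors)
        return len(names)

    def to_formula(self) -> str:
        parts = []
        for s in self.smooths:
            inner = f"{s.covariate},k={s.k}"
            if s.by:
                inner += f",by={s.by}"
            parts.append(f"s({inner})")
        parts.extend(self.factors)
        return f"{self.family}_{self.link}({self.response}): " + "+".join(parts)

    @classmethod
    def from_formula(cls, text: str) -> "ModelSpec":
        m = re.match(r"\s*(\w+)_(\w+)\((\w+)\)\s*:\s*(.+)", text)
        if not m:
            raise ValueError(f"cannot parse model formula {text!r}")
        family, link, response, rhs = m.groups()
        smooths, factors = [], []
        for part in re.findall(r"s\([^)]*\)|[\w]+", rhs):
            if part.startswith("s("):
                inner = part[2:-1]
                kw = {"k": 6, "by": None}
                fields = [f.strip() for f in inner.split(",")]
                cov = fields[0]
                for f_ in fields[1:]:
                    key, val = f_.split("=")
                    kw[key] = int(val) if key == "k" else val
                smooths.append(SmoothTerm(cov, kw["k"], kw["by"]))
            else:
                factors.append(part)
        return cls(response=response, smooths=tuple(smooths),
                   factors=tuple(factors), family=family, link=link)


@dataclass
class _Term:
    """One block of the design matrix."""

    name: str
    kind: str                    # 'intercept' | 'factor_coef' | 'smooth'
    sl: slice
    penalty: np.ndarray | None = None
    smooth: SmoothTerm | None = None
    level: str | None = None     # by-factor level for by-smooths
    knots: np.ndarray | None = None
    Z: np.ndarray | None = None  # constraint-absorbing reparametrization


def _constraint_null_basis(c: np.ndarray) -> np.ndarray:
    """Orthonormal basis of {v : c.v = 0} (k x (k-1)), via Householder QR.

    Used to absorb the sum-to-zero constraint: the constant function lies
    in both the basis span and the penalty null space, so without this the
    penalized system is exactly singular against the intercept.
    """
    k = c.size
    Q, _ = np.linalg.qr(c[:, None], mode="complete")
    return Q[:, 1:].reshape(k, k - 1)


def _factor_levels(name: str, values) -> list[str]:
    present = set(str(v) for v in values)
    if name in FACTOR_LEVELS:
        return [l for l in FACTOR_LEVELS[name] if l in present]
    return sorted(present)


class _Design:
    """Design matrix builder; freezes knots/levels/centering at training."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        self.terms: list[_Term] = []
        self.levels: dict[str, list[str]] = {}
        cols = []
        p = 0

        def add(name, kind, block, **kw):
            nonlocal p
            w = block.shape[1]
            self.terms.append(_Term(name, kind, slice(p, p + w), **kw))
            cols.append(block)
            p += w

        n = len(data)
        if spec.intercept:
            add("Intercept", "intercept", np.ones((n, 1)))
        for fac in spec.factors:
            levels = _factor_levels(fac, data[fac])
            self.levels[fac] = levels
            vals = data[fac].astype(str).to_numpy()
            for lev in levels[1:]:
                add(f"{fac}{lev}", "factor_coef",
                    (vals == lev).astype(float)[:, None], level=lev)
        for sm in spec.smooths:
            x = data[sm.covariate].to_numpy(dtype=float)
            knots = crs_knots(x, sm.k, name=sm.covariate)
            S = crs_penalty(knots)
            Xs = crs_design(x, knots)
            if sm.by is None:
                Z = _constraint_null_basis(Xs.sum(axis=0))
                B, P = Xs @ Z, Z.T @ S @ Z
                P = P * (np.linalg.norm(B.T @ B) / np.linalg.norm(P))
                add(sm.covariate, "smooth", B, penalty=P,
                    smooth=sm, knots=knots, Z=Z)
            else:
                by_levels = self.levels.get(sm.by) or _factor_levels(
                    sm.by, data[sm.by])
                self.levels.setdefault(sm.by, by_levels)
                byvals = data[sm.by].astype(str).to_numpy()
                for lev in by_levels:
                    mask = byvals == lev
                    if mask.sum() < 2:
                        raise ValueError(
                            f"factor {sm.by!r} level {lev!r} has fewer than "
                            "2 observations")
                    # sum-to-zero within the level's own rows
                    Z = _constraint_null_basis(Xs[mask].sum(axis=0))
                    block = mask[:, None] * (Xs @ Z)
                    P = Z.T @ S @ Z
                    # rescale so a unit smoothing parameter is comparable
                    # to the data curvature of the block
                    P = P * (np.linalg.norm(block.T @ block)
                             / np.linalg.norm(P))
                    add(f"{sm.covariate}:{sm.by}{lev}", "smooth", block,
                        penalty=P, smooth=sm, level=lev,
                        knots=knots, Z=Z)
        self.X = np.hstack(cols)
        self.p = p

    @property
    def smooth_terms(self) -> list[_Term]:
        return [t for t in self.terms if t.kind == "smooth"]

    def penalty_total(self, loglams: np.ndarray) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        for lam, t in zip(np.exp(loglams), self.smooth_terms):
            S[t.sl, t.sl] += lam * t.penalty
        return S

    def matrix_for(self, newdata: pd.DataFrame) -> np.ndarray:
        """Design matrix for new data under the frozen training layout."""
        n = len(newdata)
        X = np.zeros((n, self.p))
        for t in self.terms:
            if t.kind == "intercept":
                X[:, t.sl] = 1.0
            elif t.kind == "factor_coef":
                fac = t.name[: -len(t.level)]
                vals = newdata[fac].astype(str).to_numpy()
                known = self.levels[fac]
                unseen = set(vals) - set(known)
                if unseen:
                    raise ValueError(
                        f"unseen level(s) {sorted(unseen)} of factor {fac!r}")
                X[:, t.sl] = (vals == t.level).astype(float)[:, None]
            else:
                sm = t.smooth
                x = newdata[sm.covariate].to_numpy(dtype=float)
                Xs = crs_design(x, t.knots) @ t.Z
                if sm.by is None:
                    X[:, t.sl] = Xs
                else:
                    byvals = newdata[sm.by].astype(str).to_numpy()
                    unseen = set(byvals) - set(self.levels[sm.by])
                    if unseen:
                        raise ValueError(
                            f"unseen level(s) {sorted(unseen)} of factor "
                            f"{sm.by!r}")
                    mask = byvals == t.level
                    X[:, t.sl] = np.where(mask[:, None], Xs, 0.0)
        return X


def _gamma_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    return float(2.0 * np.sum((y - mu) / mu - np.log(y / mu)))


def _pirls(X, y, S, beta0=None, tol=1e-8, maxit=200):
    """Penalized IRLS for Gamma/log (unit Fisher weights).

    Returns (beta, eta, deviance, A_cho, trace); raises on non-convergence.
    """
    XtX = X.T @ X
    # tiny data-scaled ridge guards against exact singularity in
    # degenerate folds without perturbing heavily penalized fits
    A = XtX + S + (1e-10 * np.trace(XtX) / XtX.shape[0]) * np.eye(XtX.shape[0])
    A_cho = linalg.cho_factor(A)

    def pdev(beta_, eta_):
        return _gamma_deviance(y, np.exp(eta_)) + float(beta_ @ S @ beta_)

    eta = X @ beta0 if beta0 is not None else np.log(y)
    eta = np.clip(eta, -MAX_ETA, MAX_ETA)
    beta = beta0
    crit = pdev(beta, eta) if beta is not None else np.inf
    trace = []
    for it in range(maxit):
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        beta_new = linalg.cho_solve(A_cho, X.T @ z)
        # step-halving on the penalized deviance to break limit cycles
        step = 1.0
        while True:
            beta_try = (beta_new if beta is None
                        else beta + step * (beta_new - beta))
            eta_try = np.clip(X @ beta_try, -MAX_ETA, MAX_ETA)
            crit_try = pdev(beta_try, eta_try)
            if crit_try <= crit + 1e-12 or step < 1e-4 or beta is None:
                break
            step *= 0.5
        converged = (np.isfinite(crit)
                     and abs(crit - crit_try) < tol * (abs(crit_try) + 0.1))
        beta, eta, crit = beta_try, eta_try, crit_try
        trace.append(crit)
        if converged:
            return beta, eta, _gamma_deviance(y, np.exp(eta)), A_cho, trace
    # iteration cap reached: accept a slowly creeping but effectively
    # converged fit; a still-moving criterion is a genuine failure
    if len(trace) > 2 and abs(trace[-1] - trace[-2]) < 1e-5 * (abs(trace[-1])
                                                               + 0.1):
        return beta, eta, _gamma_deviance(y, np.exp(eta)), A_cho, trace
    raise RuntimeError(
        f"PIRLS failed to converge in {maxit} iterations; penalized "
        f"deviance trace tail: {trace[-5:]}")


def _gamma_shape_ml(y: np.ndarray, mu: np.ndarray) -> float:
    """ML estimate of the Gamma shape given fitted means."""
    rhs = 1.0 + float(np.mean(np.log(y / mu)) - np.mean(y / mu))
    # psi(a) - log(a) is increasing from -inf to 0; rhs <= 0 always
    f = lambda la: special.digamma(np.exp(la)) - la - rhs
    lo, hi = -10.0, 20.0
    if f(hi) < 0:          # essentially zero residual variation
        return float(np.exp(hi))
    return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-10)))


def _gamma_loglik(y: np.ndarray, mu: np.ndarray, shape: float) -> float:
    return float(np.sum(shape * np.log(shape / mu) + (shape - 1) * np.log(y)
                        - shape * y / mu - special.gammaln(shape)))


@dataclass
class FittedGAM:
    spec: ModelSpec
    design: _Design
    beta: np.ndarray
    Vb: np.ndarray               # Bayesian coefficient covariance
    lambdas: np.ndarray          # per-smooth smoothing parameters
    edf_by_term: dict
    edf_total: float
    phi: float                   # Pearson dispersion
    shape: float                 # ML Gamma shape
    loglik: float
    aic: float
    deviance: float
    null_deviance: float
    n: int
    criterion: float             # value of the smoothing-selection criterion

    @property
    def deviance_explained(self) -> float:
        if self.null_deviance <= 0:
            return 0.0
        return 1.0 - self.deviance / self.null_deviance

    @property
    def adj_r2(self) -> float:
        # computed at fit time from response-scale residuals
        return self._adj_r2

    def coef(self, name: str) -> float:
        for t in self.design.terms:
            if t.name == name and t.kind in ("intercept", "factor_coef"):
                return float(self.beta[t.sl][0])
        raise KeyError(f"no parametric coefficient {name!r}")


def fit_gam(spec: ModelSpec, data: pd.DataFrame, lambdas=None,
            method: str = "REML", maxfev: int = 250,
            loglam0: float = 8.0) -> FittedGAM:
    """Fit a Gamma/log additive model.

    ``lambdas`` fixes the smoothing parameters (one per smooth block, in
    term order); otherwise they are chosen by minimizing the restricted
    marginal likelihood of the converged working Gaussian model
    (``method='REML'``, the default) or the generalized cross-validation
    score (``method='GCV'``).
    """
    y = data[spec.response].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError(
            f"response {spec.response!r} must be positive and finite "
            "(filter records first)")
    design = _Design(spec, data)
    X = design.X
    n, p = X.shape
    XtX = X.T @ X
    n_sm = len(design.smooth_terms)

    # penalty ranks and log pseudo-determinants of the unit-lambda blocks,
    # for the REML criterion (blocks are disjoint, so they add)
    pranks, plogdets = [], []
    for t in design.smooth_terms:
        w = np.linalg.eigvalsh(t.penalty)
        nz = w > w.max() * 1e-9
        pranks.append(int(nz.sum()))
        plogdets.append(float(np.sum(np.log(w[nz]))))
    null_dim = p - sum(pranks)   # unpenalized coefficients

    def fit_at(loglams, beta0=None):
        S = design.penalty_total(loglams)
        beta, eta, dev, A_cho, trace = _pirls(X, y, S, beta0=beta0)
        # edf = tr[(X'X + S)^-1 X'X]
        H = linalg.cho_solve(A_cho, XtX)
        tau = float(np.trace(H))
        if method.upper() == "GCV":
            crit = n * dev / max(n - tau, 1e-8) ** 2
        else:
            # Gaussian REML of the working model at convergence, with the
            # scale profiled out (Fisher weights are 1 for Gamma/log)
            mu = np.exp(eta)
            z = eta + (y - mu) / mu
            r = z - X @ beta
            rss_pen = float(r @ r + beta @ S @ beta)
            logdet_A = 2.0 * float(np.sum(np.log(np.diag(A_cho[0]))))
            logdet_S = float(np.dot(loglams, pranks) + sum(plogdets))
            nf = max(n - null_dim, 1.0)
            phi_w = rss_pen / nf
            crit = (nf * (1.0 + np.log(2.0 * np.pi * phi_w))
                    + logdet_A - logdet_S)
        return beta, eta, dev, A_cho, H, tau, crit

    warm = {"beta": None}
    if n_sm == 0 or lambdas is not None:
        loglams = (np.log(np.asarray(lambdas, dtype=float))
                   if lambdas is not None and n_sm else np.zeros(n_sm))
    else:
        def objective(ll):
            try:
                beta, *_rest, crit = fit_at(ll, beta0=warm["beta"])
            except (RuntimeError, np.linalg.LinAlgError):
                return 1e12
            warm["beta"] = beta
            return crit

        x0 = np.full(n_sm, loglam0)
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B",
            bounds=[(-12.0, 16.0)] * n_sm,
            options={"maxfun": maxfev, "eps": 1e-3})
        loglams = res.x

    beta, eta, dev, A_cho, H, tau, crit = fit_at(loglams, beta0=warm["beta"])
    mu = np.exp(eta)

    phi = float(np.sum((y - mu) ** 2 / mu ** 2) / max(n - tau, 1.0))
    shape = _gamma_shape_ml(y, mu)
    ll = _gamma_loglik(y, mu, shape)
    aic = -2.0 * ll + 2.0 * (tau + 1.0)
    Vb = phi * linalg.cho_solve(A_cho, np.eye(p))

    edf_diag = np.diag(H)
    edf_by_term = {t.name: float(edf_diag[t.sl].sum())
                   for t in design.terms}

    mu0 = float(np.mean(y))
    null_dev = _gamma_deviance(y, np.full(n, mu0))

    fitted = FittedGAM(
        spec=spec, design=design, beta=beta, Vb=Vb,
        lambdas=np.exp(loglams), edf_by_term=edf_by_term,
        edf_total=tau, phi=phi, shape=shape, loglik=ll, aic=aic,
        deviance=dev, null_deviance=null_dev, n=n, criterion=crit)
    rss = float(np.sum((y - mu) ** 2))
    tss = float(np.sum((y - np.mean(y)) ** 2))
    fitted._adj_r2 = (1.0 - (rss / max(n - tau, 1.0))
                      / (tss / (n - 1)) if tss > 0 else 0.0)
    fitted._mu = mu
    return fitted


def aic(fitted: FittedGAM) -> float:
    """AIC = -2 loglik + 2 (total edf + 1 for the Gamma shape)."""
    return fitted.aic


def predict(fitted: FittedGAM, newdata: pd.DataFrame, with_se: bool = False):
    """Response-scale predictions (and delta-method SEs) for new data."""
    X = fitted.design.matrix_for(newdata)
    eta = np.clip(X @ fitted.beta, -MAX_ETA, MAX_ETA)
    mu = np.exp(eta)
    if not with_se:
        return mu
    se_eta = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, fitted.Vb, X),
                                0.0))
    return mu, mu * se_eta


def _smooth_test(fitted: FittedGAM, term: _Term) -> tuple[float, float, float]:
    """Wald-type F test of one smooth block: (edf, F, p).

    The statistic is formed on the evaluated smooth f = X_j b_j over the
    training rows, using a pseudo-inverse of its covariance truncated at
    rank ~ edf, so shrunk directions do not dilute the test.
    """
    Xj = fitted.design.X[:, term.sl]
    f = Xj @ fitted.beta[term.sl]
    Vf = Xj @ fitted.Vb[term.sl, term.sl] @ Xj.T
    edf = fitted.edf_by_term[term.name]
    r = int(min(term.penalty.shape[0], max(1, round(edf))))
    w, U = np.linalg.eigh(Vf)
    w, U = w[::-1][:r], U[:, ::-1][:, :r]
    w = np.maximum(w, w[0] * 1e-10 if w.size and w[0] > 0 else 1e-12)
    proj = U.T @ f
    T = float(np.sum(proj ** 2 / w))
    df2 = max(fitted.n - fitted.edf_total, 1.0)
    Fstat = T / r
    p = float(stats.f.sf(Fstat, r, df2))
    return edf, Fstat, p


def summarize(fitted: FittedGAM) -> dict:
    """Model summary mirroring the usual GAM output tables.

    Returns parametric rows (estimate, SE, t, p), smooth rows (edf,
    reference df, F, p), deviance explained and adjusted R^2.
    """
    df2 = max(fitted.n - fitted.edf_total, 1.0)
    parametric = []
    for t in fitted.design.terms:
        if t.kind in ("intercept", "factor_coef"):
            est = float(fitted.beta[t.sl][0])
            se = float(np.sqrt(fitted.Vb[t.sl, t.sl][0, 0]))
            tval = est / se if se > 0 else np.inf
            p = 2.0 * float(stats.t.sf(abs(tval), df2))
            parametric.append({"term": t.name, "estimate": est, "se": se,
                               "t": tval, "p": p})
    smooth = []
    for t in fitted.design.smooth_terms:
        edf, Fstat, p = _smooth_test(fitted, t)
        smooth.append({"term": t.name, "edf": edf,
                       "df": t.penalty.shape[0], "F": Fstat, "p": p})
    return {
        "parametric": parametric,
        "smooth": smooth,
        "deviance_explained": fitted.deviance_explained,
        "adj_r2": fitted.adj_r2,
        "aic": fitted.aic,
        "n": fitted.n,
    }


def summary_frames(fitted: FittedGAM) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(parametric, smooth) summary tables as DataFrames for CSV export."""
    s = summarize(fitted)
    return pd.DataFrame(s["parametric"]), pd.DataFrame(s["smooth"])


def term_significance(fitted: FittedGAM, term: str) -> float:
    """p-value of one named term (parametric coefficient or smooth block)."""
    s = summarize(fitted)
    for row in s["parametric"] + s["smooth"]:
        if row["term"] == term:
            return float(row["p"])
    known = [r["term"] for r in s["parametric"] + s["smooth"]]
    raise KeyError(f"unknown term {term!r}; model terms: {known}")


def term_pvalues(fitted: FittedGAM) -> dict:
    """All testable term p-values (factor coefficients and smooths)."""
    s = summarize(fitted)
    out = {}
    for row in s["parametric"]:
        if row["term"] != "Intercept":
            out[row["term"]] = float(row["p"])
    for row in s["smooth"]:
        out[row["term"]] = float(row["p"])
    return out


def effect_percent(coefficient: float) -> float:
    """Percent change of the response mean implied by a log-link coefficient.

    100 * (exp(b) - 1): +92 means 92 % higher than the reference level,
    negative values read as '% lower'.
    """
    return 100.0 * (np.exp(coefficient) - 1.0)
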