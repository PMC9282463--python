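"""Ordinary kriging with an exponential variogram.

Small, self-contained implementation: the empirical semivariogram is
binned from point pairs, an exponential model
``gamma(h) = nugget + sill * (1 - exp(-h / range))`` is fitted by
weighted least squares (Cressie weights, pair counts over squared model
value), and prediction solves the standard ordinary-kriging system whose
weights are constrained to sum to one.  With a zero nugget the predictor
interpolates the data exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


@dataclass(frozen=True)
class Variogram:
    sill: float
    vrange: float
    nugget: float = 0.0

    def __call__(self, h):
        h = np.asarray(h, dtype=float)
        return self.nugget + self.sill * (1.0 - np.exp(-h / self.vrange))

    def covariance(self, h):
        h = np.asarray(h, dtype=float)
        return self.sill * np.exp(-h / self.vrange)


def empirical_semivariogram(coords: np.ndarray, values: np.ndarray,
                            n_bins: int = 12, max_dist: float | None = None):
    """Binned semivariance: (bin centers, gamma estimates, pair counts)."""
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(len(values), k=1)
    dist = d[iu]
    sq = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    if max_dist is None:
        max_dist = float(dist.max()) * 0.7
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (dist > lo) & (dist <= hi)
        if m.sum() == 0:
            continue
        centers.append(0.5 * (lo + hi))
        gammas.append(float(sq[m].mean()))
        counts.append(int(m.sum()))
    return np.array(centers), np.array(gammas), np.array(counts)


def fit_exponential_variogram(lags, gammas, counts, nugget: float = 0.0
                              ) -> Variogram:
    """Weighted-least-squares fit of sill and range (nugget held fixed)."""
    lags = np.asarray(lags, dtype=float)
    gammas = np.asarray(gammas, dtype=float)
    counts = np.asarray(counts, dtype=float)
    s0 = max(float(gammas.max()), 1e-12)
    r0 = max(float(lags.max()) / 3.0, 1e-6)

    def loss(theta):
        s, r = np.exp(theta)
        model = nugget + s * (1.0 - np.exp(-lags / r))
        w = counts / np.maximum(model, 1e-12) ** 2
        return float(np.sum(w * (gammas - model) ** 2))

    res = optimize.minimize(loss, np.log([s0, r0]), method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-10,
                                     "maxfev": 2000})
    s, r = np.exp(res.x)
    return Variogram(sill=float(s), vrange=float(r), nugget=nugget)


def kriging_weights(stations: np.ndarray, target: np.ndarray,
                    vg: Variogram) -> np.ndarray:
    """Ordinary-kriging weights for one target point (sum to one)."""
    w, _ = _solve(stations, np.atleast_2d(target), vg)
    return w[0]


def _solve(stations: np.ndarray, targets: np.ndarray, vg: Variogram):
    n = len(stations)
    d = np.sqrt(((stations[:, None, :] - stations[None, :, :]) ** 2).sum(-1))
    K = np.empty((n + 1, n + 1))
    K[:n, :n] = vg.covariance(d) + vg.nugget * np.eye(n)
    K[n, :n] = 1.0
    K[:n, n] = 1.0
    K[n, n] = 0.0
    dt = np.sqrt(((targets[:, None, :] - stations[None, :, :]) ** 2).sum(-1))
    rhs = np.empty((n + 1, len(targets)))
    rhs[:n] = vg.covariance(dt).T
    rhs[n] = 1.0
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
    return sol[:n].T, sol[n]


def ordinary_kriging(stations: np.ndarray, values: np.ndarray,
                     targets: np.ndarray, vg: Variogram,
                     jitter: float = 1e-9) -> np.ndarray:
    """Predict at target points from station values.

    Duplicate station locations make the system singular; they are
    deterministically jittered apart (documented small perturbation).
    """
    stations = np.asarray(stations, dtype=float).copy()
    values = np.asarray(values, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if len(stations) < 4:
        raise ValueError("kriging needs at least 4 stations")
    # resolve exact duplicates
    d = np.sqrt(((stations[:, None, :] - stations[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(len(stations), k=1)
    dup = d[iu] < 1e-12
    if dup.any():
        rows = np.unique(iu[1][dup])
        for i, r in enumerate(rows):
            stations[r] += jitter * (i + 1)
    w, _ = _solve(stations, targets, vg)
    return w @ values


def krige_field(stations_xy: np.ndarray, values: np.ndarray,
                targets_xy: np.ndarray, n_bins: int = 12,
                nugget: float = 0.0) -> tuple[np.ndarray, Variogram]:
    """Fit the variogram from the stations and krige to the targets."""
    lags, gammas, counts = empirical_semivariogram(stations_xy, values,
                                                   n_bins=n_bins)
    if len(lags) < 3 or np.all(gammas < 1e-15):
        # (near-)constant field: return the constant
        vg = Variogram(sill=max(float(np.var(values)), 1e-15),
                       vrange=max(float(lags.max() if len(lags) else 1.0), 1e-6))
        return np.full(len(np.atleast_2d(targets_xy)),
                       float(values.mean())), vg
    vg = fit_exponential_variogram(lags, gammas, counts, nugget=nugget)
    return ordinary_kriging(stations_xy, values, targets_xy, vg), vg
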