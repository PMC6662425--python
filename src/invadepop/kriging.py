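"""Ordinary kriging on geographic point data, without a trend surface.

Predictions at grid nodes are best linear unbiased combinations of the site
values, with weights obtained from a variogram-derived covariance and
constrained to sum to one (the Lagrange-multiplier form of the ordinary
kriging system). Distances are great-circle (haversine) kilometres.

The variogram model is exponential by default,
``gamma(h) = nugget + psill * (1 - exp(-h / range_km))``; its parameters can
be supplied or fitted to the empirical semivariogram by weighted least
squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import lu_factor, lu_solve

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (np.asarray(lat1, float),
                                              np.asarray(lon1, float),
                                              np.asarray(lat2, float),
                                              np.asarray(lon2, float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class VariogramModel:
    """Exponential variogram: nugget, partial sill and range (km)."""

    nugget: float
    psill: float
    range_km: float
    model: str = "exponential"

    def __post_init__(self):
        if self.psill <= 0 or self.range_km <= 0 or self.nugget < 0:
            raise ValueError("variogram parameters must be positive (nugget >= 0)")
        if self.model != "exponential":
            raise ValueError(f"unsupported variogram model {self.model!r}")

    def semivariance(self, h) -> np.ndarray:
        h = np.asarray(h, float)
        return self.nugget + self.psill * (1.0 - np.exp(-h / self.range_km))

    def covariance(self, h) -> np.ndarray:
        """C(h) = psill * exp(-h / range); C(0) additionally carries the nugget."""
        h = np.asarray(h, float)
        c = self.psill * np.exp(-h / self.range_km)
        return np.where(h == 0, c + self.nugget, c)


def fit_variogram(lats, lons, values, n_bins: int = 12) -> VariogramModel:
    """Fit an exponential variogram to the empirical semivariogram.

    Pairwise semivariances ``0.5 (v_i - v_j)^2`` are binned by distance and
    the model is fitted by least squares weighted by sqrt(bin count).
    Degenerate inputs (constant values) fall back to a unit sill.
    """
    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    values = np.asarray(values, float)
    n = len(values)
    iu = np.triu_indices(n, 1)
    h = haversine_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])[iu]
    gamma = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    if h.max() == 0 or np.allclose(gamma, 0):
        logger.warning("degenerate semivariogram; falling back to default parameters")
        return VariogramModel(nugget=0.0, psill=max(float(np.var(values)), 1e-12),
                              range_km=max(float(h.max()), 1.0))
    edges = np.linspace(0, h.max() * 1.0001, n_bins + 1)
    which = np.digitize(h, edges) - 1
    centers, means, counts = [], [], []
    for b in range(n_bins):
        m = which == b
        if m.sum() > 0:
            centers.append(h[m].mean())
            means.append(gamma[m].mean())
            counts.append(m.sum())
    centers = np.array(centers)
    means = np.array(means)
    w = np.sqrt(np.array(counts, float))

    def resid(theta):
        nugget, psill, rng = np.exp(theta)
        return w * (nugget + psill * (1 - np.exp(-centers / rng)) - means)

    sill0 = max(means.max(), 1e-12)
    x0 = np.log([max(sill0 * 0.05, 1e-12), sill0, max(centers.max() / 3, 1e-6)])
    sol = optimize.least_squares(resid, x0, method="lm", max_nfev=2000)
    nugget, psill, rng = np.exp(sol.x)
    if nugget < 1e-10 * psill:
        nugget = 0.0
    return VariogramModel(nugget=float(nugget), psill=float(psill),
                          range_km=float(rng))


@dataclass
class KrigingSurface:
    """Gridded ordinary-kriging predictions over the padded site bounding box."""

    grid_lat: np.ndarray
    grid_lon: np.ndarray
    predictions: np.ndarray  # (n_lat, n_lon)
    variance: np.ndarray = field(repr=False)
    variogram: VariogramModel = None
    site_lats: np.ndarray = field(default=None, repr=False)
    site_lons: np.ndarray = field(default=None, repr=False)
    site_values: np.ndarray = field(default=None, repr=False)

    def max_node(self) -> tuple[float, float, float]:
        """(lat, lon, prediction) of the surface maximum."""
        i, j = np.unravel_index(np.nanargmax(self.predictions),
                                self.predictions.shape)
        return float(self.grid_lat[i]), float(self.grid_lon[j]), \
            float(self.predictions[i, j])

    def to_frame(self):
        import pandas as pd

        la, lo = np.meshgrid(self.grid_lat, self.grid_lon, indexing="ij")
        return pd.DataFrame({"lat": la.ravel(), "lon": lo.ravel(),
                             "prediction": self.predictions.ravel()})


class _KrigingSolver:
    def __init__(self, lats, lons, values, variogram: VariogramModel,
                 on_singular: str = "jitter"):
        self.variogram = variogram
        lats = np.asarray(lats, float).copy()
        lons = np.asarray(lons, float).copy()
        self.values = np.asarray(values, float)
        n = len(self.values)
        if n < 3:
            raise ValueError("kriging requires at least 3 sites")
        for attempt in range(2):
            h = haversine_km(lats[:, None], lons[:, None],
                             lats[None, :], lons[None, :])
            A = np.empty((n + 1, n + 1))
            A[:n, :n] = variogram.covariance(h)
            A[n, :n] = A[:n, n] = 1.0
            A[n, n] = 0.0
            try:
                self.factor = lu_factor(A)
                # verify conditioning with a solve
                if not np.all(np.isfinite(lu_solve(self.factor,
                                                   np.ones(n + 1)))):
                    raise np.linalg.LinAlgError("non-finite solve")
                break
            except (np.linalg.LinAlgError, ValueError):
                if attempt == 0 and on_singular == "jitter":
                    logger.warning("singular kriging system (duplicate "
                                   "coordinates?); jittering sites by ~1e-5 deg")
                    rng = np.random.default_rng(0)
                    lats = lats + rng.normal(0, 1e-5, n)
                    lons = lons + rng.normal(0, 1e-5, n)
                else:
                    raise ValueError("singular kriging system "
                                     "(duplicate coordinates)") from None
        self.lats, self.lons, self.n = lats, lons, n

    def predict(self, lat, lon):
        lat = np.atleast_1d(np.asarray(lat, float))
        lon = np.atleast_1d(np.asarray(lon, float))
        h0 = haversine_km(self.lats[:, None], self.lons[:, None],
                          lat[None, :], lon[None, :])
        rhs = np.vstack([self.variogram.psill * np.exp(-h0 / self.variogram.range_km),
                         np.ones((1, len(lat)))])
        sol = lu_solve(self.factor, rhs)
        w = sol[:self.n, :]
        wsum = w.sum(axis=0)
        if not np.allclose(wsum, 1.0, atol=1e-6):
            raise RuntimeError("kriging weights do not sum to 1 "
                               f"(max deviation {np.abs(wsum - 1).max():.2e})")
        pred = w.T @ self.values
        mu = sol[self.n, :]
        sill0 = self.variogram.psill + self.variogram.nugget
        var = sill0 - (w * rhs[:self.n, :]).sum(axis=0) - mu
        return pred, np.maximum(var, 0.0)


def ordinary_kriging(
    lats,
    lons,
    values,
    grid_spacing: float = 0.05,
    margin: float = 0.25,
    variogram: VariogramModel | None = None,
    on_singular: str = "jitter",
) -> KrigingSurface:
    """Krige site values onto a regular lat/lon grid.

    The grid covers the bounding box of the sites padded by ``margin``
    degrees at ``grid_spacing`` degree spacing. If ``variogram`` is None it
    is fitted from the empirical semivariogram. With ``nugget = 0`` the
    predictor interpolates the observations exactly.
    """
    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    values = np.asarray(values, float)
    if variogram is None:
        variogram = fit_variogram(lats, lons, values)
    solver = _KrigingSolver(lats, lons, values, variogram, on_singular)
    glat = np.arange(lats.min() - margin, lats.max() + margin + grid_spacing / 2,
                     grid_spacing)
    glon = np.arange(lons.min() - margin, lons.max() + margin + grid_spacing / 2,
                     grid_spacing)
    la, lo = np.meshgrid(glat, glon, indexing="ij")
    pred, var = solver.predict(la.ravel(), lo.ravel())
    surf = KrigingSurface(
        grid_lat=glat, grid_lon=glon,
        predictions=pred.reshape(la.shape), variance=var.reshape(la.shape),
        variogram=variogram, site_lats=lats, site_lons=lons, site_values=values,
    )
    surf._solver = solver  # retained for point predictions
    return surf


def krige_at_points(surface: KrigingSurface, lats, lons):
    """Point predictions from a fitted surface's solver."""
    return surface._solver.predict(lats, lons)[0]
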