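"""Spatial interpolation of group-membership probabilities and range overlap.

Per-group ordinary kriging of membership probabilities onto a regular
lat/lon grid, with an exponential covariance model

    C(d) = sill * exp(-d / range) + nugget * 1[d = 0]

whose parameters are fitted by restricted maximum likelihood (REML,
constant-mean model).  Distances are great-circle kilometres (the
continental extents involved make planar approximations poor).
Predictions are clamped to [0, 1]; groups are kriged independently and
never renormalized across groups — each surface is that group's own
occurrence probability, not a partition.

A group's *range* is the set of grid cells where its surface reaches a
probability threshold, and overlap between two ranges is their Jaccard
index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "MembershipPoints",
    "VariogramConfig",
    "GridSpec",
    "RangeSurface",
    "krige_membership",
    "range_overlap",
    "great_circle_km",
]

EARTH_RADIUS_KM = 6371.0088


def great_circle_km(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray
) -> np.ndarray:
    """Haversine great-circle distance in km; inputs broadcast in degrees."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class MembershipPoints:
    """Per-sample coordinates and membership probability vectors."""

    lat: np.ndarray
    lon: np.ndarray
    membership: pd.DataFrame  # one column per group, rows align with lat/lon

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if not (len(self.lat) == len(self.lon) == len(self.membership)):
            raise ValueError("lat, lon and membership must have equal length")
        probs = self.membership.to_numpy(dtype=float)
        if (probs < -1e-9).any() or (probs > 1 + 1e-9).any():
            raise ValueError("membership probabilities must lie in [0, 1]")
        sums = probs.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("membership vectors must sum to 1 (tolerance 1e-6)")

    @property
    def groups(self) -> list[str]:
        return list(self.membership.columns)


@dataclass
class VariogramConfig:
    """Exponential-covariance parameters; leave fields None to fit by REML."""

    sill: float | None = None
    range_km: float | None = None
    nugget: float | None = None
    n_starts: int = 3
    xtol: float = 1e-6
    jitter_deg: float = 1e-4  # applied to exactly duplicated coordinates

    @property
    def fixed(self) -> bool:
        return None not in (self.sill, self.range_km, self.nugget)


@dataclass
class GridSpec:
    """Regular lat/lon grid; default 0.5-degree spacing, bounding box + 2-degree
    margin.  ``support_km`` bounds how far from the nearest sample a cell can
    lie and still belong to any group's mapped range (ordinary kriging
    reverts to a mean far from data, which is not evidence of occurrence)."""

    spacing_deg: float = 0.5
    margin_deg: float = 2.0
    support_km: float = 500.0
    bounds: tuple[float, float, float, float] | None = None  # lat0, lat1, lon0, lon1

    def axes(self, lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.bounds is not None:
            lat0, lat1, lon0, lon1 = self.bounds
        else:
            lat0, lat1 = lat.min() - self.margin_deg, lat.max() + self.margin_deg
            lon0, lon1 = lon.min() - self.margin_deg, lon.max() + self.margin_deg
        lats = np.arange(lat0, lat1 + self.spacing_deg / 2, self.spacing_deg)
        lons = np.arange(lon0, lon1 + self.spacing_deg / 2, self.spacing_deg)
        return lats, lons


@dataclass
class RangeSurface:
    grid_lat: np.ndarray
    grid_lon: np.ndarray
    surfaces: dict[str, np.ndarray]  # group -> (nlat, nlon), clamped to [0, 1]
    variogram: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    support: np.ndarray | None = None  # cells within support_km of any sample

    def range_mask(self, group: str, threshold: float = 0.5) -> np.ndarray:
        mask = self.surfaces[group] >= threshold
        if self.support is not None:
            mask = mask & self.support
        return mask

    def to_dataframe(self) -> pd.DataFrame:
        lat_g, lon_g = np.meshgrid(self.grid_lat, self.grid_lon, indexing="ij")
        data = {"lat": lat_g.ravel(), "lon": lon_g.ravel()}
        for group, surf in self.surfaces.items():
            data[group] = surf.ravel()
        return pd.DataFrame(data)


def _cov_matrix(d: np.ndarray, sill: float, rng_km: float, nugget: float) -> np.ndarray:
    c = sill * np.exp(-d / rng_km)
    if c.ndim == 2 and c.shape[0] == c.shape[1]:
        c = c + nugget * np.eye(c.shape[0])
    return c


def _log_bounds(d: np.ndarray) -> tuple:
    """Log-parameter box keeping the fit on physically sensible scales:
    sill/nugget of a probability surface, correlation range tied to the
    spatial extent of the data (a range far beyond it is unidentifiable
    and makes the kriging system numerically singular)."""
    hi_range = max(100.0, float(d.max()) / 3.0)
    return (
        (np.log(1e-6), np.log(4.0)),
        (np.log(5.0), np.log(hi_range)),
        (np.log(1e-4), np.log(4.0)),
    )


def _reml_neg_loglik(log_params: np.ndarray, d: np.ndarray, y: np.ndarray, bounds) -> float:
    for x, (lo, hi) in zip(log_params, bounds):
        if not lo <= x <= hi:
            return 1e12
    sill, rng_km, nugget = np.exp(log_params)
    n = len(y)
    v = _cov_matrix(d, sill, rng_km, nugget) + (1e-8 * sill + 1e-10) * np.eye(n)
    try:
        chol = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return 1e12
    logdet_v = 2.0 * np.log(np.diag(chol)).sum()
    ones = np.ones(n)
    vi_ones = np.linalg.solve(v, ones)
    vi_y = np.linalg.solve(v, y)
    xvx = ones @ vi_ones
    mu = (ones @ vi_y) / xvx
    resid = y - mu
    quad = resid @ np.linalg.solve(v, resid)
    return 0.5 * (logdet_v + np.log(xvx) + quad)


def _fit_variogram(
    d: np.ndarray, y: np.ndarray, cfg: VariogramConfig, seed: int
) -> tuple[float, float, float]:
    var_y = max(float(np.var(y)), 1e-6)
    med_d = max(float(np.median(d[d > 0])), 1.0) if (d > 0).any() else 100.0
    bounds = _log_bounds(d)
    rng = np.random.default_rng(seed)
    best, best_val = None, np.inf
    base = np.log([var_y, med_d, 0.1 * var_y])
    base = np.clip(base, [b[0] for b in bounds], [b[1] for b in bounds])
    for k in range(cfg.n_starts):
        x0 = base if k == 0 else np.clip(
            base + rng.normal(0.0, 1.0, size=3),
            [b[0] for b in bounds], [b[1] for b in bounds],
        )
        res = minimize(
            _reml_neg_loglik, x0, args=(d, y, bounds), method="Nelder-Mead",
            options={"xatol": cfg.xtol, "fatol": cfg.xtol, "maxiter": 400},
        )
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    sill, rng_km, nugget = np.exp(best)
    return float(sill), float(rng_km), float(nugget)


def _dedupe(lat: np.ndarray, lon: np.ndarray, eps: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    coords = np.column_stack([lat, lon])
    _uniq, inverse, counts = np.unique(coords, axis=0, return_inverse=True, return_counts=True)
    if counts.max() <= 1:
        return lat, lon
    warnings.warn(
        "duplicate coordinates jittered to keep the kriging system non-singular",
        stacklevel=3,
    )
    rng = np.random.default_rng(seed)
    jit = rng.normal(0.0, eps, size=coords.shape)
    dup = counts[inverse] > 1
    coords = coords + jit * dup[:, None]
    return coords[:, 0], coords[:, 1]


def krige_membership(
    points: MembershipPoints,
    grid_spec: GridSpec | None = None,
    variogram_cfg: VariogramConfig | None = None,
    seed: int = 0,
) -> RangeSurface:
    """Ordinary kriging of each group's membership probabilities onto a grid."""
    grid_spec = grid_spec or GridSpec()
    cfg = variogram_cfg or VariogramConfig()
    lat, lon = _dedupe(points.lat.copy(), points.lon.copy(), cfg.jitter_deg, seed)
    if len(lat) < 3:
        raise ValueError("kriging needs at least 3 points")
    d = great_circle_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    glats, glons = grid_spec.axes(lat, lon)
    glat_full, glon_full = np.meshgrid(glats, glons, indexing="ij")
    d0 = great_circle_km(
        lat[:, None], lon[:, None], glat_full.ravel()[None, :], glon_full.ravel()[None, :]
    )

    support = (d0.min(axis=0) <= grid_spec.support_km).reshape(glat_full.shape)
    surfaces: dict[str, np.ndarray] = {}
    variograms: dict[str, tuple[float, float, float]] = {}
    for gi, group in enumerate(points.groups):
        y = points.membership[group].to_numpy(dtype=float)
        if cfg.fixed:
            sill, rng_km, nugget = cfg.sill, cfg.range_km, cfg.nugget
        else:
            sill, rng_km, nugget = _fit_variogram(d, y, cfg, seed + 1000 * gi)
        n = len(y)
        v = _cov_matrix(d, sill, rng_km, nugget) + (1e-8 * sill) * np.eye(n)
        # ordinary kriging: bordered system enforcing weights summing to 1
        a = np.zeros((n + 1, n + 1))
        a[:n, :n] = v
        a[n, :n] = 1.0
        a[:n, n] = 1.0
        c0 = sill * np.exp(-d0 / rng_km)
        rhs = np.vstack([c0, np.ones((1, c0.shape[1]))])
        sol = np.linalg.solve(a, rhs)
        pred = sol[:n].T @ y
        surfaces[group] = np.clip(pred.reshape(glat_full.shape), 0.0, 1.0)
        variograms[group] = (sill, rng_km, nugget)
    return RangeSurface(grid_lat=glats, grid_lon=glons, surfaces=surfaces,
                        variogram=variograms, support=support)


def range_overlap(
    surface_a: np.ndarray, surface_b: np.ndarray, threshold: float = 0.5
) -> float:
    """Jaccard overlap of the two thresholded ranges (same grid)."""
    a = np.asarray(surface_a) >= threshold
    b = np.asarray(surface_b) >= threshold
    if a.shape != b.shape:
        raise ValueError("surfaces are not on the same grid")
    union = int((a | b).sum())
    if union == 0:
        warnings.warn("both ranges are empty at this threshold; overlap defined as 0",
                      stacklevel=2)
        return 0.0
    return int((a & b).sum()) / union


def overlap_matrix(
    surface: RangeSurface,
    threshold: float = 0.5,
    groups: Sequence[str] | None = None,
    relative: bool = False,
) -> pd.DataFrame:
    """Pairwise Jaccard range overlaps for all groups on one surface.

    With ``relative=True`` each group's range edge is ``threshold`` times
    that group's surface maximum rather than an absolute probability.
    Far from any data, ordinary kriging reverts to a group's overall mean
    frequency, so an absolute cut makes common groups' ranges unbounded;
    the relative cut tracks where each group peaks instead (the region
    where it is expected at highest probability).
    """
    groups = list(groups or surface.surfaces)
    masks = {}
    for g in groups:
        surf = surface.surfaces[g]
        if surface.support is not None:
            peak = float(surf[surface.support].max()) if surface.support.any() else 0.0
        else:
            peak = float(surf.max())
        cut = threshold * peak if relative else threshold
        masks[g] = surface.range_mask(g, cut)
    mat = pd.DataFrame(0.0, index=groups, columns=groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            union = int((masks[a] | masks[b]).sum())
            j = int((masks[a] & masks[b]).sum()) / union if union else 0.0
            mat.loc[a, b] = mat.loc[b, a] = j
        mat.loc[a, a] = 1.0
    return mat


def one_hot_membership(
    lat: Sequence[float], lon: Sequence[float], labels: Sequence[str]
) -> MembershipPoints:
    """Build hard (0/1) membership points from per-sample group labels."""
    groups = sorted(set(labels))
    df = pd.DataFrame(0.0, index=range(len(labels)), columns=groups)
    for i, lab in enumerate(labels):
        df.loc[i, lab] = 1.0
    return MembershipPoints(np.asarray(lat, float), np.asarray(lon, float), df)
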