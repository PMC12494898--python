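"""Spatial diagnostics of diffusion-model residuals: local Getis-Ord Gi.

Residuals (observed presence minus posterior mean probability) are screened
for local spatial clustering with the Getis-Ord Gi statistic — the variant
that *excludes* the focal point from its own neighbourhood — on samples
assigned to a time slice by calibrated probability mass.  Significance uses
a two-sided conditional permutation test: the focal value is held fixed
while the remaining values are shuffled across the other locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibratedDensity, cumulative_mass
from .data_prep import great_circle_km


@dataclass
class SpatialWeights:
    """Neighbour lists and weights per point (no self-neighbours).

    ``neighbors[i]`` holds indices j != i and ``weights[i]`` their
    non-negative weights; ``scheme`` records how they were built.  Points
    with no neighbour are flagged in ``isolated``.
    """

    neighbors: list[np.ndarray]
    weights: list[np.ndarray]
    scheme: str

    def __post_init__(self) -> None:
        for i, (nbr, w) in enumerate(zip(self.neighbors, self.weights)):
            if len(nbr) != len(w):
                raise ValueError("neighbour and weight lists must align")
            if np.any(np.asarray(nbr) == i):
                raise ValueError("self-neighbours are not allowed (Gi convention)")
            if np.any(np.asarray(w) < 0):
                raise ValueError("weights must be non-negative")

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def isolated(self) -> np.ndarray:
        return np.array([len(nbr) == 0 for nbr in self.neighbors])


def residuals(y, p_mean):
    """Presence residual r_i = y_i - posterior mean p_i, in (-1, 1)."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p_mean, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("posterior mean probabilities must lie in [0, 1]")
    return y - p


def time_slice_membership(density: CalibratedDensity, slice_center: float,
                          half_width: float = 500.0,
                          threshold: float = 0.5) -> bool:
    """Does a sample belong to the slice centred at ``slice_center`` cal BP?

    True iff the calibrated probability mass on
    [center + half_width, center - half_width] exceeds ``threshold``
    (strict, per the "over 0.5" rule).
    """
    mass = cumulative_mass(density, slice_center + half_width,
                           slice_center - half_width)
    return bool(mass > threshold)


def build_weights(lons, lats, scheme: str = "knn", k: int = 8,
                  band_km: float | None = None,
                  row_standardize: bool = False) -> SpatialWeights:
    """Spatial weights from great-circle distances.

    ``knn``: binary weights to the k nearest points (default k=8);
    ``distance_band``: binary weights to every point within ``band_km``.
    Optionally row-standardised.  Self-neighbours are never included.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    n = lons.size
    if n < 2:
        raise ValueError("need at least 2 points to build spatial weights")
    dist = great_circle_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    np.fill_diagonal(dist, np.inf)
    neighbors: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    if scheme == "knn":
        if k >= n:
            raise ValueError(f"k={k} must be smaller than the number of points {n}")
        for i in range(n):
            nbr = np.argsort(dist[i], kind="stable")[:k]
            neighbors.append(np.sort(nbr))
            weights.append(np.ones(k))
        label = f"knn(k={k})"
    elif scheme == "distance_band":
        if band_km is None or band_km <= 0:
            raise ValueError("distance_band scheme needs a positive band_km")
        for i in range(n):
            nbr = np.flatnonzero(dist[i] <= band_km)
            neighbors.append(nbr)
            weights.append(np.ones(nbr.size))
        label = f"distance_band({band_km} km)"
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")
    if row_standardize:
        weights = [w / w.sum() if w.size else w for w in weights]
        label += ", row-standardized"
    w = SpatialWeights(neighbors, weights, label)
    if w.isolated.any():
        warnings.warn(f"{int(w.isolated.sum())} isolated point(s) in the "
                      "weights structure", stacklevel=2)
    return w


def getis_ord_gi(values, weights: SpatialWeights) -> np.ndarray:
    """Standardised local Gi statistic per point (focal point excluded).

    For each point i, with sums over j != i, leave-one-out mean and SD:

        Gi = (sum_j w_ij x_j - W_i xbar_(i))
             / (s_(i) sqrt(((n-1) sum_j w_ij^2 - W_i^2) / (n-2)))

    Zero local variance (all other values identical) yields Gi = 0.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Gi needs at least 3 points")
    if n != weights.n:
        raise ValueError("values and weights refer to different point sets")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    total = x.sum()
    total_sq = (x ** 2).sum()
    gi = np.zeros(n)
    for i in range(n):
        w = weights.weights[i]
        if w.size == 0:
            gi[i] = np.nan
            continue
        lag = float(w @ x[weights.neighbors[i]])
        w_i = w.sum()
        mean_i = (total - x[i]) / (n - 1)
        var_i = (total_sq - x[i] ** 2) / (n - 1) - mean_i ** 2
        s_i = np.sqrt(max(var_i, 0.0))
        denom = s_i * np.sqrt(max((n - 1) * (w ** 2).sum() - w_i ** 2, 0.0) / (n - 2))
        gi[i] = (lag - w_i * mean_i) / denom if denom > 0 else 0.0
    return gi


def permutation_pvalues(values, weights: SpatialWeights, n_perm: int = 999,
                        seed: int = 0) -> np.ndarray:
    """Two-sided conditional-permutation p-values for the Gi statistics.

    Point i's value stays fixed while the other values are shuffled across
    the remaining locations; only the spatial lag varies under this null,
    since the leave-one-out moments are permutation-invariant.
    p_i = (1 + #{|Gi_perm| >= |Gi_obs|}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    x = np.asarray(values, dtype=float)
    n = x.size
    gi_obs = getis_ord_gi(x, weights)
    total = x.sum()
    total_sq = (x ** 2).sum()
    rng = np.random.default_rng(seed)
    p = np.ones(n)
    for i in range(n):
        w = weights.weights[i]
        if w.size == 0 or not np.isfinite(gi_obs[i]):
            p[i] = np.nan
            continue
        others = np.delete(x, i)
        w_i = w.sum()
        mean_i = (total - x[i]) / (n - 1)
        var_i = (total_sq - x[i] ** 2) / (n - 1) - mean_i ** 2
        s_i = np.sqrt(max(var_i, 0.0))
        denom = s_i * np.sqrt(max((n - 1) * (w ** 2).sum() - w_i ** 2, 0.0) / (n - 2))
        if denom == 0:
            p[i] = 1.0
            continue
        # sample w.size values from the others, n_perm times
        keys = rng.random((n_perm, others.size))
        picks = np.argpartition(keys, w.size - 1, axis=1)[:, : w.size]
        lag_perm = others[picks] @ w
        gi_perm = (lag_perm - w_i * mean_i) / denom
        exceed = np.count_nonzero(np.abs(gi_perm) >= np.abs(gi_obs[i]))
        p[i] = (1.0 + exceed) / (1.0 + n_perm)
    return p


def hotspot_slice(values, lons, lats, n_perm: int = 999, seed: int = 0,
                  alpha: float = 0.05, scheme: str = "knn", k: int = 8,
                  band_km: float | None = None) -> pd.DataFrame:
    """Gi + permutation test for one slice's members; returns a table."""
    w = build_weights(lons, lats, scheme=scheme, k=min(k, len(lons) - 1),
                      band_km=band_km)
    gi = getis_ord_gi(values, w)
    p = permutation_pvalues(values, w, n_perm=n_perm, seed=seed)
    sig = (p <= alpha) & np.isfinite(gi)
    return pd.DataFrame({
        "lon": np.asarray(lons, dtype=float),
        "lat": np.asarray(lats, dtype=float),
        "residual": np.asarray(values, dtype=float),
        "gi": gi,
        "p_value": p,
        "significant": sig,
        "cluster_sign": np.where(~sig, "none", np.where(gi > 0, "positive", "negative")),
    })


def hotspot_report(resid, lons, lats, densities, slice_centers,
                   half_width: float = 500.0, threshold: float = 0.5,
                   n_perm: int = 999, seed: int = 0, alpha: float = 0.05,
                   scheme: str = "knn", k: int = 8,
                   band_km: float | None = None) -> dict[float, pd.DataFrame]:
    """Per-time-slice hotspot tables for the model residuals.

    Samples enter a slice when their calibrated mass in the +/-half_width
    window exceeds ``threshold``; slices with fewer than 3 members are
    skipped with a warning.  Returns {slice_center: table} where each table
    carries a ``sample_index`` column into the input arrays.
    """
    resid = np.asarray(resid, dtype=float)
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    out: dict[float, pd.DataFrame] = {}
    for center in slice_centers:
        members = np.array([
            time_slice_membership(dens, center, half_width, threshold)
            for dens in densities
        ])
        idx = np.flatnonzero(members)
        if idx.size < 3:
            warnings.warn(f"time slice {center} cal BP has {idx.size} member(s); "
                          "skipped", stacklevel=2)
            continue
        table = hotspot_slice(resid[idx], lons[idx], lats[idx], n_perm=n_perm,
                              seed=seed, alpha=alpha, scheme=scheme, k=k,
                              band_km=band_km)
        table.insert(0, "sample_index", idx)
        out[float(center)] = table
    return out
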