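"""Radiocarbon database loading, screening, site-level binning and distances.

The analysis table is a pandas DataFrame with one row per laboratory
determination and columns

    lab_id, site_id, lon, lat, c14_age, c14_error, ceramic

(``ceramic`` is the binary presence flag y_i).  Preparation follows the
standard protocol for density-of-dates analyses: screen to the study window,
group near-contemporaneous dates from the same site into bins
(complete-linkage clustering on uncalibrated ages, cut at a 100-year
threshold), keep one representative per bin (lowest measurement error,
seeded random tie-break), then attach great-circle distances from each
candidate origin point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

REQUIRED_COLUMNS = ["lab_id", "site_id", "lon", "lat", "c14_age", "c14_error", "ceramic"]

_TRUE_FLAGS = {"1", "true", "t", "yes", "y", "present"}
_FALSE_FLAGS = {"0", "false", "f", "no", "n", "absent"}

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


@dataclass(frozen=True)
class OriginPoint:
    """A named putative origin location (decimal degrees, west negative)."""

    name: str
    lon: float
    lat: float

    def __post_init__(self) -> None:
        _validate_coords(self.lon, self.lat)


@dataclass
class PreparedDataset:
    """Post-binning analysis table plus per-origin distances.

    ``samples`` holds one retained row per (site_id, bin_id) with a
    ``dist_<origin>`` column (km) for every origin in ``origins``.
    """

    samples: pd.DataFrame
    origins: tuple[OriginPoint, ...]

    @property
    def distance_columns(self) -> list[str]:
        return [f"dist_{o.name}" for o in self.origins]

    @property
    def distances(self) -> np.ndarray:
        """(n_samples, n_origins) great-circle distances in km."""
        return self.samples[self.distance_columns].to_numpy(dtype=float)


def _validate_coords(lon, lat) -> None:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180) or \
            np.any(~np.isfinite(lon)) or np.any(~np.isfinite(lat)):
        raise ValueError("coordinates must satisfy |lat| <= 90 and |lon| <= 180")


# The three candidate origin locations considered in the study region:
# an eastern Nile-adjacent centre, a central Saharan massif, and a
# south-western Sahelian site.
BIR_KISEIBA = OriginPoint("bir_kiseiba", 30.02, 22.65)
ADRAR_BOUS = OriginPoint("adrar_bous", 9.03, 20.32)
OUNJOUGOU = OriginPoint("ounjougou", -3.23, 14.63)

STUDY_ORIGINS = {"b": BIR_KISEIBA, "a": ADRAR_BOUS, "o": OUNJOUGOU}


def _parse_flag(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUE_FLAGS:
        return True
    if text in _FALSE_FLAGS:
        return False
    raise ValueError(f"unrecognised presence flag {value!r}")


def load_database(path, column_map: dict[str, str] | None = None,
                  unknown_marker: str | None = None,
                  strict: bool = False) -> pd.DataFrame:
    """Load and validate a radiocarbon date database CSV.

    Parameters
    ----------
    path
        CSV file with a header row (UTF-8).
    column_map
        Optional mapping from this package's column names to the file's
        column names, for external databases with different headers.
    unknown_marker
        Rows whose presence flag equals this marker are dropped: the
        presence model is Bernoulli and has no third state.
    strict
        If True, any invalid row raises; otherwise invalid rows are dropped
        and reported via a ``UserWarning`` naming the row numbers.
    """
    raw = pd.read_csv(path, dtype={"lab_id": str, "site_id": str})
    if column_map:
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(
            f"database is missing required column(s) {missing}; expected header "
            f"{REQUIRED_COLUMNS}"
        )
    raw = raw[REQUIRED_COLUMNS].copy()
    if unknown_marker is not None:
        known = raw["ceramic"].astype(str).str.strip().str.lower() != unknown_marker.lower()
        raw = raw[known]

    bad_rows: list[tuple[int, str]] = []
    flags = []
    for idx, value in raw["ceramic"].items():
        try:
            flags.append(_parse_flag(value))
        except ValueError as exc:
            bad_rows.append((idx, str(exc)))
            flags.append(False)
    raw["ceramic"] = flags
    for col in ("lon", "lat", "c14_age", "c14_error"):
        raw[col] = pd.to_numeric(raw[col], errors="coerce")

    invalid = (
        ~np.isfinite(raw[["lon", "lat", "c14_age", "c14_error"]]).all(axis=1)
        | (raw["c14_error"] <= 0)
        | (raw["lat"].abs() > 90)
        | (raw["lon"].abs() > 180)
    )
    for idx in raw.index[invalid]:
        bad_rows.append((idx, "invalid coordinates, age or non-positive error"))
    if bad_rows:
        report = "; ".join(f"row {i}: {msg}" for i, msg in sorted(set(bad_rows)))
        if strict:
            raise ValueError(f"invalid database rows: {report}")
        import warnings

        warnings.warn(f"dropped invalid database rows: {report}", stacklevel=2)
    keep = ~raw.index.isin([i for i, _ in bad_rows])
    return raw[keep].reset_index(drop=True)


def filter_study_window(samples: pd.DataFrame, lat_min: float = 10.0,
                        lat_max: float = 34.0, age_min: float = 7000.0,
                        age_max: float = 12000.0) -> pd.DataFrame:
    """Retain samples inside the study window (closed intervals).

    Defaults reflect the Saharan/Sahelian study design: latitudes 10-34
    degrees N and uncalibrated ages 7000-12000 BP.
    """
    if lat_min > lat_max or age_min > age_max:
        raise ValueError("filter bounds must be ordered")
    mask = (
        samples["lat"].between(lat_min, lat_max)
        & samples["c14_age"].between(age_min, age_max)
    )
    return samples[mask].reset_index(drop=True)


def bin_samples(c14_ages, threshold_years: float = 100.0) -> np.ndarray:
    """Cluster one site's uncalibrated ages into bins.

    Complete-linkage agglomerative clustering on absolute age differences,
    cut so that no bin spans more than ``threshold_years``.  Returns integer
    bin labels (0-based, ordered by each bin's first occurrence).
    """
    ages = np.asarray(c14_ages, dtype=float).reshape(-1, 1)
    n = ages.shape[0]
    if n == 0:
        return np.array([], dtype=int)
    if n == 1:
        return np.zeros(1, dtype=int)
    z = linkage(ages, method="complete", metric="euclidean")
    labels = fcluster(z, t=threshold_years, criterion="distance")
    # relabel in order of first appearance so labels are deterministic
    _, first_idx = np.unique(labels, return_index=True)
    order = {labels[i]: rank for rank, i in enumerate(sorted(first_idx))}
    return np.array([order[lab] for lab in labels], dtype=int)


def assign_bins(samples: pd.DataFrame, threshold_years: float = 100.0) -> pd.DataFrame:
    """Add a ``bin_id`` column: per-site complete-linkage bins."""
    out = samples.copy()
    out["bin_id"] = ""
    for site, group in out.groupby("site_id", sort=False):
        labels = bin_samples(group["c14_age"].to_numpy(), threshold_years)
        out.loc[group.index, "bin_id"] = [f"{site}.{k}" for k in labels]
    return out


def select_representatives(samples: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep one date per (site, bin): lowest error, seeded random tie-break."""
    if "bin_id" not in samples.columns:
        raise ValueError("run assign_bins first (bin_id column missing)")
    rng = np.random.default_rng(seed)
    keep_idx = []
    for _, group in samples.groupby(["site_id", "bin_id"], sort=True):
        best = group.index[group["c14_error"] == group["c14_error"].min()]
        keep_idx.append(best[rng.integers(len(best))] if len(best) > 1 else best[0])
    return samples.loc[sorted(keep_idx)].reset_index(drop=True)


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance on a sphere of radius 6371.0088 km."""
    _validate_coords(lon1, lat1)
    _validate_coords(lon2, lat2)
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def attach_distances(samples: pd.DataFrame,
                     origins: list[OriginPoint] | tuple[OriginPoint, ...]) -> PreparedDataset:
    """Attach one great-circle distance column per origin (stable order)."""
    if not origins:
        raise ValueError("at least one origin point is required")
    out = samples.copy()
    for origin in origins:
        out[f"dist_{origin.name}"] = great_circle_km(
            out["lon"].to_numpy(), out["lat"].to_numpy(), origin.lon, origin.lat
        )
    return PreparedDataset(out, tuple(origins))


def prepare(samples: pd.DataFrame, origins, seed: int = 0,
            threshold_years: float = 100.0, **window_kwargs) -> PreparedDataset:
    """Full preparation pipeline: filter -> bin -> select -> distances."""
    filtered = filter_study_window(samples, **window_kwargs)
    binned = assign_bins(filtered, threshold_years)
    selected = select_representatives(binned, seed)
    return attach_distances(selected, list(origins))
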