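"""Synthetic study generator with known ground truth.

Generates complete synthetic analogues of a Saharan-scale radiocarbon
presence/absence study: random site locations in a bounding box, per-site
clusters of calendar dates, presence outcomes drawn from the multi-origin
logistic diffusion model, and observed 14C ages drawn through the
calibration-curve measurement model.  Every generative parameter is
recorded so parameter-recovery and model-selection behaviour can be tested
end to end without any external data.

Deliberately not emulated: the real clustering of sites along wadis and
massifs, taphonomic loss, and research-intensity bias — sites are uniform
in the box and every date is observed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .calibration import CalCurve, interp_curve, make_test_curve
from .data_prep import (ADRAR_BOUS, BIR_KISEIBA, OUNJOUGOU, OriginPoint,
                        attach_distances, great_circle_km)
from .origin_diffusion import multi_origin_probability, scale_covariates
from .quantile_dispersal import asymlaplace_rvs

# Study-scale defaults: 259 sites over the Sahara/Sahel box, dates in the
# Early-Holocene analysis window, errors typical of legacy 14C archives.
DEFAULT_BBOX = (-17.0, 37.0, 10.0, 34.0)  # lon_min, lon_max, lat_min, lat_max
DEFAULT_WINDOW = (12000.0, 7500.0)        # cal BP, older to younger

# True per-origin blocks (b0, b_time, b_distance, b_interaction) on scaled
# covariates: presence grows with passing time and decays strongly away
# from each origin, so the origins carry genuinely local, separable
# signals; one origin gets a positive interaction (accelerating spread).
DEFAULT_TRUE_BLOCKS = {
    "bir_kiseiba": (-1.0, 1.2, 2.0, 0.3),
    "adrar_bous": (-0.5, 1.0, 2.6, 0.5),
    "ounjougou": (-0.8, 1.5, 2.2, 0.0),
}


@dataclass
class SyntheticConfig:
    """Ground-truth configuration of one synthetic study."""

    seed: int
    n_sites: int = 259
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX
    origins: tuple[OriginPoint, ...] = (BIR_KISEIBA, ADRAR_BOUS, OUNJOUGOU)
    true_blocks: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_BLOCKS))
    # front-regression truth (cal BP axis: negative slope = younger farther).
    # With tau = 0.05 on the early edge, dates scatter below the front with
    # scale lam/tau, so lam = 100 yr gives a ~2000-yr occupation spread.
    gamma0: float = 10500.0
    gamma1: float = -0.5
    lam: float = 100.0
    tau: float = 0.05
    window: tuple[float, float] = DEFAULT_WINDOW
    dates_per_site_mean: float = 3.0
    error_range: tuple[float, float] = (40.0, 120.0)
    curve_kind: str = "wiggle"

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be at least 1")
        lon_min, lon_max, lat_min, lat_max = self.bbox
        if not (lon_max > lon_min and lat_max > lat_min):
            raise ValueError("degenerate bounding box")
        for o in self.origins:
            if o.name not in self.true_blocks:
                raise ValueError(f"no true parameter block for origin {o.name!r}")

    def make_curve(self, margin: float = 2000.0) -> CalCurve:
        older, younger = max(self.window), min(self.window)
        return make_test_curve(self.curve_kind,
                               (younger - margin, older + margin))


def gen_sites(config: SyntheticConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Uniform random site locations in the bounding box, stable ids."""
    rng = rng or np.random.default_rng(config.seed)
    lon_min, lon_max, lat_min, lat_max = config.bbox
    return pd.DataFrame({
        "site_id": [f"S{i:04d}" for i in range(config.n_sites)],
        "lon": rng.uniform(lon_min, lon_max, config.n_sites),
        "lat": rng.uniform(lat_min, lat_max, config.n_sites),
    })


def gen_presence(theta, distance_matrix, blocks, rng,
                 scaling=None):
    """Bernoulli presence outcomes from the true multi-origin model.

    Covariates are scaled on the generated data (the generative scaling
    constants are returned alongside the draws and the true probabilities).
    """
    if scaling is None:
        t_s, d_s, scaling = scale_covariates(theta, distance_matrix)
    else:
        t_s = scaling.scale_theta(theta)
        d_s = scaling.scale_d(distance_matrix)
    p = multi_origin_probability(np.asarray(blocks, dtype=float), t_s, d_s)
    y = rng.random(np.shape(p)) < p
    return y, p, scaling


def uncalibrate(theta_true, curve: CalCurve, meas_error, rng):
    """Simulate observed 14C ages: Normal(f(theta), combined sigma)."""
    theta_true = np.asarray(theta_true, dtype=float)
    mu, curve_err = interp_curve(curve, theta_true)
    sigma = np.hypot(np.asarray(meas_error, dtype=float), curve_err)
    x = np.asarray(mu) + sigma * rng.standard_normal(np.shape(theta_true))
    return float(x) if x.ndim == 0 else x


def _truncated_window_dates(rng, mu, lam, tau, window, size):
    """AsymLaplace draws rejected outside the calendar window.

    Each position keeps its own location parameter mu[i]; only rejected
    positions are redrawn.
    """
    older, younger = max(window), min(window)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (size,))
    out = np.empty(size)
    pending = np.arange(size)
    for _ in range(200):
        draw = asymlaplace_rvs(mu[pending], lam, tau, size=pending.size, rng=rng)
        ok = (draw >= younger) & (draw <= older)
        out[pending[ok]] = draw[ok]
        pending = pending[~ok]
        if pending.size == 0:
            break
    else:  # pathological truth far outside the window
        out[pending] = np.clip(
            asymlaplace_rvs(mu[pending], lam, tau, pending.size, rng),
            younger, older)
    return out


def gen_quantile_study(config: SyntheticConfig, n_dates: int = 150,
                       origin: OriginPoint | None = None) -> pd.DataFrame:
    """Synthetic presence-only dataset from the front-regression truth.

    One date per synthetic site: calendar age AsymLaplace(gamma0 +
    gamma1 * d, lam, tau) on the cal BP axis (truncated to the study
    window), observed through the calibration measurement model.  Returns a
    table ready for :func:`paleodispersal.quantile_dispersal.fit_quantile_model`.
    """
    rng = np.random.default_rng(config.seed)
    origin = origin or config.origins[0]
    cfg = SyntheticConfig(**{**asdict_config(config), "n_sites": n_dates})
    sites = gen_sites(cfg, rng)
    d = great_circle_km(sites["lon"].to_numpy(), sites["lat"].to_numpy(),
                        origin.lon, origin.lat)
    mu = config.gamma0 + config.gamma1 * d
    curve = config.make_curve()
    lo, hi = curve.support
    # the modelled tau-edge is the upper (older) tail on the cal BP axis;
    # truncate at the curve support (not the window) so the likelihood the
    # fit uses matches the generator apart from a negligible tail clip
    theta = _truncated_window_dates(rng, mu, config.lam, 1.0 - config.tau,
                                    (hi - 100.0, lo + 100.0), n_dates)
    err = rng.uniform(*config.error_range, n_dates)
    x = uncalibrate(theta, curve, err, rng)
    return pd.DataFrame({
        "lab_id": [f"Q{i:04d}" for i in range(n_dates)],
        "site_id": sites["site_id"],
        "lon": sites["lon"], "lat": sites["lat"],
        "c14_age": x, "c14_error": err, "ceramic": True,
        f"dist_{origin.name}": d, "theta_true": theta,
    })


def asdict_config(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["origins"] = config.origins  # keep OriginPoint objects
    return d


def gen_full_study(config: SyntheticConfig):
    """Generate a complete presence/absence study.

    Returns ``(database, truth)`` where ``database`` matches the data_prep
    input schema (including same-site near-duplicate dates so binning has
    work to do) and ``truth`` records every generative parameter plus the
    generative scaling constants and true per-date presence probabilities.
    """
    rng = np.random.default_rng(config.seed)
    sites = gen_sites(config, rng)
    older, younger = max(config.window), min(config.window)

    rows = []
    for _, site in sites.iterrows():
        n_dates = 1 + rng.poisson(max(config.dates_per_site_mean - 1.0, 0.0))
        theta_prev = None
        for _ in range(n_dates):
            if theta_prev is None or rng.random() < 0.5:
                theta = rng.uniform(younger, older)     # new occupation phase
            else:
                # near-duplicate within the 100-yr binning threshold
                theta = np.clip(theta_prev + rng.uniform(-40.0, 40.0),
                                younger, older)
            rows.append({"site_id": site["site_id"], "lon": site["lon"],
                         "lat": site["lat"], "theta_true": theta})
            theta_prev = theta
    df = pd.DataFrame(rows)
    df.insert(0, "lab_id", [f"L{i:05d}" for i in range(len(df))])

    prepared = attach_distances(df, list(config.origins))
    dist = prepared.distances
    df = prepared.samples
    blocks = np.array([config.true_blocks[o.name] for o in config.origins])
    y, p_true, scaling = gen_presence(df["theta_true"].to_numpy(), dist,
                                      blocks, rng)
    df["ceramic"] = y

    curve = config.make_curve()
    err = rng.uniform(*config.error_range, len(df))
    df["c14_error"] = err
    df["c14_age"] = uncalibrate(df["theta_true"].to_numpy(), curve, err, rng)

    truth = {
        "seed": config.seed,
        "origins": {o.name: [o.lon, o.lat] for o in config.origins},
        "true_blocks": {name: list(map(float, b))
                        for name, b in config.true_blocks.items()},
        "scaling": {"theta_mean": scaling.theta_mean,
                    "theta_sd": scaling.theta_sd,
                    "d_mean": list(scaling.d_mean),
                    "d_sd": list(scaling.d_sd)},
        "gamma0": config.gamma0, "gamma1": config.gamma1,
        "lam": config.lam, "tau": config.tau,
        "window": list(config.window),
        "curve_kind": config.curve_kind,
        "p_true": [float(v) for v in np.atleast_1d(p_true)],
    }
    cols = ["lab_id", "site_id", "lon", "lat", "c14_age", "c14_error",
            "ceramic", "theta_true"] + [f"dist_{o.name}" for o in config.origins]
    return df[cols], truth


def write_study(config: SyntheticConfig, outdir) -> dict[str, str]:
    """Write a generated study to disk: database CSV, origins CSV, truth JSON.

    The database CSV contains only the data_prep input schema (the latent
    truth stays in the truth file).
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df, truth = gen_full_study(config)
    db_path = outdir / "dates.csv"
    df[["lab_id", "site_id", "lon", "lat", "c14_age", "c14_error",
        "ceramic"]].assign(ceramic=lambda t: t["ceramic"].astype(int)).to_csv(
        db_path, index=False)
    origins_path = outdir / "origins.csv"
    pd.DataFrame([{"name": o.name, "lon": o.lon, "lat": o.lat}
                  for o in config.origins]).to_csv(origins_path, index=False)
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    return {"database": str(db_path), "origins": str(origins_path),
            "truth": str(truth_path)}
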