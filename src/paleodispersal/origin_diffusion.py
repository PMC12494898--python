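"""Single- and multi-origin Bayesian binomial diffusion models.

The probability that a dated context contains ceramic is modelled on the
logit scale as a function of its (scaled, centred) calendar date theta and
distance d from a putative origin:

    y_i ~ Bernoulli(p_i)
    logit(p_i) = b0 - b_time * theta_i - b_distance * d_i
                 + b_interaction * d_i * theta_i

With theta in scaled cal BP (larger = older), positive b_time means the
technology becomes more probable as time passes, positive b_distance means
decay away from the origin, and the interaction lets diffusion accelerate
or decelerate far from the origin or late in time.  Multi-origin models
give every origin its own full parameter block and combine them by taking
the highest per-origin probability for each sample.  Latent calendar ages
are shared with the calibration measurement model, so chronological
uncertainty propagates into the diffusion parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .calibration import CalCurve, c14_loglik
from .data_prep import OriginPoint, PreparedDataset, great_circle_km
from .inference import (McmcConfig, StepAdapter, chain_rngs, diagnostics_table,
                        RHAT_THRESHOLD)

BLOCK_PARAMS = ("b0", "b_time", "b_distance", "b_interaction")


def zscore(values):
    """Centre and scale to unit variance; returns (scaled, mean, sd)."""
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=0))
    if sd == 0.0:
        raise ValueError("cannot scale a zero-variance covariate")
    return (values - mean) / sd, mean, sd


@dataclass(frozen=True)
class ScalingConstants:
    """Centre/scale constants for theta and each origin's distances.

    Computed once on the analysis dataset and reused for every model and
    prediction surface, so parameter blocks and probability surfaces are
    comparable across model fits.
    """

    theta_mean: float
    theta_sd: float
    d_mean: tuple[float, ...]   # one per origin, same order as the spec
    d_sd: tuple[float, ...]

    def scale_theta(self, theta):
        return (np.asarray(theta, dtype=float) - self.theta_mean) / self.theta_sd

    def scale_d(self, d):
        """Scale an (n, K) or (K,) distance array origin-wise."""
        d = np.asarray(d, dtype=float)
        return (d - np.asarray(self.d_mean)) / np.asarray(self.d_sd)


def scale_covariates(theta_values, distance_matrix):
    """Z-score theta and each origin's distance column.

    Returns ``(theta_scaled, d_scaled, constants)`` where ``distance_matrix``
    is (n, K).  Raises on zero-variance input.
    """
    theta_scaled, t_mean, t_sd = zscore(theta_values)
    d = np.atleast_2d(np.asarray(distance_matrix, dtype=float))
    cols, means, sds = [], [], []
    for k in range(d.shape[1]):
        col, m, s = zscore(d[:, k])
        cols.append(col)
        means.append(m)
        sds.append(s)
    constants = ScalingConstants(t_mean, t_sd, tuple(means), tuple(sds))
    return theta_scaled, np.column_stack(cols), constants


@dataclass
class DiffusionModelSpec:
    """Model definition: ordered origins, priors and scaling constants."""

    origins: tuple[OriginPoint, ...]
    scaling: ScalingConstants
    prior_sd: float = 10.0

    def __post_init__(self) -> None:
        self.origins = tuple(self.origins)
        if not self.origins:
            raise ValueError("at least one origin is required")
        if len(self.scaling.d_mean) != len(self.origins):
            raise ValueError("scaling constants must cover every origin")

    @property
    def n_origins(self) -> int:
        return len(self.origins)

    @property
    def parameter_names(self) -> list[str]:
        return [f"{p}[{o.name}]" for o in self.origins for p in BLOCK_PARAMS]


def diffusion_logit(block, theta_scaled, d_scaled):
    """Per-origin presence probability from one parameter block.

    ``block`` is (b0, b_time, b_distance, b_interaction); the linear
    predictor is b0 - b_time*theta - b_distance*d + b_interaction*d*theta
    with the covariates already scaled and centred.
    """
    b0, bt, bd, bi = np.asarray(block, dtype=float)
    theta_scaled = np.asarray(theta_scaled, dtype=float)
    d_scaled = np.asarray(d_scaled, dtype=float)
    eta = b0 - bt * theta_scaled - bd * d_scaled + bi * d_scaled * theta_scaled
    out = expit(eta)
    return float(out) if out.ndim == 0 else out


def _eta_matrix(blocks: np.ndarray, theta_scaled: np.ndarray,
                d_scaled: np.ndarray) -> np.ndarray:
    """(n, K) linear predictors for all origins at once."""
    t = theta_scaled[:, None]
    return (blocks[:, 0] - blocks[:, 1] * t - blocks[:, 2] * d_scaled
            + blocks[:, 3] * d_scaled * t)


def multi_origin_probability(blocks, theta_scaled, d_scaled):
    """Highest per-origin presence probability across K origins.

    ``blocks`` is (K, 4) and ``d_scaled`` has K as its last axis; for a
    single origin this is exactly :func:`diffusion_logit`.
    """
    blocks = np.atleast_2d(np.asarray(blocks, dtype=float))
    d = np.asarray(d_scaled, dtype=float)
    scalar = np.ndim(theta_scaled) == 0 and d.ndim == 1
    theta = np.atleast_1d(np.asarray(theta_scaled, dtype=float))
    d = d.reshape(1, -1) if d.ndim == 1 else d
    if d.shape[-1] != blocks.shape[0]:
        raise ValueError(
            f"got {blocks.shape[0]} parameter block(s) but {d.shape[-1]} "
            "distance column(s)"
        )
    p = expit(_eta_matrix(blocks, theta, d)).max(axis=-1)
    return float(p[0]) if scalar else p


def _bernoulli_pointwise(y: np.ndarray, eta_star: np.ndarray) -> np.ndarray:
    """Pointwise Bernoulli log-likelihood at the winning linear predictor."""
    return np.where(y > 0, log_expit(eta_star), log_expit(-eta_star))


def diffusion_joint_logpost(params, data: PreparedDataset, curve: CalCurve,
                            spec: DiffusionModelSpec) -> float:
    """Joint log-posterior over (all blocks, theta_1..n); -inf off-support.

    ``params`` is the flat vector [K x 4 block coefficients, n latent
    calendar ages in cal BP].  Reference implementation for oracle tests;
    the sampler evaluates the same terms blockwise.
    """
    k = spec.n_origins
    params = np.asarray(params, dtype=float)
    blocks = params[: 4 * k].reshape(k, 4)
    theta = params[4 * k:]
    df = data.samples
    y = df["ceramic"].to_numpy(dtype=float)
    lo, hi = curve.support
    if np.any((theta < lo) | (theta > hi)):
        return -np.inf
    t_s = spec.scaling.scale_theta(theta)
    d_s = spec.scaling.scale_d(data.distances)
    eta_star = _eta_matrix(blocks, t_s, d_s).max(axis=1)
    lp = float(_bernoulli_pointwise(y, eta_star).sum())
    lp += float(np.sum(c14_loglik(df["c14_age"].to_numpy(dtype=float),
                                  df["c14_error"].to_numpy(dtype=float),
                                  theta, curve)))
    lp += float(-0.5 * np.sum((blocks / spec.prior_sd) ** 2))
    return lp


def _single_origin_map(y: np.ndarray, t_s: np.ndarray, d_s: np.ndarray,
                       prior_var: float) -> np.ndarray:
    """Ridge-penalised logistic MAP fit of one origin's block.

    Used only to initialise the chains in the joint-mode basin (the
    max-combination posterior can hold a minor mode with an origin
    switched off that random-walk chains cannot leave).
    """
    from scipy.optimize import minimize

    design = np.column_stack([np.ones_like(t_s), -t_s, -d_s, d_s * t_s])

    def nll(beta):
        eta = design @ beta
        return (-np.sum(np.where(y > 0, log_expit(eta), log_expit(-eta)))
                + 0.5 * np.sum(beta ** 2) / prior_var)

    res = minimize(nll, np.zeros(4), method="BFGS")
    return np.clip(res.x, -8.0, 8.0)


@dataclass
class DiffusionPosterior:
    """MCMC output of a diffusion-model fit."""

    blocks: np.ndarray            # (chains, draws, K, 4)
    theta_mean: np.ndarray        # posterior mean latent age per sample
    pointwise_loglik: np.ndarray  # (chains*draws, n) Bernoulli term
    p_mean: np.ndarray            # posterior mean presence probability per sample
    diagnostics: pd.DataFrame
    acceptance: pd.DataFrame
    spec: DiffusionModelSpec
    theta_draws: np.ndarray | None = None  # (chains*draws, n) if requested

    def stacked_blocks(self) -> np.ndarray:
        """(total draws, K, 4) with chains concatenated."""
        c, d, k, _ = self.blocks.shape
        return self.blocks.reshape(c * d, k, 4)


def make_spec(prepared: PreparedDataset, curve: CalCurve,
              origins: tuple[OriginPoint, ...] | None = None,
              prior_sd: float = 10.0) -> DiffusionModelSpec:
    """Build a model spec with scaling constants from the analysis dataset.

    Theta scaling uses quick point-calibrated ages; distance scaling is
    per origin.  Pass ``origins`` to restrict to a subset of the prepared
    dataset's origins (e.g. single-origin models m1-m3).
    """
    from .quantile_dispersal import point_calibrate

    origins = tuple(origins) if origins is not None else prepared.origins
    theta_hat = point_calibrate(prepared.samples["c14_age"].to_numpy(), curve)
    _, t_mean, t_sd = zscore(theta_hat)
    means, sds = [], []
    for o in origins:
        col = prepared.samples[f"dist_{o.name}"].to_numpy(dtype=float)
        _, m, s = zscore(col)
        means.append(m)
        sds.append(s)
    return DiffusionModelSpec(origins, ScalingConstants(t_mean, t_sd,
                                                        tuple(means), tuple(sds)),
                              prior_sd)


def fit_diffusion_model(spec: DiffusionModelSpec, data: PreparedDataset,
                        curve: CalCurve, mcmc_config: McmcConfig,
                        seed: int | None = None,
                        store_theta: bool = False) -> DiffusionPosterior:
    """Fit the binomial diffusion model by Metropolis-within-Gibbs.

    Block coefficients are updated coordinate-wise with adaptive random
    walks against the full Bernoulli likelihood; latent calendar ages,
    conditionally independent given the blocks, are updated in one
    vectorised elementwise sweep.  The per-draw pointwise Bernoulli
    log-likelihood matrix is retained for WAIC.  Reproducible under a
    fixed seed.
    """
    df = data.samples
    y = df["ceramic"].to_numpy(dtype=float)
    n = y.size
    if n == 0:
        raise ValueError("cannot fit the diffusion model to an empty dataset")
    if y.min() == y.max():
        warnings.warn("all-presence or all-absence data: the intercept is "
                      "weakly identified (separation risk)", stacklevel=2)
    x = df["c14_age"].to_numpy(dtype=float)
    err = df["c14_error"].to_numpy(dtype=float)
    d_cols = [f"dist_{o.name}" for o in spec.origins]
    d_s = spec.scaling.scale_d(df[d_cols].to_numpy(dtype=float))
    k = spec.n_origins
    lo, hi = curve.support
    prior_var = spec.prior_sd ** 2

    from .quantile_dispersal import point_calibrate

    theta_hat = point_calibrate(x, curve)
    t_hat_s = spec.scaling.scale_theta(theta_hat)
    init_blocks = np.stack([
        _single_origin_map(y, t_hat_s, d_s[:, j], spec.prior_sd ** 2)
        for j in range(k)
    ])

    cfg = mcmc_config if seed is None else McmcConfig(
        mcmc_config.n_chains, mcmc_config.n_iterations, mcmc_config.burn_in,
        mcmc_config.n_keep, seed)
    keep = cfg.keep_indices()
    keep_set = set(keep.tolist())
    n_kept = keep.size
    rngs = chain_rngs(cfg.seed, cfg.n_chains)

    block_draws = np.empty((cfg.n_chains, n_kept, k, 4))
    ll_matrix = np.empty((cfg.n_chains, n_kept, n))
    theta_store = np.empty((cfg.n_chains, n_kept, n)) if store_theta else None
    theta_sum = np.zeros(n)
    p_sum = np.zeros(n)
    acc_rows = []

    for c, rng in enumerate(rngs):
        blocks = init_blocks + 0.2 * rng.standard_normal((k, 4))
        theta = np.clip(theta_hat + 20.0 * rng.standard_normal(n), lo, hi)
        t_s = spec.scaling.scale_theta(theta)
        eta = _eta_matrix(blocks, t_s, d_s)               # (n, K)
        bern = _bernoulli_pointwise(y, eta.max(axis=1))   # (n,)
        cal_ll = c14_loglik(x, err, theta, curve)

        beta_adapt = StepAdapter(4 * k, initial_step=0.3)
        theta_adapt = StepAdapter(n, initial_step=50.0)
        kept_ptr = 0
        acc_post = np.zeros(4 * k + 1)
        n_post = 0

        for it in range(cfg.n_iterations):
            if it == cfg.n_burn:
                beta_adapt.freeze()
                theta_adapt.freeze()
            step = beta_adapt.step
            accepted = np.zeros(4 * k)
            for idx in range(4 * k):
                ko, j = divmod(idx, 4)
                prop_blocks = blocks.copy()
                prop_blocks[ko, j] += step[idx] * rng.standard_normal()
                eta_k = _eta_matrix(prop_blocks[ko:ko + 1], t_s,
                                    d_s[:, ko:ko + 1])[:, 0]
                eta_prop = eta.copy()
                eta_prop[:, ko] = eta_k
                bern_prop = _bernoulli_pointwise(y, eta_prop.max(axis=1))
                log_ratio = (bern_prop.sum() - bern.sum()
                             - 0.5 * (prop_blocks[ko, j] ** 2
                                      - blocks[ko, j] ** 2) / prior_var)
                if np.log(rng.random()) < log_ratio:
                    blocks, eta, bern = prop_blocks, eta_prop, bern_prop
                    accepted[idx] = 1.0
            beta_adapt.record(accepted)

            # latent ages: elementwise vectorised Metropolis sweep
            theta_prop = theta + theta_adapt.step * rng.standard_normal(n)
            in_support = (theta_prop >= lo) & (theta_prop <= hi)
            theta_eval = np.where(in_support, theta_prop, theta)
            t_s_prop = spec.scaling.scale_theta(theta_eval)
            eta_prop = _eta_matrix(blocks, t_s_prop, d_s)
            bern_prop = _bernoulli_pointwise(y, eta_prop.max(axis=1))
            cal_prop = c14_loglik(x, err, theta_eval, curve)
            log_ratio = np.where(in_support,
                                 bern_prop + cal_prop - bern - cal_ll, -np.inf)
            acc_theta = np.log(rng.random(n)) < log_ratio
            theta = np.where(acc_theta, theta_prop, theta)
            t_s = np.where(acc_theta, t_s_prop, t_s)
            eta = np.where(acc_theta[:, None], eta_prop, eta)
            bern = np.where(acc_theta, bern_prop, bern)
            cal_ll = np.where(acc_theta, cal_prop, cal_ll)
            theta_adapt.record(acc_theta.astype(float))

            if it >= cfg.n_burn:
                acc_post += np.append(accepted, acc_theta.mean())
                n_post += 1
            if it in keep_set:
                block_draws[c, kept_ptr] = blocks
                ll_matrix[c, kept_ptr] = bern
                if store_theta:
                    theta_store[c, kept_ptr] = theta
                theta_sum += theta
                p_sum += expit(eta.max(axis=1))
                kept_ptr += 1
        acc_rows.append(acc_post / max(n_post, 1))

    names = spec.parameter_names
    flat = block_draws.reshape(cfg.n_chains, n_kept, 4 * k)
    diag = diagnostics_table(flat, names)
    if (diag["rhat"] > RHAT_THRESHOLD).any():
        bad = diag.loc[diag["rhat"] > RHAT_THRESHOLD, "parameter"].tolist()
        warnings.warn(f"R-hat above {RHAT_THRESHOLD} for {bad}; treat the fit "
                      "as non-converged and lengthen the chains", stacklevel=2)
    acc = pd.DataFrame(acc_rows, columns=names + ["theta"])
    total = cfg.n_chains * n_kept
    return DiffusionPosterior(
        blocks=block_draws, theta_mean=theta_sum / total,
        pointwise_loglik=ll_matrix.reshape(total, n),
        p_mean=p_sum / total, diagnostics=diag, acceptance=acc, spec=spec,
        theta_draws=theta_store.reshape(total, n) if store_theta else None,
    )


@dataclass
class ProbabilitySurface:
    """Posterior mean presence probability on a lon/lat grid at one time."""

    lons: np.ndarray
    lats: np.ndarray
    time_slice: float              # cal BP
    prob: np.ndarray               # (n_lat, n_lon), in [0, 1]


def posterior_mean_surface(posterior: DiffusionPosterior,
                           lons, lats, time_slice: float,
                           max_draws: int = 500) -> ProbabilitySurface:
    """Average the multi-origin presence probability over posterior draws.

    Distances from each grid cell to each origin are great-circle km,
    scaled with the spec's stored constants; at most ``max_draws`` evenly
    spaced posterior draws are used.
    """
    spec = posterior.spec
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    glon, glat = np.meshgrid(lons, lats)
    cells = glon.size
    d = np.empty((cells, spec.n_origins))
    for j, o in enumerate(spec.origins):
        d[:, j] = great_circle_km(glon.ravel(), glat.ravel(), o.lon, o.lat)
    d_s = spec.scaling.scale_d(d)
    t_s = float(spec.scaling.scale_theta(time_slice))

    draws = posterior.stacked_blocks()
    if draws.shape[0] > max_draws:
        idx = np.linspace(0, draws.shape[0] - 1, max_draws).astype(int)
        draws = draws[idx]
    acc = np.zeros(cells)
    t_vec = np.full(cells, t_s)
    for blocks in draws:
        acc += multi_origin_probability(blocks, t_vec, d_s)
    prob = (acc / draws.shape[0]).reshape(glat.shape)
    return ProbabilitySurface(lons, lats, float(time_slice), prob)
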