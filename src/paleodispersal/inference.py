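"""Shared MCMC machinery, convergence diagnostics and WAIC model comparison.

The sampler is an adaptive random-walk Metropolis-within-Gibbs engine:
each coordinate is updated with a Gaussian random-walk proposal whose scale
is tuned toward a 44% acceptance rate during burn-in only, so the
post-adaptation chain targets the stated posterior exactly.  Model modules
reuse the same adaptation rule for their blocked/latent updates.

Diagnostics follow current practice: split-chain (optionally
rank-normalised) Gelman-Rubin R-hat, and autocorrelation-based effective
sample size with Geyer's initial positive-sequence truncation.  Model
comparison uses WAIC with the pointwise-variance penalty (pWAIC2) and
Akaike-type evidence weights on the WAIC differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtri
from scipy.stats import rankdata

RHAT_THRESHOLD = 1.01


@dataclass
class McmcConfig:
    """Chain layout: count, length, burn-in fraction, thinning target, seed.

    Defaults give a desk-scale run; raise ``n_iterations`` (and the per-chain
    retention target) to reproduce long production runs.
    """

    n_chains: int = 4
    n_iterations: int = 10_000
    burn_in: float = 0.5
    n_keep: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if not 0.0 < self.burn_in < 1.0:
            raise ValueError("burn_in must be a fraction in (0, 1)")
        if self.n_iterations < 4:
            raise ValueError("n_iterations too small")

    @property
    def n_burn(self) -> int:
        return int(self.n_iterations * self.burn_in)

    def keep_indices(self) -> np.ndarray:
        """Post-burn-in iteration indices retained after even thinning."""
        post = self.n_iterations - self.n_burn
        kept = min(self.n_keep, post)
        return self.n_burn + np.unique(
            np.round(np.linspace(0, post - 1, kept)).astype(int)
        )


class StepAdapter:
    """Per-coordinate Robbins-Monro step-size adaptation (burn-in only).

    Scales are multiplied by exp(+/-) after every ``batch`` proposals so the
    empirical acceptance rate approaches ``target``; the adjustment decays
    as 1/sqrt(batch number), and `freeze()` stops all adaptation.
    """

    def __init__(self, size: int, initial_step=1.0, target: float = 0.44,
                 batch: int = 50) -> None:
        self.log_step = np.log(np.broadcast_to(np.asarray(initial_step, dtype=float),
                                               (size,)).copy())
        self.target = target
        self.batch = batch
        self._acc = np.zeros(size)
        self._count = 0
        self._n_batches = 0
        self.frozen = False

    @property
    def step(self) -> np.ndarray:
        return np.exp(self.log_step)

    def record(self, accepted: np.ndarray) -> None:
        if self.frozen:
            return
        self._acc += accepted
        self._count += 1
        if self._count >= self.batch:
            self._n_batches += 1
            rate = self._acc / self._count
            self.log_step += (rate - self.target) / np.sqrt(self._n_batches)
            self._acc[:] = 0.0
            self._count = 0

    def freeze(self) -> None:
        self.frozen = True


def chain_rngs(seed: int, n_chains: int) -> list[np.random.Generator]:
    """Independent per-chain generators derived from one seed."""
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n_chains)]


def mcmc_sample(log_posterior, initial, config: McmcConfig,
                initial_step=1.0):
    """Sample a generic vector target with single-site adaptive RW Metropolis.

    Parameters
    ----------
    log_posterior
        Callable mapping a parameter vector to a scalar log density
        (may return ``-inf`` for out-of-support states).
    initial
        Starting vector, or a callable ``(rng, chain_index) -> vector`` used
        to overdisperse chain starts.
    config
        Chain layout and seed.
    initial_step
        Scalar or per-coordinate initial proposal scale.

    Returns
    -------
    draws : ndarray, shape (n_chains, n_kept, dim)
    acceptance : ndarray, shape (n_chains, dim)
        Post-burn-in acceptance rates.
    """
    rngs = chain_rngs(config.seed, config.n_chains)
    keep = config.keep_indices()
    draws = None
    acc_rates = []
    for c, rng in enumerate(rngs):
        x = np.array(initial(rng, c) if callable(initial) else initial, dtype=float)
        dim = x.size
        lp = float(log_posterior(x))
        if not np.isfinite(lp):
            raise ValueError(
                "log-posterior is not finite at the initial value; supply a "
                "valid start (e.g. draw one from the priors)"
            )
        if draws is None:
            draws = np.empty((config.n_chains, keep.size, dim))
        adapter = StepAdapter(dim, initial_step)
        acc_post = np.zeros(dim)
        n_post = 0
        kept_ptr = 0
        keep_set = set(keep.tolist())
        for it in range(config.n_iterations):
            if it == config.n_burn:
                adapter.freeze()
            step = adapter.step
            accepted = np.zeros(dim)
            for j in range(dim):
                prop = x.copy()
                prop[j] += step[j] * rng.standard_normal()
                lp_prop = float(log_posterior(prop))
                if np.log(rng.random()) < lp_prop - lp:
                    x, lp = prop, lp_prop
                    accepted[j] = 1.0
            adapter.record(accepted)
            if it >= config.n_burn:
                acc_post += accepted
                n_post += 1
            if it in keep_set:
                draws[c, kept_ptr] = x
                kept_ptr += 1
        acc_rates.append(acc_post / max(n_post, 1))
    return draws, np.array(acc_rates)


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def _split(chains: np.ndarray) -> np.ndarray:
    """Split each chain in half -> (2m, n//2)."""
    m, n = chains.shape
    half = n // 2
    return np.concatenate([chains[:, :half], chains[:, n - half:]], axis=0)


def _rank_normalize(chains: np.ndarray) -> np.ndarray:
    flat = chains.reshape(-1)
    ranks = rankdata(flat, method="average")
    z = ndtri((ranks - 3.0 / 8.0) / (flat.size + 0.25))
    return z.reshape(chains.shape)


def _rhat_classic(chains: np.ndarray) -> float:
    m, n = chains.shape
    means = chains.mean(axis=1)
    variances = chains.var(axis=1, ddof=1)
    w = variances.mean()
    b_over_n = means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_plus / w))


def gelman_rubin(chains, rank_normalized: bool = True) -> float:
    """Split-chain R-hat for one parameter.

    ``chains`` has shape (n_chains, n_draws).  With ``rank_normalized`` the
    draws are replaced by normal scores of their pooled ranks first, which
    makes the statistic robust to heavy tails; values above 1.01 indicate
    non-convergence.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("chains must be a (n_chains >= 2, n_draws) array")
    halves = _split(chains)
    if rank_normalized:
        halves = _rank_normalize(halves)
    return _rhat_classic(halves)


def effective_sample_size(chains) -> float:
    """Autocorrelation-based ESS (Geyer initial positive sequence).

    Combines chains the standard way: per-chain autocovariances are averaged
    and corrected by the between-chain variance before summing paired
    autocorrelations up to the first negative pair.  Capped at the total
    draw count.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 1:
        chains = chains[None, :]
    m, n = chains.shape
    total = m * n
    if np.ptp(chains) == 0:
        warnings.warn("constant chain: effective sample size undefined, returning 1",
                      stacklevel=2)
        return 1.0
    acov = np.empty((m, n))
    for c in range(m):
        x = chains[c] - chains[c].mean()
        size = 2 ** int(np.ceil(np.log2(2 * n)))
        f = np.fft.rfft(x, size)
        ac = np.fft.irfft(f * np.conjugate(f), size)[:n].real
        acov[c] = ac / n
    w = (acov[:, 0] * n / (n - 1)).mean()
    mean_acov = acov.mean(axis=0)
    b_over_n = chains.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * w + b_over_n
    rho = 1.0 - (w - mean_acov) / var_plus
    # Geyer: sum of adjacent pairs, truncated at the first negative pair and
    # forced monotone non-increasing
    tau = -1.0 + 2.0 * rho[0]
    prev_pair = np.inf
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev_pair)
        tau += 2.0 * pair
        prev_pair = pair
        t += 2
    tau = max(tau, 1.0 / np.log10(total + 10))
    return float(min(total / tau, total))


def diagnostics_table(draws: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Per-parameter R-hat and ESS for draws of shape (chains, draws, dim)."""
    rows = []
    for j, name in enumerate(names):
        chains = draws[:, :, j]
        rows.append({
            "parameter": name,
            "rhat": gelman_rubin(chains),
            "ess": effective_sample_size(chains),
            "converged": gelman_rubin(chains) <= RHAT_THRESHOLD,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# WAIC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaicResult:
    """Pointwise WAIC decomposition for one model (deviance scale)."""

    lppd: float
    p_waic: float
    waic: float
    se: float
    n_obs: int


def waic(pointwise_loglik) -> WaicResult:
    """WAIC from a (draws, observations) pointwise log-likelihood matrix.

    lppd_i = log mean_s exp(ll_si) (log-sum-exp stabilised);
    p_i = Var_s(ll_si) (pWAIC2); WAIC = -2 (sum lppd_i - sum p_i).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be (draws, observations)")
    s, n = ll.shape
    if s < 2:
        raise ValueError("need at least 2 posterior draws for the WAIC variance term")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihood contains non-finite entries")
    lppd_i = logsumexp(ll, axis=0) - np.log(s)
    p_i = ll.var(axis=0, ddof=1)
    waic_i = -2.0 * (lppd_i - p_i)
    se = float(np.sqrt(n * waic_i.var(ddof=1))) if n > 1 else 0.0
    return WaicResult(float(lppd_i.sum()), float(p_i.sum()), float(waic_i.sum()),
                      se, n)


def waic_compare(models) -> pd.DataFrame:
    """Rank models by WAIC with differences and Akaike-type weights.

    ``models`` maps a label to either a :class:`WaicResult` or a raw WAIC
    value.  Returns a DataFrame sorted by WAIC ascending with columns
    ``model, lppd, p_waic, waic, delta_waic, weight``; weights are
    exp(-delta/2) normalised to sum to one.
    """
    if len(models) < 2:
        raise ValueError("model comparison needs at least 2 models")
    rows = []
    for label, res in models.items():
        if isinstance(res, WaicResult):
            rows.append({"model": label, "lppd": res.lppd, "p_waic": res.p_waic,
                         "waic": res.waic})
        else:
            rows.append({"model": label, "lppd": np.nan, "p_waic": np.nan,
                         "waic": float(res)})
    table = pd.DataFrame(rows).sort_values("waic", kind="stable").reset_index(drop=True)
    table["delta_waic"] = table["waic"] - table["waic"].min()
    raw = np.exp(-0.5 * table["delta_waic"].to_numpy())
    table["weight"] = raw / raw.sum()
    return table
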