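"""Radiocarbon calibration curves and the 14C measurement model.

A calibration curve tabulates the expected radiocarbon age f(theta) (and its
1-sigma uncertainty) for each calendar age theta, in calendar years before
present (cal BP, present = 1950 CE; larger = older).  An observed
determination x with laboratory error sigma_m relates to the latent calendar
age theta through

    x ~ Normal(f(theta), sqrt(sigma_m^2 + sigma_curve(theta)^2))

All evaluation is restricted to the tabulated support of the curve: queries
outside it raise rather than extrapolate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CalCurve:
    """A tabulated calibration curve.

    Parameters
    ----------
    cal_age
        Calendar ages of the grid, cal BP, strictly monotone.
    c14_age
        Curve radiocarbon age f(theta) at each grid point, 14C yr BP.
    curve_error
        1-sigma curve uncertainty at each grid point, 14C yr (>= 0).
    name
        Text label, e.g. ``"intcal20"`` or ``"test-identity"``.
    """

    cal_age: np.ndarray
    c14_age: np.ndarray
    curve_error: np.ndarray
    name: str = "unnamed"

    def __post_init__(self) -> None:
        for attr in ("cal_age", "c14_age", "curve_error"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if not (self.cal_age.size == self.c14_age.size == self.curve_error.size):
            raise ValueError("cal_age, c14_age and curve_error must have equal length")
        if self.cal_age.size < 2:
            raise ValueError("calibration curve needs at least two grid points")
        diffs = np.diff(self.cal_age)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("cal_age must be strictly monotone")
        if np.any(self.curve_error < 0):
            raise ValueError("curve_error must be non-negative everywhere")
        # store ascending in cal BP for interpolation
        if diffs[0] < 0:
            order = slice(None, None, -1)
            object.__setattr__(self, "cal_age", self.cal_age[order].copy())
            object.__setattr__(self, "c14_age", self.c14_age[order].copy())
            object.__setattr__(self, "curve_error", self.curve_error[order].copy())

    @property
    def support(self) -> tuple[float, float]:
        """(youngest, oldest) calendar age covered, cal BP."""
        return float(self.cal_age[0]), float(self.cal_age[-1])

    def in_support(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        lo, hi = self.support
        return (theta >= lo) & (theta <= hi)


@dataclass
class CalibratedDensity:
    """Discrete posterior weights for a calendar age on a regular grid.

    ``density`` holds non-negative weights summing to one; the grid is in
    cal BP, ascending.
    """

    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.size != self.density.size:
            raise ValueError("grid and density must have equal length")
        if np.any(self.density < 0):
            raise ValueError("density weights must be non-negative")
        total = self.density.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"density must sum to 1 (got {total!r})")


def read_intcal(path, name: str | None = None) -> CalCurve:
    """Read an IntCal-style 5-column curve file (cal BP, 14C BP, error, ...).

    Only the first three columns are used.  Comma- and whitespace-separated
    dialects are both accepted; header/comment lines starting with ``#`` are
    skipped.
    """
    df = pd.read_csv(path, comment="#", sep=None, engine="python", header=None,
                     skip_blank_lines=True)
    first = df.iloc[0]
    try:
        [float(v) for v in first[:3]]
    except (TypeError, ValueError):
        df = df.iloc[1:]
    arr = df.iloc[:, :3].to_numpy(dtype=float)
    return CalCurve(arr[:, 0], arr[:, 1], arr[:, 2],
                    name=name or str(path))


def _check_support(curve: CalCurve, theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if not np.all(curve.in_support(theta)):
        lo, hi = curve.support
        raise ValueError(
            f"calendar age outside support [{lo}, {hi}] cal BP of curve "
            f"'{curve.name}'"
        )
    return theta


def interp_curve(curve: CalCurve, theta):
    """Linearly interpolate the curve mean and error at calendar age theta.

    Returns ``(mu, err)`` in 14C years; raises for theta outside the
    tabulated support.
    """
    theta = _check_support(curve, theta)
    mu = np.interp(theta, curve.cal_age, curve.c14_age)
    err = np.interp(theta, curve.cal_age, curve.curve_error)
    if np.ndim(theta) == 0:
        return float(mu), float(err)
    return mu, err


def combined_sigma(meas_error, curve_error):
    """Total 14C-age standard deviation: errors added in quadrature."""
    meas_error = np.asarray(meas_error, dtype=float)
    curve_error = np.asarray(curve_error, dtype=float)
    if np.any(meas_error < 0) or np.any(curve_error < 0):
        raise ValueError("errors must be non-negative")
    out = np.hypot(meas_error, curve_error)
    return float(out) if out.ndim == 0 else out


_LOG_2PI = np.log(2.0 * np.pi)


def c14_loglik(x, meas_error, theta, curve: CalCurve):
    """Normal log-density of observed 14C age x at latent calendar age theta.

    The mean is the interpolated curve value f(theta); the standard
    deviation combines the measurement and curve errors in quadrature.
    Vectorised over ``theta`` (and broadcast-compatible ``x``/``meas_error``).
    """
    if np.any(np.asarray(meas_error, dtype=float) <= 0):
        raise ValueError("measurement error must be positive")
    theta = _check_support(curve, theta)
    mu = np.interp(theta, curve.cal_age, curve.c14_age)
    curve_err = np.interp(theta, curve.cal_age, curve.curve_error)
    sigma = np.hypot(np.asarray(meas_error, dtype=float), curve_err)
    x = np.asarray(x, dtype=float)
    out = -0.5 * _LOG_2PI - np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2
    return float(out) if out.ndim == 0 else out


def calibrate(x: float, meas_error: float, curve: CalCurve,
              grid_step: float = 1.0) -> CalibratedDensity:
    """Calibrate one determination to a discrete calendar-age density.

    The density is proportional to the measurement-model likelihood
    evaluated on a regular calendar grid spanning the curve support, then
    normalised to sum to one.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    lo, hi = curve.support
    grid = np.arange(np.ceil(lo), np.floor(hi) + 0.5 * grid_step, grid_step)
    ll = c14_loglik(x, meas_error, grid, curve)
    ll = ll - ll.max()
    w = np.exp(ll)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise FloatingPointError(
            "calibrated density underflowed to zero everywhere; widen the "
            "curve support or check the determination against the curve range"
        )
    return CalibratedDensity(grid, w / total)


def cumulative_mass(density: CalibratedDensity, start: float, end: float) -> float:
    """Probability mass on the closed calendar interval [start, end].

    Bounds may be given in either order (cal BP convention is
    older-to-younger, i.e. start > end); a non-overlapping interval gives 0.
    """
    hi, lo = (start, end) if start >= end else (end, start)
    mask = (density.grid >= lo) & (density.grid <= hi)
    return float(density.density[mask].sum())


def make_test_curve(kind: str, span: tuple[float, float], step: float = 5.0,
                    amplitude: float = 25.0, period: float = 40.0,
                    error: float = 15.0) -> CalCurve:
    """Build a synthetic calibration curve for tests and simulations.

    ``identity``: f(theta) = theta with zero curve error.
    ``wiggle``: f(theta) = theta + amplitude * sin(theta / period) with a
    small constant curve error; amplitude < period keeps f single-valued
    (f'(theta) = 1 + (A/P) cos(theta/P) > 0 whenever A < P).
    """
    lo, hi = min(span), max(span)
    if not hi > lo:
        raise ValueError("span must be a nonempty calendar range")
    grid = np.arange(lo, hi + 0.5 * step, step)
    if kind == "identity":
        return CalCurve(grid, grid.copy(), np.zeros_like(grid), name="test-identity")
    if kind == "wiggle":
        if amplitude >= period:
            raise ValueError("amplitude must be < period to keep the curve single-valued")
        c14 = grid + amplitude * np.sin(grid / period)
        return CalCurve(grid, c14, np.full_like(grid, float(error)), name="test-wiggle")
    raise ValueError(f"unknown test curve kind {kind!r} (expected 'identity' or 'wiggle')")


def write_density_csv(density: CalibratedDensity, path) -> None:
    """Write a calibrated density as two-column CSV (cal BP, probability)."""
    pd.DataFrame({"cal_bp": density.grid, "probability": density.density}).to_csv(
        path, index=False
    )
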