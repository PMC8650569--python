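"""Lag-logistic growth model and constrained least-squares fitting.

The population model is a logistic curve preceded by a latency (lag) phase
of fixed duration ``tau``:

    dx/dt = 0                      for t <  tau
    dx/dt = mu * x * (1 - x/K)     for t >= tau

whose closed form is ``x(t) = x0`` during the lag and the classical logistic
``K*x0 / (x0 + (K - x0)*exp(-mu*(t - tau)))`` afterwards.  Counts are colony
forming units (cfu) per cm^2 of substratum, time is in hours.

Fitting minimises the sum of squared residuals on log10 counts with the
initial condition ``x0`` pinned to the observed count at t = 0 (the density
measured immediately after the adhesion step), subject to box constraints
``mu in [0, mu_max]``, ``tau in [0, tau_max]`` and ``K > 0``.  Curves with no
apparent growth are not fitted: their carrying capacity is reported as the
mean of the observed counts, with the rate and lag undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GrowthParams",
    "FitBounds",
    "GrowthCurve",
    "FitResult",
    "InvalidParameterError",
    "FitFailureError",
    "logistic_value",
    "growth_ode_rhs",
    "detect_growth",
    "fit_growth",
    "LOG10K_BOUNDS",
]

#: Box constraint on log10(K) used by the fitter and by grid-search oracles
#: (1 to 1e12 cfu covers any plate-count experiment).
LOG10K_BOUNDS = (0.0, 12.0)

#: Default growth-detection threshold in log10 units (about threefold).
GROWTH_THRESHOLD = 0.5


class InvalidParameterError(ValueError):
    """Raised when growth parameters are non-finite or out of range."""


class FitFailureError(RuntimeError):
    """Raised when the optimiser fails to converge from every start."""


def _is_undef(v: float) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the lag-logistic model.

    x0   initial count (cfu cm^-2), fixed by the t = 0 observation
    mu   maximal growth rate (h^-1); NaN when undefined (no-growth curves)
    K    carrying capacity (cfu cm^-2)
    tau  lag time (h); NaN when undefined
    """

    x0: float
    mu: float
    K: float
    tau: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x0) and self.x0 > 0):
            raise InvalidParameterError(f"x0 must be finite and > 0, got {self.x0}")
        if not (math.isfinite(self.K) and self.K > 0):
            raise InvalidParameterError(f"K must be finite and > 0, got {self.K}")
        if not _is_undef(self.mu) and not (math.isfinite(self.mu) and self.mu >= 0):
            raise InvalidParameterError(f"mu must be >= 0 or NaN, got {self.mu}")
        if not _is_undef(self.tau) and not (math.isfinite(self.tau) and self.tau >= 0):
            raise InvalidParameterError(f"tau must be >= 0 or NaN, got {self.tau}")

    @property
    def defined(self) -> bool:
        """True when the dynamic parameters (mu, tau) are defined."""
        return not (_is_undef(self.mu) or _is_undef(self.tau))


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the least-squares fit (mu_max in h^-1, tau_max in h)."""

    mu_max: float = 1.0
    tau_max: float = 72.0

    def __post_init__(self) -> None:
        if not (self.mu_max > 0 and self.tau_max > 0):
            raise InvalidParameterError("mu_max and tau_max must be positive")


@dataclass
class GrowthCurve:
    """Observed counts (Ti, Xi) for one species in one community context.

    Replicate observations may share a time point (pooled fitting); times
    must be sorted.  Censored points carry the detection limit as their
    stored value and are excluded from fitting.
    """

    times: np.ndarray
    counts: np.ndarray
    censored: np.ndarray = None  # type: ignore[assignment]
    detection_limit: float = 1e3

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(self.times.shape, dtype=bool)
        self.censored = np.asarray(self.censored, dtype=bool)
        if not (self.times.shape == self.counts.shape == self.censored.shape):
            raise ValueError("times, counts and censored must have equal length")
        if self.times.size == 0:
            raise ValueError("empty growth curve")
        if np.any(np.diff(self.times) < 0):
            order = np.argsort(self.times, kind="stable")
            self.times = self.times[order]
            self.counts = self.counts[order]
            self.censored = self.censored[order]
        if np.any(self.counts[~self.censored] <= 0):
            raise ValueError("non-censored counts must be positive")

    @classmethod
    def from_frame(cls, df, species: str, context: str) -> "GrowthCurve":
        """Extract the curve of one (species, context) from a count table."""
        sub = df[(df["species"] == species) & (df["context"] == context)]
        if sub.empty:
            raise ValueError(f"no rows for species={species!r} context={context!r}")
        return cls(
            times=sub["time_h"].to_numpy(float),
            counts=sub["cfu_per_cm2"].to_numpy(float),
            censored=sub["censored"].to_numpy(bool),
            detection_limit=float(sub["detection_limit"].iloc[0]),
        )


FitStatus = Literal["fitted", "no_growth", "insufficient_data"]


@dataclass(frozen=True)
class FitResult:
    """Outcome of a growth-curve fit.

    For ``no_growth`` curves K equals the mean of the observed counts and
    mu/tau are NaN.  ``insufficient_data`` carries no parameters.
    """

    params: GrowthParams | None
    status: FitStatus
    sse: float
    n_points: int


def logistic_value(t, p: GrowthParams):
    """Closed-form lag-logistic count at time(s) ``t``.

    Returns ``x0`` for t < tau and the logistic expression afterwards;
    the two branches agree at t = tau.
    """
    if not p.defined:
        raise InvalidParameterError("mu/tau undefined; no closed form available")
    t_arr = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):
        decay = np.exp(-p.mu * np.maximum(t_arr - p.tau, 0.0))
    value = p.K * p.x0 / (p.x0 + (p.K - p.x0) * decay)
    out = np.where(t_arr < p.tau, p.x0, value)
    return float(out) if np.isscalar(t) or out.ndim == 0 else out


def growth_ode_rhs(t: float, x, p: GrowthParams):
    """Right-hand side of the lag-logistic ODE (0 during the lag phase)."""
    if not p.defined:
        raise InvalidParameterError("mu/tau undefined; no ODE available")
    x_arr = np.asarray(x, dtype=float)
    rate = np.where(t < p.tau, 0.0, p.mu * x_arr * (1.0 - x_arr / p.K))
    return float(rate) if np.isscalar(x) or rate.ndim == 0 else rate


def _per_time_mean_log10(curve: GrowthCurve) -> tuple[np.ndarray, np.ndarray]:
    """Geometric-mean count (as log10) per sampling time, non-censored points."""
    ok = ~curve.censored
    times = curve.times[ok]
    logs = np.log10(curve.counts[ok])
    uniq = np.unique(times)
    means = np.array([logs[times == u].mean() for u in uniq])
    return uniq, means


def detect_growth(curve: GrowthCurve, threshold: float = GROWTH_THRESHOLD) -> bool:
    """True when the curve shows apparent growth.

    Growth is called when the largest per-time geometric-mean count exceeds
    the count at the first sampling time by at least ``threshold`` log10
    units (default 0.5, about threefold).
    """
    if not np.any(~curve.censored):
        raise ValueError("all points censored; growth cannot be assessed")
    uniq, means = _per_time_mean_log10(curve)
    if uniq.size < 2:
        raise ValueError("need non-censored points at >= 2 times")
    return bool(means.max() - means[0] >= threshold)


def _residuals(theta: np.ndarray, times: np.ndarray, log_counts: np.ndarray, x0: float):
    mu, tau, log_k = theta
    k = 10.0 ** log_k
    with np.errstate(over="ignore"):
        decay = np.exp(-mu * np.maximum(times - tau, 0.0))
    value = k * x0 / (x0 + (k - x0) * decay)
    model = np.where(times < tau, x0, value)
    return np.log10(model) - log_counts


def fit_growth(
    curve: GrowthCurve,
    bounds: FitBounds = FitBounds(),
    growth_threshold: float = GROWTH_THRESHOLD,
) -> FitResult:
    """Constrained least-squares fit of (mu, K, tau) on log10 counts.

    x0 is fixed to the (geometric-mean) count at t = 0.  Multi-start local
    optimisation: a 4x4 grid of (mu, tau) starting points over the bounded
    box with K started at the maximum observed count; the best final
    objective wins and ties go to the smallest tau.

    Returns status ``insufficient_data`` when the t = 0 point is censored
    (x0 unknown) or fewer than 4 non-censored points remain, and
    ``no_growth`` (K = mean count, mu/tau undefined) when no apparent
    growth is detected.
    """
    ok = ~curve.censored
    if curve.times.size == 0 or not np.any(ok):
        raise ValueError("empty growth curve")
    t0 = curve.times.min()
    at_t0 = ok & (curve.times == t0)
    n_usable = int(ok.sum())
    if t0 != 0 or not np.any(at_t0) or n_usable < 4:
        return FitResult(params=None, status="insufficient_data", sse=math.nan,
                         n_points=n_usable)

    x0 = float(10.0 ** np.log10(curve.counts[at_t0]).mean())
    times = curve.times[ok]
    log_counts = np.log10(curve.counts[ok])

    if not detect_growth(curve, threshold=growth_threshold):
        k_mean = float(curve.counts[ok].mean())
        sse = float(np.sum((math.log10(k_mean) - log_counts) ** 2))
        params = GrowthParams(x0=x0, mu=math.nan, K=k_mean, tau=math.nan)
        return FitResult(params=params, status="no_growth", sse=sse, n_points=n_usable)

    lo = np.array([0.0, 0.0, LOG10K_BOUNDS[0]])
    hi = np.array([bounds.mu_max, bounds.tau_max, LOG10K_BOUNDS[1]])
    log_k0 = float(np.clip(np.log10(curve.counts[ok].max()), *LOG10K_BOUNDS))
    fractions = (0.125, 0.375, 0.625, 0.875)

    best: tuple[float, float, np.ndarray] | None = None  # (sse, tau, theta)
    diagnostics = []
    for f_mu in fractions:
        for f_tau in fractions:
            theta0 = np.array([f_mu * bounds.mu_max, f_tau * bounds.tau_max, log_k0])
            try:
                res = least_squares(
                    _residuals, theta0, bounds=(lo, hi),
                    args=(times, log_counts, x0), method="trf",
                )
            except Exception as exc:  # pragma: no cover - defensive
                diagnostics.append(f"start {theta0}: {exc}")
                continue
            if res.status <= 0:
                diagnostics.append(f"start {theta0}: status {res.status}")
                continue
            sse = float(2.0 * res.cost)
            tau_hat = float(res.x[1])
            if (
                best is None
                or sse < best[0] - 1e-12
                or (abs(sse - best[0]) <= 1e-12 and tau_hat < best[1])
            ):
                best = (sse, tau_hat, res.x)
    if best is None:
        raise FitFailureError(
            "optimizer failed from all starts: " + "; ".join(diagnostics)
        )
    sse, _, theta = best
    params = GrowthParams(x0=x0, mu=float(theta[0]), K=float(10.0 ** theta[2]),
                          tau=float(theta[1]))
    return FitResult(params=params, status="fitted", sse=sse, n_points=n_usable)
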