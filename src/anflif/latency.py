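"""Empirical latency and jitter functions of the fiber response.

The mean latency lat(p) and the initiation-period jitter jit(p) are sigmoid
functions of firing probability p, expressed through the *effective
threshold* x = mu + sigma * PhiInv(p): the membrane-potential peak that a
stimulus firing with probability p must have reached.  Working in this
coordinate makes both functions level-invariant descriptions of the fiber.

Units: coefficients a1, a2 in uV (effective-threshold coordinate), a3, a4 in
us.  Table-of-record defaults describe a cat auditory nerve fiber.
"""

from __future__ import annotations

from dataclasses import dataclass, astuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import norm

__all__ = [
    "LatSigmoid",
    "JitSigmoid",
    "FittingError",
    "effective_threshold",
    "lat",
    "jit",
    "fit_latency_functions",
    "JIT_FLOOR",
    "PROB_CLIP",
]

#: Probabilities are clipped to [PROB_CLIP, 1 - PROB_CLIP] before the normal
#: quantile, avoiding infinities at p in {0, 1}.
PROB_CLIP = 1e-9

#: Floor (us) applied to jit wherever it acts as the scale of an exponential
#: waiting time; prevents division by zero as p -> 1.
JIT_FLOOR = 0.01


@dataclass(frozen=True)
class LatSigmoid:
    """Coefficients of lat(p) = a3 / (1 + exp((x - a1)/a2)) + a4."""

    a1: float = 106.0  # uV, sigmoid midpoint
    a2: float = 5.14  # uV, sigmoid width
    a3: float = 368.0  # us, sigmoid height
    a4: float = 472.0  # us, asymptotic (high-level) latency

    def __post_init__(self) -> None:
        if not self.a2 > 0 or not self.a3 > 0 or self.a4 < 0:
            raise ValueError("require a2 > 0, a3 > 0, a4 >= 0")


@dataclass(frozen=True)
class JitSigmoid:
    """Coefficients of jit(p) = a3 / (1 + exp((x - a1)/a2))."""

    a1: float = 109.0  # uV
    a2: float = 3.24  # uV
    a3: float = 136.0  # us, low-level jitter asymptote

    def __post_init__(self) -> None:
        if not self.a2 > 0 or not self.a3 > 0:
            raise ValueError("require a2 > 0, a3 > 0")


class FittingError(RuntimeError):
    """Raised when the latency/jitter sigmoids cannot be identified."""


def effective_threshold(p, mu: float, sigma: float):
    """Map firing probability to the peak potential x = mu + sigma*PhiInv(p) (uV)."""
    p = np.clip(p, PROB_CLIP, 1.0 - PROB_CLIP)
    return mu + sigma * norm.ppf(p)


def _sigmoid(x, a1, a2, a3):
    z = np.clip((np.asarray(x, dtype=float) - a1) / a2, -500.0, 500.0)
    return a3 / (1.0 + np.exp(z))


def lat_from_x(x, s: LatSigmoid):
    """lat evaluated directly at an effective-threshold (peak-potential) value."""
    return _sigmoid(x, s.a1, s.a2, s.a3) + s.a4


def jit_from_x(x, s: JitSigmoid):
    """jit evaluated directly at an effective-threshold value, floored at JIT_FLOOR."""
    return np.maximum(_sigmoid(x, s.a1, s.a2, s.a3), JIT_FLOOR)


def lat(p, s: LatSigmoid, mu: float, sigma: float):
    """Mean delay (us) between the start of the initiation period and spike observation.

    Strictly decreasing in p; bounded in (a4, a3 + a4).
    """
    return lat_from_x(effective_threshold(p, mu, sigma), s)


def jit(p, s: JitSigmoid, mu: float, sigma: float):
    """SD (us) of the action-potential initiation period duration.

    Strictly decreasing in p; bounded in (0, a3) and floored at JIT_FLOOR.
    """
    return jit_from_x(effective_threshold(p, mu, sigma), s)


def fit_latency_functions(
    latency_samples,
    jitter_samples,
    mu: float,
    sigma: float,
) -> tuple[LatSigmoid, JitSigmoid]:
    """Fit the lat/jit sigmoids to (probability, statistic) calibration points.

    The fit is a trust-region nonlinear least squares carried out in the
    effective-threshold coordinate.  Requires >= 4 latency points and >= 3
    jitter points spanning p in (0, 1).

    Returns the fitted coefficient sets; raises :class:`FittingError` on
    underdetermined or degenerate input (e.g. constant latencies, for which
    the sigmoid height a3 collapses to zero).
    """
    lat_pts = np.asarray(latency_samples, dtype=float)
    jit_pts = np.asarray(jitter_samples, dtype=float)
    if lat_pts.ndim != 2 or lat_pts.shape[0] < 4:
        raise FittingError("need at least 4 (probability, mean latency) points")
    if jit_pts.ndim != 2 or jit_pts.shape[0] < 3:
        raise FittingError("need at least 3 (probability, jitter) points")

    x_lat = effective_threshold(lat_pts[:, 0], mu, sigma)
    y_lat = lat_pts[:, 1]
    x_jit = effective_threshold(jit_pts[:, 0], mu, sigma)
    y_jit = jit_pts[:, 1]
    if np.ptp(x_lat) <= 0 or np.ptp(x_jit) <= 0:
        raise FittingError("probabilities must span a non-degenerate range")

    def lat_model(x, a1, a2, a3, a4):
        return _sigmoid(x, a1, a2, a3) + a4

    def jit_model(x, a1, a2, a3):
        return _sigmoid(x, a1, a2, a3)

    height = float(np.ptp(y_lat))
    p0_lat = [mu, sigma, max(height, 1e-6), float(np.min(y_lat))]
    p0_jit = [mu, sigma, max(float(np.max(y_jit)), 1e-6)]
    try:
        popt_lat, _ = curve_fit(
            lat_model,
            x_lat,
            y_lat,
            p0=p0_lat,
            bounds=([-np.inf, 1e-6, 0.0, 0.0], np.inf),
            maxfev=20000,
        )
        popt_jit, _ = curve_fit(
            jit_model,
            x_jit,
            y_jit,
            p0=p0_jit,
            bounds=([-np.inf, 1e-6, 0.0], np.inf),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:  # no convergence / bad input
        raise FittingError(f"sigmoid fit failed: {exc}") from exc

    if popt_lat[2] < 1e-3 * max(1.0, abs(popt_lat[3])):
        raise FittingError("degenerate latency fit: sigmoid height a3 ~ 0")
    if popt_jit[2] < 1e-6:
        raise FittingError("degenerate jitter fit: sigmoid height a3 ~ 0")
    return LatSigmoid(*map(float, popt_lat)), JitSigmoid(*map(float, popt_jit))


def sigmoid_coefficients(s) -> tuple:
    """Coefficients of a sigmoid parameter set as a plain tuple."""
    return astuple(s)
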