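"""The temporal LIF (TLIF) neuron: realistic spike latency and jitter.

The TLIF neuron splits the action potential into three epochs: the threshold
crossing t0 (start of the initiation period), the end of the initiation
period t1, and the observed spike time t_spk.  The delay t1 - t0 is
exponentially distributed with a stimulus-dependent scale jit(P_TLIF(t)),
found causally as the fixed point of t -> t0 + Y jit(P_TLIF(t)); t_spk is
Gaussian about lat(p) with SD jit(p), where p = P_TLIF(t1) is the
probability that the membrane peak exceeded threshold during the initiation
period.  Firing probability itself is unchanged from the SLIF neuron.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .latency import jit, jit_from_x, lat
from .membrane import FiberParams, MembraneTrace, integrate_membrane, threshold_crossing
from .stimulus import PulseWaveform

__all__ = ["SpikeOutcome", "p_tlif", "draw_t1", "draw_tspk", "tlif_trial"]

#: Bisection tolerance (us) for the t1 fixed point.
T1_TOL = 0.01


@dataclass(frozen=True)
class SpikeOutcome:
    """Result of one simulated trial."""

    fired: bool
    canceled: bool = False
    t0: float | None = None  # us, threshold crossing
    t1: float | None = None  # us, end of initiation period
    t_spk: float | None = None  # us, observed spike time
    p_at_t1: float | None = None  # firing probability used for the latency draw

    def __post_init__(self) -> None:
        if self.fired:
            if self.t0 is None or self.t1 is None or self.t_spk is None:
                raise ValueError("fired outcomes need t0, t1 and t_spk")
            if self.t1 < self.t0:
                raise ValueError("t1 must not precede t0")
        elif self.t_spk is not None:
            raise ValueError("non-fired outcomes have no spike time")


def p_tlif(trace: MembraneTrace, t: float, p: FiberParams):
    """Probability that the membrane peak over [0, t] exceeds the threshold.

    Phi((V_peak(t) - mu)/sigma); non-decreasing in t, and equal to the
    analytic rectangular-pulse probability once the pulse has ended.
    """
    return norm.cdf((trace.peak_at(t) - p.mu) / p.sigma)


def draw_t1(
    trace: MembraneTrace,
    t0: float,
    p: FiberParams,
    rng: np.random.Generator,
    phi: float = 0.0,
) -> float:
    """Draw the end of the action-potential initiation period.

    With Y ~ Exp(1), t1 is the unique fixed point of

        t  ->  t0 + phi + Y * jit(P_TLIF(t)),

    located by bisection to 0.01 us.  jit(P_TLIF(t)) is non-increasing in t,
    so the fixed point is unique; the bracket [t0 + phi, t0 + phi + Y*a3] is
    guaranteed because jit is bounded by its low-level asymptote a3.  The
    delay t1 - t0 is never shorter than phi, and stimulus current after t1
    has no influence on it (causality).

    For phi = 0 this is the TLIF generation rule; the BLIF neuron passes its
    minimum initiation duration phi > 0, which makes the waiting-time clock
    start at t0 + phi, exactly matching the closed-form survival probability
    used by the semi-analytic engine.
    """
    y = rng.exponential(1.0)
    return _t1_fixed_point(trace, t0, p, y, phi)


def _t1_fixed_point(
    trace: MembraneTrace, t0: float, p: FiberParams, y: float, phi: float
) -> float:
    base = t0 + phi
    if y <= 0.0:
        return base
    # peak potential doubles as the effective-threshold coordinate of jit
    def excess(t):
        return t - base - y * float(jit_from_x(trace.peak_at(t), p.jit_params))

    lo = base
    hi = base + y * p.jit_params.a3 + T1_TOL
    if excess(lo) >= 0.0:
        return lo
    while hi - lo > T1_TOL:
        mid = 0.5 * (lo + hi)
        if excess(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def draw_tspk(
    t0: float, prob: float, p: FiberParams, rng: np.random.Generator
) -> float:
    """Draw the observed spike time t0 + X jit(p) + lat(p), X standard normal."""
    x = rng.standard_normal()
    mean = float(lat(prob, p.lat_params, p.mu, p.sigma))
    sd = float(jit(prob, p.jit_params, p.mu, p.sigma))
    return t0 + x * sd + mean


def tlif_trial(
    w: PulseWaveform, p: FiberParams, rng: np.random.Generator
) -> SpikeOutcome:
    """One TLIF trial.

    Draws, in order: theta (Normal), Y (unit-rate exponential), X (standard
    normal) from the provided stream.  Firing probability is identical to the
    SLIF neuron's for the same waveform.
    """
    trace = integrate_membrane(w, p)
    theta = rng.normal(p.mu, p.sigma)
    t0 = threshold_crossing(trace, theta)
    if t0 is None:
        return SpikeOutcome(fired=False)
    t1 = draw_t1(trace, t0, p, rng)
    prob = float(p_tlif(trace, t1, p))
    t_spk = draw_tspk(t0, prob, p, rng)
    return SpikeOutcome(
        fired=True, canceled=False, t0=t0, t1=t1, t_spk=t_spk, p_at_t1=prob
    )
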