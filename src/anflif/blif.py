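"""The biphasic LIF (BLIF) neuron: spike cancelation by net anodic charge.

After a threshold crossing at t0, the impending spike is canceled if the
cumulative stimulus charge since t0 becomes net positive (anodic) at any
time before the initiation period ends at t1.  The initiation period has a
minimum duration phi, so raising phi lengthens the window during which a
trailing anodic phase can cancel the spike, elevating biphasic thresholds
while leaving monophasic responses untouched.

The marginal firing probability has a semi-analytic form: integrate the
crossing-time density against the probability that the initiation period
ends before the cancelation time T_Q0,

    P_BLIF(t) = sum over crossing samples s <= t of
                dP_TLIF(s) * P_t1(T_Q0(s); s),

with the closed-form survival CDF

    P_t1(t; s) = 1 - exp(-(t - s - phi) / jit(P_TLIF(t)))   for t >= s + phi

(0 below s + phi, 1 at t = infinity).  For purely cathodic stimuli T_Q0 is
infinite everywhere and P_BLIF reduces exactly to P_TLIF.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .latency import jit_from_x
from .membrane import FiberParams, MembraneTrace, integrate_membrane, threshold_crossing
from .stimulus import PulseWaveform, first_net_anodic_time, first_net_anodic_times
from .tlif import SpikeOutcome, draw_t1, draw_tspk, p_tlif

__all__ = [
    "apply_min_initiation",
    "is_canceled",
    "p_t1",
    "p_t1_general",
    "p_blif",
    "firing_probability",
    "blif_trial",
]

#: Integration horizon past the stimulus end, in units of tau.  The peak and
#: the cancelation times are final after the pulse; the margin only has to
#: cover late initiation-period endings.
HORIZON_TAUS = 5.0


def apply_min_initiation(t0: float, t_fixed_point: float, phi: float) -> float:
    """Enforce the minimum initiation-period duration: max(t0 + phi, t_fixed_point).

    The generation rule in :func:`anflif.tlif.draw_t1` already starts the
    waiting-time clock at t0 + phi, so this clamp is a no-op on its output;
    it is kept as the explicit guarantee that t1 - t0 >= phi.
    """
    if t_fixed_point < t0:
        raise ValueError("t_fixed_point must not precede t0")
    if phi < 0:
        raise ValueError("phi must be non-negative")
    return max(t0 + phi, t_fixed_point)


def is_canceled(w: PulseWaveform, t0: float, t1: float) -> bool:
    """True iff the charge since t0 turns net anodic before the initiation period ends."""
    if t1 < t0:
        raise ValueError("t1 must not precede t0")
    return first_net_anodic_time(w, t0) < t1


def p_t1(t: float, s: float, trace: MembraneTrace, p: FiberParams) -> float:
    """Probability that the initiation period started at s has ended by time t.

    Closed form of the waiting-time CDF; ``t`` may be ``inf`` (returns 1).
    """
    if np.isinf(t):
        return 1.0
    wait = t - s - p.phi
    if wait <= 0.0:
        return 0.0
    scale = float(jit_from_x(trace.peak_at(t), p.jit_params))
    return float(1.0 - np.exp(-wait / scale))


def p_t1_general(
    t: float,
    s: float,
    trace: MembraneTrace,
    p: FiberParams,
    refine: int = 4,
) -> float:
    """General integral form of the initiation-period waiting-time CDF.

    Evaluates, by trapezoidal quadrature on a grid ``refine`` times finer
    than the sample grid,

        int_{s+phi}^{t} [lam(u) + (u-s-phi) lam'(u)] exp(-(u-s-phi) lam(u)) du

    with the hazard lam(u) = 1/jit(P_TLIF(u)).  Because lam increases
    monotonically with u, this integrand is an exact derivative and the
    integral collapses to the closed form of :func:`p_t1`; the quadrature
    therefore serves as an independent oracle for it.
    """
    if np.isinf(t):
        return 1.0
    a = s + p.phi
    if t <= a:
        return 0.0
    dt = trace.sample_interval / refine
    n = max(int(np.ceil((t - a) / dt)), 2)
    u = np.linspace(a, t, n + 1)
    lam = 1.0 / jit_from_x(trace.peak_at(u), p.jit_params)
    dlam = np.gradient(lam, u)
    wait = u - a
    integrand = (lam + wait * dlam) * np.exp(-wait * lam)
    return float(np.trapezoid(integrand, u))


def _blif_knot_probabilities(
    w: PulseWaveform, p: FiberParams, trace: MembraneTrace
) -> tuple[np.ndarray, bool]:
    """Cumulative P_BLIF at the trace knots; flags the pure-cathodic shortcut.

    Returns ``(P_knots, reduces_to_tlif)``.  The crossing-time distribution
    is discretized as per-sample increments of P_TLIF, each weighted by the
    closed-form survival probability evaluated for a crossing at that
    sample's edge.
    """
    peaks = trace.running_peak
    p_tlif_knots = norm.cdf((peaks - p.mu) / p.sigma)
    d_p = np.diff(p_tlif_knots)
    active = np.nonzero(d_p > 1e-300)[0]  # crossing lands at knot k+1
    if active.size == 0:
        return p_tlif_knots, True

    knot_idx = active + 1
    # cancelation times exist only within the waveform support
    in_support = knot_idx <= w.n_samples
    tq0 = np.full(knot_idx.shape, np.inf)
    if np.any(in_support):
        tq0[in_support] = first_net_anodic_times(w, knot_idx[in_support])
    if not np.any(np.isfinite(tq0)):
        return p_tlif_knots, True

    knots = trace.knot_times()
    s_times = knots[knot_idx]
    surv = np.ones_like(s_times)
    finite = np.isfinite(tq0)
    wait = tq0[finite] - s_times[finite] - p.phi
    scale = jit_from_x(trace.peak_at(tq0[finite]), p.jit_params)
    ratio = np.clip(wait / scale, 0.0, 700.0)  # negative wait -> survival 0
    surv[finite] = np.where(wait > 0.0, -np.expm1(-ratio), 0.0)

    p_knots = np.zeros_like(p_tlif_knots)
    p_knots[0] = p_tlif_knots[0]  # crossing before any stimulation (~0)
    increments = np.zeros(len(d_p))
    increments[active] = d_p[active] * surv
    p_knots[1:] = p_tlif_knots[0] + np.cumsum(increments)
    return p_knots, False


def p_blif(
    w: PulseWaveform,
    t: float,
    p: FiberParams,
    trace: MembraneTrace | None = None,
) -> float:
    """Marginal firing probability of the BLIF neuron up to time t.

    Non-decreasing in t and bounded above by P_TLIF(t); identical to
    P_TLIF(t) for purely cathodic stimuli.  ``t = inf`` gives the total
    firing probability.
    """
    if trace is None:
        trace = integrate_membrane(w, p, horizon=w.end_time + HORIZON_TAUS * p.tau)
    p_knots, reduces = _blif_knot_probabilities(w, p, trace)
    if reduces:
        return float(p_tlif(trace, min(t, trace.end_time), p))
    t_eff = min(t, trace.end_time)
    return float(np.interp(t_eff, trace.knot_times(), p_knots))


def firing_probability(w: PulseWaveform, p: FiberParams) -> float:
    """Total firing probability of the stimulus (P_BLIF at infinity)."""
    return p_blif(w, np.inf, p)


def blif_trial(
    w: PulseWaveform, p: FiberParams, rng: np.random.Generator
) -> SpikeOutcome:
    """One BLIF trial.

    Same draw order as the TLIF trial (theta, Y, then X for surviving
    spikes).  A canceled trial terminates as though no threshold crossing
    occurred: not fired, no spike time; the cancelation flag is kept for
    diagnostics.
    """
    trace = integrate_membrane(w, p, horizon=w.end_time + HORIZON_TAUS * p.tau)
    theta = rng.normal(p.mu, p.sigma)
    t0 = threshold_crossing(trace, theta)
    if t0 is None:
        return SpikeOutcome(fired=False)
    t_fp = draw_t1(trace, t0, p, rng, phi=p.phi)
    t1 = apply_min_initiation(t0, t_fp, p.phi)
    if is_canceled(w, t0, t1):
        return SpikeOutcome(fired=False, canceled=True, t0=t0, t1=t1)
    prob = p_blif(w, t1, p, trace=trace)
    t_spk = draw_tspk(t0, prob, p, rng)
    return SpikeOutcome(
        fired=True, canceled=False, t0=t0, t1=t1, t_spk=t_spk, p_at_t1=prob
    )
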