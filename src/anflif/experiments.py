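"""Derived response statistics: thresholds, input-output fits, sweeps.

Threshold searches use the deterministic semi-analytic firing probability;
Monte-Carlo simulation is used only for response statistics and for
cross-validating the deterministic engine.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit
from scipy.stats import norm

from .blif import HORIZON_TAUS, _blif_knot_probabilities, firing_probability
from .latency import jit_from_x, lat_from_x
from .membrane import FiberParams, IOFunction, integrate_membrane
from .stimulus import (
    PulseSpec,
    PulseWaveform,
    first_net_anodic_times,
    make_monophasic,
    make_waveform,
)

__all__ = [
    "ResponseStats",
    "ThresholdCurve",
    "find_threshold",
    "estimate_io",
    "simulate_trials",
    "response_statistics",
    "sweep",
    "db_ratio",
    "make_synthetic_latency_dataset",
]

SWEEP_VARIABLES = ("ipg", "phase_duration", "anodic_duration", "phi")


@dataclass(frozen=True)
class ResponseStats:
    """Aggregate outcome of repeated trials with one stimulus.

    Latency is measured from the waveform onset to the observed spike time,
    over fired trials only; jitter is its standard deviation.  Statistics are
    absent (None) when fewer than two trials fired.
    """

    n_trials: int
    fired: int
    canceled: int
    firing_probability: float
    mean_latency: float | None  # us
    jitter: float | None  # us

    def to_dict(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "fired": self.fired,
            "canceled": self.canceled,
            "p_fire": self.firing_probability,
            "mean_latency_us": self.mean_latency,
            "jitter_us": self.jitter,
        }


@dataclass(frozen=True)
class ThresholdCurve:
    """Thresholds across a parameter sweep, absolute and re a reference."""

    sweep_variable: str
    units: str
    values: np.ndarray
    thresholds: np.ndarray  # uA
    reference_threshold: float  # uA
    reference_description: str

    @property
    def thresholds_db(self) -> np.ndarray:
        return 20.0 * np.log10(self.thresholds / self.reference_threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.sweep_variable,
                "value": self.values,
                "threshold_uA": self.thresholds,
                "threshold_dB": self.thresholds_db,
            }
        )


def db_ratio(a: float, b: float) -> float:
    """Current-amplitude ratio in dB: 20 log10(a / b)."""
    if not (a > 0 and b > 0):
        raise ValueError("levels must be positive")
    return float(20.0 * np.log10(a / b))


def find_threshold(
    spec: PulseSpec,
    p: FiberParams,
    target_p: float = 0.5,
) -> float:
    """Stimulus level (uA, cathodic magnitude) at the target firing probability.

    Deterministic: solves firing_probability(level) = target_p by root
    bracketing on the semi-analytic engine.  The initial bracket is seeded
    by the analytic rectangular-pulse threshold of the cathodic phase and
    widened automatically if needed.
    """
    if not 0.0 < target_p < 1.0:
        raise ValueError("target_p must be in (0, 1)")

    def prob(level: float) -> float:
        return firing_probability(make_waveform(spec.with_amplitude(level)), p)

    # analytic SLIF threshold of the cathodic phase alone seeds the bracket
    x_target = p.mu + p.sigma * norm.ppf(target_p)
    guess = x_target / (p.R * (1.0 - np.exp(-spec.cathodic_duration / p.tau)))
    lo, hi = guess * 0.5, guess * 2.0
    for _ in range(60):
        if prob(lo) < target_p:
            break
        lo *= 0.5
    else:
        raise RuntimeError("could not bracket the threshold from below")
    for _ in range(60):
        if prob(hi) > target_p:
            break
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket the threshold from above")
    return float(brentq(lambda l: prob(l) - target_p, lo, hi, rtol=1e-7))


def estimate_io(levels, probabilities) -> IOFunction:
    """Fit a Gaussian-CDF input-output function to (level, probability) points."""
    levels = np.asarray(levels, dtype=float)
    probs = np.asarray(probabilities, dtype=float)
    if levels.size < 3 or levels.size != probs.size:
        raise ValueError("need at least 3 matched (level, probability) points")
    if np.ptp(levels) <= 0:
        raise ValueError("levels must span a non-degenerate range")
    m0 = float(levels[np.argmin(np.abs(probs - 0.5))])
    s0 = max(float(np.ptp(levels)) / 4.0, 1e-6)
    popt, _ = curve_fit(
        lambda l, m, s: norm.cdf((l - m) / s),
        levels,
        probs,
        p0=[m0, s0],
        bounds=([1e-12, 1e-12], np.inf),
        maxfev=20000,
    )
    return IOFunction(m=float(popt[0]), s=float(popt[1]))


def _rng_streams(rng: np.random.Generator | int, n: int) -> list[np.random.Generator]:
    if isinstance(rng, np.random.Generator):
        return rng.spawn(n)
    ss = np.random.SeedSequence(rng)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def simulate_trials(
    w: PulseWaveform,
    p: FiberParams,
    n_trials: int,
    rng: np.random.Generator | int,
    model: str = "blif",
) -> pd.DataFrame:
    """Vectorized ensemble of independent single-pulse trials.

    Statistically equivalent to repeated calls of the scalar trial functions
    (per trial: one threshold draw theta, one exponential draw Y, one normal
    draw X), but with each random variable drawn from its own child stream
    so that trial i's draws do not depend on ``n_trials``.

    ``model`` selects the readout: ``"slif"`` reports the threshold-crossing
    time t0 as the spike time; ``"tlif"`` disables cancelation and the
    minimum initiation period; ``"blif"`` is the full model.

    Returns a DataFrame with columns trial, fired, canceled, t0_us, t1_us,
    tspk_us.
    """
    if model not in ("slif", "tlif", "blif"):
        raise ValueError(f"unknown model {model!r}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    phi = p.phi if model == "blif" else 0.0
    trace = integrate_membrane(w, p, horizon=w.end_time + HORIZON_TAUS * p.tau)
    knots = trace.knot_times()
    peaks = trace.running_peak

    theta_rng, y_rng, x_rng = _rng_streams(rng, 3)
    theta = theta_rng.normal(p.mu, p.sigma, size=n_trials)
    t0_idx = np.searchsorted(peaks, theta, side="right")
    crossed = t0_idx < len(peaks)

    t0 = np.full(n_trials, np.nan)
    t1 = np.full(n_trials, np.nan)
    tspk = np.full(n_trials, np.nan)
    fired = np.zeros(n_trials, dtype=bool)
    canceled = np.zeros(n_trials, dtype=bool)

    if np.any(crossed):
        idx = t0_idx[crossed]
        t0c = knots[idx]
        y = y_rng.exponential(1.0, size=n_trials)[crossed]
        t1c = _t1_fixed_points(trace, t0c, y, phi, p)
        t1[crossed] = t1c
        t0[crossed] = t0c

        if model == "slif":
            fired[crossed] = True
            tspk[crossed] = t0c
        else:
            if model == "blif":
                tq0_by_knot = np.full(len(knots), np.inf)
                support = np.arange(w.n_samples + 1)
                tq0_by_knot[support] = first_net_anodic_times(w, support)
                surv = tq0_by_knot[idx] >= t1c
            else:
                surv = np.ones(len(t0c), dtype=bool)
            canceled[crossed] = ~surv
            fired[crossed] = surv

            if model == "blif":
                p_knots, reduces = _blif_knot_probabilities(w, p, trace)
                if reduces:
                    p_knots = norm.cdf((peaks - p.mu) / p.sigma)
            else:
                p_knots = norm.cdf((peaks - p.mu) / p.sigma)
            prob = np.interp(np.minimum(t1c, knots[-1]), knots, p_knots)
            x = x_rng.standard_normal(n_trials)[crossed]
            x_eff = p.mu + p.sigma * norm.ppf(np.clip(prob, 1e-9, 1 - 1e-9))
            draw = (
                t0c
                + x * jit_from_x(x_eff, p.jit_params)
                + lat_from_x(x_eff, p.lat_params)
            )
            tspk[crossed] = np.where(surv, draw, np.nan)
            tspk[crossed & ~fired] = np.nan

    return pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "fired": fired,
            "canceled": canceled,
            "t0_us": t0,
            "t1_us": t1,
            "tspk_us": np.where(fired, tspk, np.nan),
        }
    )


def _t1_fixed_points(trace, t0, y, phi, p: FiberParams) -> np.ndarray:
    """Vectorized bisection for the initiation-period fixed points."""
    knots = trace.knot_times()
    peaks = trace.running_peak
    base = t0 + phi
    lo = base.copy()
    hi = base + y * p.jit_params.a3 + 0.01
    span = float(np.max(hi - lo))
    n_iter = max(int(np.ceil(np.log2(span / 0.01))) + 1, 1)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        j = jit_from_x(np.interp(mid, knots, peaks), p.jit_params)
        below = mid - base - y * j < 0.0
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def response_statistics(
    w: PulseWaveform,
    p: FiberParams,
    n_trials: int,
    rng: np.random.Generator | int,
    model: str = "blif",
) -> ResponseStats:
    """Firing probability, mean latency and jitter over repeated trials.

    Latency runs from the waveform onset to the observed spike time; canceled
    and sub-threshold trials contribute to the non-fired count and are
    excluded from the latency statistics.
    """
    df = simulate_trials(w, p, n_trials, rng, model=model)
    fired = int(df["fired"].sum())
    canceled = int(df["canceled"].sum())
    lat_us = df.loc[df["fired"], "tspk_us"].to_numpy() - w.onset_time
    mean_latency = float(np.mean(lat_us)) if fired >= 2 else None
    jitter = float(np.std(lat_us, ddof=1)) if fired >= 2 else None
    return ResponseStats(
        n_trials=n_trials,
        fired=fired,
        canceled=canceled,
        firing_probability=fired / n_trials,
        mean_latency=mean_latency,
        jitter=jitter,
    )


def sweep(
    spec_template: PulseSpec,
    variable: str,
    values,
    p: FiberParams,
    target_p: float = 0.5,
) -> ThresholdCurve:
    """Threshold curve over one stimulus (or model) variable.

    ``variable`` is one of ``ipg``, ``phase_duration`` (both phases of a
    symmetric biphasic pulse), ``anodic_duration`` (pseudomonophasic second
    phase) or ``phi`` (the model's minimum initiation period).  Thresholds
    are reported in uA and in dB re the threshold of a monophasic pulse
    whose duration equals the cathodic phase.
    """
    if variable not in SWEEP_VARIABLES:
        raise ValueError(f"variable must be one of {SWEEP_VARIABLES}")
    values = np.asarray(values, dtype=float)
    thresholds = np.empty(values.shape)
    for i, v in enumerate(values):
        params = p
        spec = spec_template
        if variable == "ipg":
            spec = replace(spec_template, ipg=float(v))
        elif variable == "phase_duration":
            spec = replace(
                spec_template, cathodic_duration=float(v), anodic_duration=float(v)
            )
        elif variable == "anodic_duration":
            spec = replace(spec_template, anodic_duration=float(v))
        else:  # phi
            params = p.replace(phi=float(v))
        thresholds[i] = find_threshold(spec, params, target_p=target_p)

    ref_spec = PulseSpec(
        pulse_class="monophasic",
        cathodic_amplitude=spec_template.cathodic_amplitude,
        cathodic_duration=spec_template.cathodic_duration,
        sample_interval=spec_template.sample_interval,
    )
    reference = find_threshold(ref_spec, p, target_p=target_p)
    units = {"ipg": "us", "phase_duration": "us", "anodic_duration": "us", "phi": "us"}
    return ThresholdCurve(
        sweep_variable=variable,
        units=units[variable],
        values=values,
        thresholds=thresholds,
        reference_threshold=reference,
        reference_description=(
            f"monophasic threshold, {spec_template.cathodic_duration} us duration"
        ),
    )


def make_synthetic_latency_dataset(
    p: FiberParams,
    probabilities,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Synthetic (probability, mean latency, jitter) calibration table.

    Rows are generated from the fiber's lat/jit sigmoids, optionally with
    additive Gaussian noise of SD ``noise_sd`` (us) on both statistics.  This
    stands in for empirical single-fiber calibration data when exercising
    :func:`anflif.latency.fit_latency_functions` end to end.
    """
    probs = np.asarray(probabilities, dtype=float)
    if probs.size and (np.any(probs <= 0.0) or np.any(probs >= 1.0)):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    x = p.mu + p.sigma * norm.ppf(probs) if probs.size else np.array([])
    mean_lat = lat_from_x(x, p.lat_params)
    jitter = jit_from_x(x, p.jit_params)
    if noise_sd > 0.0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        mean_lat = mean_lat + gen.normal(0.0, noise_sd, size=probs.shape)
        jitter = jitter + gen.normal(0.0, noise_sd, size=probs.shape)
    return pd.DataFrame(
        {
            "probability": probs,
            "mean_latency_us": mean_lat,
            "jitter_us": jitter,
        }
    )


def monophasic_threshold(duration: float, p: FiberParams, target_p: float = 0.5) -> float:
    """Analytic monophasic threshold at the target probability (rectangular pulse)."""
    x_target = p.mu + p.sigma * norm.ppf(target_p)
    return float(x_target / (p.R * (1.0 - np.exp(-duration / p.tau))))
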