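"""Leaky membrane integration and the stochastic-threshold (SLIF) neuron.

The membrane is a leaky integrator of the stimulus current,

    tau dV/dt = -R I - V,        V(0) = 0,

so cathodic (negative) current depolarizes the model: a constant cathodic
sample of magnitude A produces the step response V(t) = A R (1 - exp(-t/tau)).
A spike is initiated at the first time V exceeds a per-trial Gaussian
threshold theta ~ N(mu, sigma).  With R = 1 Ohm, voltages in uV and currents
in uA are numerically interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from scipy.signal import lfilter
from scipy.stats import norm

from .latency import JitSigmoid, LatSigmoid
from .stimulus import PulseWaveform

__all__ = [
    "FiberParams",
    "MembraneTrace",
    "IOFunction",
    "table1",
    "integrate_membrane",
    "p_slif",
    "slif_trial",
    "invert_io",
    "strength_duration_threshold",
    "tau_from_chronaxie",
]


@dataclass(frozen=True)
class FiberParams:
    """Full parameter set of one model fiber.

    Defaults are the reference cat auditory-nerve-fiber parameterization:
    mu = 104.5 uV, sigma = 4.595 uV, tau = 248.4 us, phi = 37.81 us, with the
    standard lat/jit sigmoid coefficients.  Set ``phi = 0`` for pure TLIF
    behavior (no minimum initiation-period duration).
    """

    mu: float = 104.5  # uV, mean of the threshold theta
    sigma: float = 4.595  # uV, SD of theta
    tau: float = 248.4  # us, membrane time constant
    R: float = 1.0  # Ohm, membrane resistance (fixed)
    phi: float = 37.81  # us, minimum initiation-period duration (BLIF)
    lat_params: LatSigmoid = field(default_factory=LatSigmoid)
    jit_params: JitSigmoid = field(default_factory=JitSigmoid)

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.sigma > 0 and self.tau > 0):
            raise ValueError("mu, sigma, tau must be positive")
        if self.phi < 0:
            raise ValueError("phi must be non-negative")
        if self.R != 1.0:
            raise ValueError("membrane resistance R is fixed at 1 Ohm")

    def replace(self, **kwargs) -> "FiberParams":
        return replace(self, **kwargs)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "tau": self.tau,
            "R": self.R,
            "phi": self.phi,
            "lat_params": vars(self.lat_params).copy(),
            "jit_params": vars(self.jit_params).copy(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FiberParams":
        d = dict(d)
        lat_d = d.pop("lat_params", None)
        jit_d = d.pop("jit_params", None)
        kwargs = dict(d)
        if lat_d is not None:
            kwargs["lat_params"] = LatSigmoid(**lat_d)
        if jit_d is not None:
            kwargs["jit_params"] = JitSigmoid(**jit_d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FiberParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def table1() -> FiberParams:
    """The packaged reference parameter set (cat ANF)."""
    text = resources.files("anflif.data").joinpath("table1.yaml").read_text()
    return FiberParams.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class MembraneTrace:
    """Membrane potential and its running peak on the sample-edge grid.

    ``potential[k]`` is V at time ``onset_time + k * sample_interval``;
    ``running_peak[k] = max(potential[:k+1])`` is non-decreasing.  Queries at
    arbitrary times interpolate linearly between edges and clamp beyond the
    integrated range (the peak is final once the stimulus has ended).
    """

    potential: np.ndarray  # uV, length n+1
    running_peak: np.ndarray  # uV, length n+1
    sample_interval: float
    onset_time: float = 0.0

    @property
    def end_time(self) -> float:
        return self.onset_time + (len(self.potential) - 1) * self.sample_interval

    def knot_times(self) -> np.ndarray:
        return self.onset_time + self.sample_interval * np.arange(len(self.potential))

    def potential_at(self, t):
        return np.interp(t, self.knot_times(), self.potential)

    def peak_at(self, t):
        """Running peak at time ``t`` (final value past the integrated range)."""
        return np.interp(t, self.knot_times(), self.running_peak)


def integrate_membrane(
    w: PulseWaveform, p: FiberParams, horizon: float | None = None
) -> MembraneTrace:
    """Integrate the membrane equation over the waveform.

    Uses the exact exponential update for piecewise-constant input,

        V[k+1] = V[k] a + R (-I[k]) (1 - a),      a = exp(-dt/tau),

    which is bit-stable and exact for rectangular pulses at the sample edges.

    Parameters
    ----------
    horizon
        Absolute end time of the integration (us); the stimulus is
        zero-padded past its end.  Defaults to the waveform end.
    """
    dt = w.sample_interval
    samples = w.samples
    if horizon is not None and horizon > w.end_time:
        extra = int(np.ceil((horizon - w.end_time) / dt - 1e-12))
        samples = np.concatenate([samples, np.zeros(extra)])
    a = np.exp(-dt / p.tau)
    drive = -p.R * samples * (1.0 - a)
    v = lfilter([1.0], [1.0, -a], drive)
    potential = np.concatenate(([0.0], v))
    running_peak = np.maximum.accumulate(potential)
    return MembraneTrace(potential, running_peak, dt, w.onset_time)


def p_slif(level: float, duration: float, p: FiberParams) -> float:
    """Analytic firing probability of a rectangular cathodic pulse.

    ``level`` is the cathodic magnitude (uA); the probability is
    Phi((level * R * (1 - exp(-d/tau)) - mu) / sigma), strictly increasing in
    level.
    """
    if not level > 0:
        raise ValueError("level must be positive")
    if not duration > 0:
        raise ValueError("duration must be positive")
    peak = level * p.R * (1.0 - np.exp(-duration / p.tau))
    return float(norm.cdf((peak - p.mu) / p.sigma))


def threshold_crossing(trace: MembraneTrace, theta: float) -> float | None:
    """First sample-edge time with V > theta (strict), or None."""
    idx = int(np.searchsorted(trace.running_peak, theta, side="right"))
    if idx >= len(trace.running_peak):
        return None
    return float(trace.onset_time + idx * trace.sample_interval)


def slif_trial(
    w: PulseWaveform, p: FiberParams, rng: np.random.Generator
) -> float | None:
    """One SLIF trial: draw theta ~ N(mu, sigma), return the crossing time t0 or None."""
    theta = rng.normal(p.mu, p.sigma)
    trace = integrate_membrane(w, p)
    return threshold_crossing(trace, theta)


def invert_io(m: float, rs: float, duration: float, tau: float) -> tuple[float, float]:
    """Invert the input-output map: (threshold m, relative spread rs) -> (mu, sigma).

    mu = m (1 - exp(-d/tau)) and sigma = rs * mu, so that a fiber with these
    parameters has threshold exactly ``m`` for a cathodic pulse of the given
    duration, with relative spread ``rs`` at any duration.
    """
    if not (m > 0 and rs > 0 and duration > 0 and tau > 0):
        raise ValueError("all inputs must be positive")
    scale = 1.0 - np.exp(-duration / tau)
    mu = m * scale
    sigma = rs * m * scale
    return float(mu), float(sigma)


def strength_duration_threshold(duration: float, rheobase: float, tau: float) -> float:
    """Threshold level I0 / (1 - exp(-d/tau)) of a cathodic pulse of the given duration.

    Monotonically decreasing in duration, approaching the rheobase I0; equals
    twice the rheobase at the chronaxie d = tau ln 2.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    if not (rheobase > 0 and tau > 0):
        raise ValueError("rheobase and tau must be positive")
    return float(rheobase / (1.0 - np.exp(-duration / tau)))


def tau_from_chronaxie(chronaxie: float) -> float:
    """Membrane time constant from the measured chronaxie: tau = chronaxie / ln 2."""
    if not chronaxie > 0:
        raise ValueError("chronaxie must be positive")
    return float(chronaxie / np.log(2.0))


@dataclass(frozen=True)
class IOFunction:
    """Gaussian-CDF input-output function: firing probability Phi((l - m)/s)."""

    m: float  # uA, threshold level (p = 0.5)
    s: float  # uA, SD (dynamic-range width)

    def __post_init__(self) -> None:
        if not (self.m > 0 and self.s > 0):
            raise ValueError("m and s must be positive")

    @property
    def rs(self) -> float:
        """Relative spread s/m, a normalized dynamic-range measure."""
        return self.s / self.m

    def probability(self, level):
        return norm.cdf((np.asarray(level, dtype=float) - self.m) / self.s)
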