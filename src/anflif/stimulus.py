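"""Sampled current waveforms for single-pulse electrical stimulation.

Sign convention: cathodic (excitatory) current is *negative*, anodic current
is *positive*.  Amplitudes are in microamperes, times in microseconds.  A
waveform is a uniformly sampled, piecewise-constant current: sample ``k``
carries the current on the half-open interval ``[onset + k*dt, onset +
(k+1)*dt)``, which makes the charge of rectangular phases exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "PulseWaveform",
    "PulseSpec",
    "make_monophasic",
    "make_biphasic",
    "make_pseudomonophasic",
    "make_waveform",
    "cumulative_charge",
    "first_net_anodic_time",
]

DEFAULT_SAMPLE_INTERVAL = 1.0  # us (1 MHz)

PulseClass = Literal["monophasic", "biphasic", "pseudomonophasic"]


@dataclass(frozen=True)
class PulseWaveform:
    """A uniformly sampled stimulus current I(t).

    Parameters
    ----------
    samples
        Current per sample in uA (signed; cathodic negative).
    sample_interval
        Duration of one sample in us (> 0).
    onset_time
        Time of the first sample in us (normally 0).
    """

    samples: np.ndarray
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL
    onset_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("all samples must be finite")
        if not self.sample_interval > 0:
            raise ValueError("sample_interval must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples * self.sample_interval

    @property
    def end_time(self) -> float:
        return self.onset_time + self.duration

    def knot_times(self) -> np.ndarray:
        """Times of the sample edges (length ``n_samples + 1``)."""
        return self.onset_time + self.sample_interval * np.arange(self.n_samples + 1)

    def charge_knots(self) -> np.ndarray:
        """Cumulative charge from onset at every sample edge (uA*us).

        The cumulative charge of a piecewise-constant current is continuous
        and piecewise linear; these are its knot values.
        """
        return np.concatenate(([0.0], np.cumsum(self.samples) * self.sample_interval))

    def charge_at(self, t: float | np.ndarray) -> np.ndarray | float:
        """Cumulative charge from onset to time ``t`` (zero-padded past the end)."""
        return np.interp(t, self.knot_times(), self.charge_knots())


@dataclass(frozen=True)
class PulseSpec:
    """Declarative description of a stimulus pulse.

    For pseudomonophasic pulses the anodic amplitude is not a field: it is
    derived from charge balance as
    ``cathodic_amplitude * cathodic_duration / anodic_duration``.
    """

    pulse_class: PulseClass = "monophasic"
    cathodic_amplitude: float = 1.0  # uA, positive magnitude
    cathodic_duration: float = 40.0  # us
    anodic_duration: float = 0.0  # us (biphasic / pseudomonophasic)
    ipg: float = 0.0  # us
    leading_polarity: Literal["cathodic", "anodic"] = "cathodic"
    sample_interval: float = field(default=DEFAULT_SAMPLE_INTERVAL)

    def __post_init__(self) -> None:
        if self.pulse_class not in ("monophasic", "biphasic", "pseudomonophasic"):
            raise ValueError(f"unknown pulse_class {self.pulse_class!r}")
        if not self.cathodic_amplitude > 0:
            raise ValueError("cathodic_amplitude must be positive")
        if self.cathodic_duration < 0 or self.anodic_duration < 0 or self.ipg < 0:
            raise ValueError("durations and ipg must be non-negative")
        if self.leading_polarity not in ("cathodic", "anodic"):
            raise ValueError("leading_polarity must be 'cathodic' or 'anodic'")

    def with_amplitude(self, amplitude: float) -> "PulseSpec":
        return replace(self, cathodic_amplitude=float(amplitude))

    def to_dict(self) -> dict:
        return {
            "pulse_class": self.pulse_class,
            "cathodic_amplitude": self.cathodic_amplitude,
            "cathodic_duration": self.cathodic_duration,
            "anodic_duration": self.anodic_duration,
            "ipg": self.ipg,
            "leading_polarity": self.leading_polarity,
            "sample_interval": self.sample_interval,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PulseSpec":
        return cls(**d)


def _n_samples(duration: float, dt: float) -> int:
    n = int(round(duration / dt))
    if not np.isclose(n * dt, duration, rtol=1e-9, atol=1e-9):
        raise ValueError(
            f"duration {duration} us is not a multiple of the sample interval {dt} us"
        )
    return n


def make_monophasic(
    amplitude: float,
    duration: float,
    sample_interval: float = DEFAULT_SAMPLE_INTERVAL,
) -> PulseWaveform:
    """Single rectangular cathodic phase: value ``-amplitude`` on [0, duration)."""
    if not amplitude > 0:
        raise ValueError("amplitude must be positive")
    if not duration > 0:
        raise ValueError("duration must be positive")
    n = _n_samples(duration, sample_interval)
    return PulseWaveform(np.full(n, -amplitude), sample_interval)


def make_biphasic(spec: PulseSpec) -> PulseWaveform:
    """Charge-balanced symmetric biphasic pulse: cathodic, gap, anodic.

    The anodic phase has the same amplitude as the cathodic one.  An
    ``anodic_duration`` of 0 means "same as cathodic".
    """
    anodic = spec.anodic_duration or spec.cathodic_duration
    if anodic != spec.cathodic_duration:
        raise ValueError(
            "make_biphasic builds symmetric pulses; use make_pseudomonophasic "
            "for unequal phase durations"
        )
    return _two_phase(
        spec.cathodic_amplitude,
        spec.cathodic_duration,
        spec.ipg,
        spec.cathodic_amplitude,
        anodic,
        spec.leading_polarity,
        spec.sample_interval,
    )


def make_pseudomonophasic(spec: PulseSpec) -> PulseWaveform:
    """Charge-balanced asymmetric pulse; the anodic amplitude is scaled down.

    The anodic amplitude equals
    ``cathodic_amplitude * cathodic_duration / anodic_duration`` so that the
    net charge is zero.
    """
    if not spec.anodic_duration > 0:
        raise ValueError("anodic_duration must be positive for pseudomonophasic pulses")
    if not spec.cathodic_duration > 0:
        raise ValueError("cathodic_duration must be positive")
    anodic_amplitude = (
        spec.cathodic_amplitude * spec.cathodic_duration / spec.anodic_duration
    )
    return _two_phase(
        spec.cathodic_amplitude,
        spec.cathodic_duration,
        spec.ipg,
        anodic_amplitude,
        spec.anodic_duration,
        spec.leading_polarity,
        spec.sample_interval,
    )


def _two_phase(
    cathodic_amplitude: float,
    cathodic_duration: float,
    ipg: float,
    anodic_amplitude: float,
    anodic_duration: float,
    leading_polarity: str,
    dt: float,
) -> PulseWaveform:
    if not cathodic_amplitude > 0:
        raise ValueError("cathodic_amplitude must be positive")
    if ipg < 0:
        raise ValueError("ipg must be non-negative")
    nc = _n_samples(cathodic_duration, dt)
    ng = _n_samples(ipg, dt)
    na = _n_samples(anodic_duration, dt)
    if nc == 0 or na == 0:
        raise ValueError("phase durations must be positive")
    cath = np.full(nc, -cathodic_amplitude)
    anod = np.full(na, anodic_amplitude)
    gap = np.zeros(ng)
    if leading_polarity == "cathodic":
        samples = np.concatenate([cath, gap, anod])
    else:
        samples = np.concatenate([anod, gap, cath])
    return PulseWaveform(samples, dt)


def make_waveform(spec: PulseSpec) -> PulseWaveform:
    """Build the waveform described by ``spec`` (dispatch on pulse class)."""
    if spec.pulse_class == "monophasic":
        return make_monophasic(
            spec.cathodic_amplitude, spec.cathodic_duration, spec.sample_interval
        )
    if spec.pulse_class == "biphasic":
        return make_biphasic(spec)
    return make_pseudomonophasic(spec)


def cumulative_charge(w: PulseWaveform, t_ref: float, t: float) -> float:
    """Charge delivered on [t_ref, t] in uA*us.

    Additive over adjacent intervals; times past the waveform end are treated
    as zero current.
    """
    if t < t_ref:
        raise ValueError("t must be >= t_ref")
    if t_ref < w.onset_time:
        raise ValueError("t_ref must lie within the waveform support")
    return float(w.charge_at(t) - w.charge_at(t_ref))


def _charge_tolerance(charge_knots: np.ndarray) -> float:
    # Guards against round-off in the cumulative sum of a charge-balanced
    # pulse being mistaken for net anodic charge.
    scale = float(np.max(np.abs(charge_knots))) if charge_knots.size else 1.0
    return 1e-9 * max(scale, 1.0)


def first_net_anodic_time(w: PulseWaveform, t_ref: float) -> float:
    """First sample-edge time after ``t_ref`` with net positive charge since ``t_ref``.

    Returns ``inf`` if the cumulative charge never becomes positive (e.g. a
    purely cathodic pulse), in which case no spike cancelation can occur.
    """
    if t_ref < w.onset_time or t_ref > w.end_time:
        raise ValueError("t_ref must lie within the waveform support")
    knots = w.knot_times()
    charge = w.charge_knots()
    q_ref = float(np.interp(t_ref, knots, charge))
    tol = _charge_tolerance(charge)
    start = int(np.searchsorted(knots, t_ref, side="right"))
    rel = charge[start:] - q_ref
    hits = np.nonzero(rel > tol)[0]
    if hits.size == 0:
        return float("inf")
    return float(knots[start + hits[0]])


def first_net_anodic_times(w: PulseWaveform, knot_indices: np.ndarray) -> np.ndarray:
    """Vectorized :func:`first_net_anodic_time` for reference sample edges.

    ``knot_indices`` are indices into ``w.knot_times()``.  Used by the
    semi-analytic firing-probability engine, which needs the cancelation time
    for every potential crossing sample.
    """
    knots = w.knot_times()
    charge = w.charge_knots()
    tol = _charge_tolerance(charge)
    out = np.full(len(knot_indices), np.inf)
    for j, k in enumerate(np.asarray(knot_indices, dtype=int)):
        rel = charge[k + 1 :] - charge[k]
        hits = np.nonzero(rel > tol)[0]
        if hits.size:
            out[j] = knots[k + 1 + hits[0]]
    return out
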