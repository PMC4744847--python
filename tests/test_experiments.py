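import numpy as np
import pytest
from scipy.stats import norm

from anflif import (
    PulseSpec,
    db_ratio,
    estimate_io,
    find_threshold,
    make_monophasic,
    make_synthetic_latency_dataset,
    make_waveform,
    p_slif,
    response_statistics,
    simulate_trials,
    sweep,
)
from conftest import THRESHOLD_40US


class TestFindThreshold:
    def test_monophasic_matches_closed_form(self, params):
        thr = find_threshold(PulseSpec("monophasic", 1.0, 40.0), params)
        assert thr == pytest.approx(THRESHOLD_40US, rel=1e-3)

    @pytest.mark.parametrize("duration", [20.0, 40.0, 100.0, 300.0])
    def test_strength_duration_identity(self, params, duration):
        # threshold(d) * (1 - exp(-d/tau)) is the constant mu
        thr = find_threshold(PulseSpec("monophasic", 1.0, duration), params)
        assert thr * (1.0 - np.exp(-duration / params.tau)) == pytest.approx(
            params.mu, rel=1e-4
        )

    def test_biphasic_threshold_grows_with_phi(self, params, biphasic_spec):
        low = find_threshold(biphasic_spec, params.replace(phi=0.0))
        high = find_threshold(biphasic_spec, params)
        assert high > low

    def test_deterministic_and_monte_carlo_thresholds_agree(self, params, biphasic_spec):
        # within 0.1 dB, via a Gaussian-CDF fit to simulated firing fractions
        thr = find_threshold(biphasic_spec, params)
        levels = thr * np.array([0.95, 0.975, 1.0, 1.025, 1.05])
        fractions = [
            simulate_trials(make_waveform(biphasic_spec.with_amplitude(l)),
                            params, 20_000, 31 + i)["fired"].mean()
            for i, l in enumerate(levels)
        ]
        io = estimate_io(levels, fractions)
        assert abs(db_ratio(io.m, thr)) < 0.1

    def test_invalid_target_rejected(self, params):
        with pytest.raises(ValueError):
            find_threshold(PulseSpec("monophasic", 1.0, 40.0), params, target_p=1.5)


class TestEstimateIO:
    def _levels(self, params, qs=(0.05, 0.15, 0.3, 0.5, 0.7, 0.85, 0.95)):
        c = 1.0 - np.exp(-40.0 / params.tau)
        return np.array([(params.mu + params.sigma * norm.ppf(q)) / c for q in qs])

    def test_recovers_analytic_io(self, params):
        levels = self._levels(params)
        probs = [p_slif(l, 40.0, params) for l in levels]
        io = estimate_io(levels, probs)
        assert io.m == pytest.approx(THRESHOLD_40US, rel=0.005)
        assert io.rs == pytest.approx(params.sigma / params.mu, rel=0.02)

    def test_sigma_scaling(self, params):
        doubled = params.replace(sigma=2 * params.sigma)
        levels = self._levels(doubled)
        probs = [p_slif(l, 40.0, doubled) for l in levels]
        io = estimate_io(levels, probs)
        base_probs = [p_slif(l, 40.0, params) for l in self._levels(params)]
        base = estimate_io(self._levels(params), base_probs)
        assert io.m == pytest.approx(base.m, rel=0.01)
        assert io.s == pytest.approx(2.0 * base.s, rel=0.01)

    def test_seven_percent_reparameterization(self, params):
        # sigma = 7.315 uV makes the monophasic relative spread 7%
        wide = params.replace(sigma=7.315)
        levels = self._levels(wide)
        probs = [p_slif(l, 40.0, wide) for l in levels]
        io = estimate_io(levels, probs)
        assert round(100.0 * io.rs, 1) == 7.0

    @pytest.mark.parametrize("duration", [20.0, 40.0, 100.0, 200.0])
    def test_rs_duration_invariance(self, params, duration):
        c = 1.0 - np.exp(-duration / params.tau)
        levels = np.array(
            [(params.mu + params.sigma * norm.ppf(q)) / c
             for q in (0.05, 0.2, 0.5, 0.8, 0.95)]
        )
        probs = [p_slif(l, duration, params) for l in levels]
        io = estimate_io(levels, probs)
        assert io.rs == pytest.approx(params.sigma / params.mu, rel=0.02)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_io([1.0, 1.0, 1.0], [0.2, 0.5, 0.8])


class TestResponseStatistics:
    def test_slif_mode_threshold_latency(self, params, threshold_pulse):
        stats = response_statistics(threshold_pulse, params, 20_000, 17, model="slif")
        assert stats.mean_latency == pytest.approx(38.0, abs=3.0)
        assert stats.jitter == pytest.approx(1.1, abs=0.5)
        assert stats.fired + (stats.n_trials - stats.fired) == stats.n_trials

    def test_latency_shrinks_with_level(self, params):
        c = 1.0 - np.exp(-40.0 / params.tau)
        stats = {}
        for q in (0.1, 0.9):
            level = (params.mu + params.sigma * norm.ppf(q)) / c
            stats[q] = response_statistics(
                make_monophasic(level, 40.0), params, 20_000, 23
            )
        assert stats[0.9].mean_latency < stats[0.1].mean_latency
        assert stats[0.9].jitter < stats[0.1].jitter

    def test_absent_statistics_without_spikes(self, params):
        w = make_monophasic(1.0, 40.0)  # hopelessly sub-threshold
        stats = response_statistics(w, params, 1, 0)
        assert stats.firing_probability == 0.0
        assert stats.mean_latency is None and stats.jitter is None


class TestSweep:
    def test_ipg_sweep_monotone_with_asymptote(self, params):
        curve = sweep(
            PulseSpec("biphasic", 1.0, 100.0), "ipg", [0.0, 50.0, 150.0, 300.0], params
        )
        assert np.all(np.diff(curve.thresholds) <= 0.0)
        assert curve.thresholds_db[-1] < 0.1  # back at the monophasic threshold

    def test_phase_duration_sweep_decreasing(self, params):
        curve = sweep(
            PulseSpec("biphasic", 1.0, 40.0), "phase_duration",
            [20.0, 40.0, 80.0, 160.0], params,
        )
        assert np.all(np.diff(curve.thresholds) < 0.0)

    def test_phi_sweep_matches_find_threshold(self, params, biphasic_spec):
        curve = sweep(biphasic_spec, "phi", [1.0, 60.0], params)
        direct = find_threshold(biphasic_spec, params.replace(phi=60.0))
        assert curve.thresholds[1] == pytest.approx(direct, rel=1e-6)
        frame = curve.to_frame()
        assert list(frame.columns) == ["variable", "value", "threshold_uA", "threshold_dB"]

    def test_unknown_variable_rejected(self, params, biphasic_spec):
        with pytest.raises(ValueError):
            sweep(biphasic_spec, "amplitude", [1.0], params)


class TestSmallPieces:
    def test_db_ratio(self):
        assert db_ratio(5.0, 5.0) == 0.0
        assert db_ratio(10.0, 5.0) == pytest.approx(6.0206, abs=1e-3)
        assert db_ratio(3.0, 7.0) == pytest.approx(-db_ratio(7.0, 3.0))
        with pytest.raises(ValueError):
            db_ratio(-1.0, 1.0)

    def test_synthetic_dataset_values(self, params):
        df = make_synthetic_latency_dataset(params, [0.5])
        assert df.loc[0, "mean_latency_us"] == pytest.approx(682.659, abs=0.01)
        assert df.loc[0, "jitter_us"] == pytest.approx(108.856, abs=0.01)

    def test_synthetic_dataset_empty(self, params):
        df = make_synthetic_latency_dataset(params, [])
        assert len(df) == 0

    def test_synthetic_dataset_validates_probabilities(self, params):
        with pytest.raises(ValueError):
            make_synthetic_latency_dataset(params, [0.0, 0.5])
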