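"""Trigger/switch state-machine semantics, invariants, and oracle equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_trigger
from triggerbench.signal_bank import DigitizedTrace
from triggerbench.trigger_core import (
    PulseTrain,
    SwitchConfig,
    TriggerConfig,
    TriggerState,
    run_switch,
    run_trigger,
    step,
)


def counts_trace(values, period_us):
    return DigitizedTrace(np.asarray(values), rate=1e6 / period_us)


class TestStepSemantics:
    def test_fixed_duration_quantized_to_sample_period(self):
        # 10 ms minimum at 160 us/sample terminates on the 63rd tick: 10.080 ms
        cfg = TriggerConfig(6250.0, threshold=50, min_pulse_duration=10_000.0,
                            pulse_increment=0.0)
        train = run_trigger(cfg, counts_trace([500] * 100, 160.0))
        assert train.durations[0] == pytest.approx(10_080.0, abs=1e-6)

    def test_subthreshold_input_never_fires(self):
        cfg = TriggerConfig(1000.0, threshold=100)
        train = run_trigger(cfg, counts_trace([100, 50, 0, 99] * 10, 1000.0))
        assert len(train) == 0 and not train.open_end

    def test_hand_enumerated_tick_table(self):
        # 1 kHz, threshold 100, min 2 ms, refractory 5 ms:
        # onset at t=1 ms, low at t=3 ms, the crossing at t=5 ms suppressed
        cfg = TriggerConfig(1000.0, threshold=100, min_pulse_duration=2000.0,
                            pulse_increment=0.0, refractory_period=5000.0)
        samples = [0, 200, 0, 0, 0, 200, 0, 0, 0, 0]
        train = run_trigger(cfg, counts_trace(samples, 1000.0))
        assert list(train.onsets) == [1000.0]
        assert list(train.offsets) == [3000.0]

    def test_refractory_allows_one_pulse_per_beep(self):
        # two 340 ms supra beeps, onsets 1 s apart, refractory 800 ms -> 2 pulses
        cfg = TriggerConfig(1000.0, threshold=100, min_pulse_duration=10_000.0,
                            pulse_increment=0.0, refractory_period=800_000.0)
        v = np.zeros(1500)
        v[100:440] = 500   # beep 1 at 100 ms
        v[1100:1440] = 500  # beep 2 at 1100 ms
        train = run_trigger(cfg, counts_trace(v, 1000.0))
        assert list(train.onsets) == [100_000.0, 1_100_000.0]

    def test_min_zero_increment_zero_gives_one_sample_pulse(self):
        cfg = TriggerConfig(1000.0, threshold=10, min_pulse_duration=0.0)
        train = run_trigger(cfg, counts_trace([0, 500, 500, 0, 0], 1000.0))
        assert train.durations[0] == pytest.approx(1000.0)

    def test_increment_sustains_through_gaps(self):
        # increment 3 ms sustains across a 2 ms input gap but not a 4 ms one
        cfg = TriggerConfig(1000.0, threshold=10, min_pulse_duration=1000.0,
                            pulse_increment=3000.0)
        v = [0, 500, 500, 0, 0, 500, 0, 0, 0, 0, 0, 0, 500, 0, 0, 0, 0, 0]
        train = run_trigger(cfg, counts_trace(v, 1000.0))
        # last supra of first event at t=5 ms -> low at t=8 ms; new onset at 12 ms
        assert list(train.onsets) == [1000.0, 12_000.0]
        assert train.offsets[0] == pytest.approx(8000.0)

    def test_non_monotone_time_rejected(self):
        cfg = TriggerConfig(1000.0, threshold=10)
        state = TriggerState()
        step(cfg, state, 0, 0.0)
        with pytest.raises(ValueError, match="non-monotone"):
            step(cfg, state, 0, 0.0)

    def test_empty_trace_gives_empty_train(self):
        cfg = TriggerConfig(1000.0)
        train = run_trigger(cfg, counts_trace([], 1000.0))
        assert len(train) == 0

    def test_dc_falling_polarity_triggers_on_drops(self):
        cfg = TriggerConfig(1000.0, threshold=300, mode="dc", polarity="falling",
                            min_pulse_duration=1000.0)
        v = [500, 500, 100, 100, 500, 500]
        train = run_trigger(cfg, counts_trace(v, 1000.0))
        assert list(train.onsets) == [2000.0]


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sampling_frequency": 0.0},
            {"sampling_frequency": 1000.0, "threshold": 1024},
            {"sampling_frequency": 1000.0, "threshold": -1},
            {"sampling_frequency": 1000.0, "min_pulse_duration": -1.0},
            {"sampling_frequency": 1000.0, "refractory_period": -5.0},
            {"sampling_frequency": 1000.0, "mode": "banana"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TriggerConfig(**kwargs)

    def test_pulse_train_rejects_nonalternating_edges(self):
        with pytest.raises(ValueError):
            PulseTrain(np.array([0.0, 5.0]), np.array([10.0, 20.0]))


class TestSwitch:
    def test_no_closure_no_events(self):
        cfg = SwitchConfig(1000.0, debounce_time=5000.0)
        train = run_switch(cfg, counts_trace(np.zeros(100), 1000.0))
        assert len(train) == 0

    def test_bounces_rejected_stable_run_timestamped_at_first_closure(self):
        # 3 bounce transitions inside 2 ms then a stable >=5 ms closure
        cfg = SwitchConfig(1000.0, debounce_time=5000.0, refractory_period=0.0)
        v = np.zeros(40, dtype=bool)
        v[10] = v[12] = True          # 1-sample bounces
        v[20:30] = True               # stable 9 ms closure at t=20 ms
        train = run_switch(cfg, DigitizedTrace(v, 1000.0))
        assert list(train.onsets) == [20_000.0]
        assert list(train.offsets) == [30_000.0]

    def test_press_train_one_event_per_press(self):
        # nurse-call style: 1 Hz presses, 100 ms hold each
        cfg = SwitchConfig(1000.0)  # defaults: 20 ms debounce, 100 ms refractory
        v = np.zeros(5000, dtype=bool)
        for k in range(5):
            v[k * 1000 + 100 : k * 1000 + 200] = True
        train = run_switch(cfg, DigitizedTrace(v, 1000.0))
        assert len(train) == 5
        assert np.allclose(np.diff(train.onsets), 1_000_000.0)


config_strategy = st.builds(
    TriggerConfig,
    sampling_frequency=st.sampled_from([1e6 / 3, 1e6 / 5, 1e6 / 8, 1e6 / 160]),
    threshold=st.integers(0, 1000),
    min_pulse_duration=st.sampled_from([0.0, 5.0, 16.0, 100.0, 1000.0]),
    pulse_increment=st.sampled_from([0.0, 5.0, 24.0, 500.0]),
    refractory_period=st.sampled_from([0.0, 10.0, 300.0, 2000.0]),
)


class TestProperties:
    @settings(max_examples=150, deadline=None)
    @given(
        cfg=config_strategy,
        values=st.lists(st.integers(0, 1023), min_size=0, max_size=60),
    )
    def test_oracle_equivalence_with_naive_reference(self, cfg, values):
        """Edge times match a history-based reference on random traces."""
        trace = counts_trace(values, 1e6 / cfg.sampling_frequency)
        train = run_trigger(cfg, trace)
        ref_on, ref_off = naive_trigger(cfg, values, trace.times * 1e6)
        assert np.allclose(train.onsets, ref_on, atol=1e-6)
        assert np.allclose(train.offsets, ref_off, atol=1e-6)

    @settings(max_examples=80, deadline=None)
    @given(
        cfg=config_strategy,
        values=st.lists(st.integers(0, 1023), min_size=2, max_size=80),
    )
    def test_refractory_and_min_duration_invariants(self, cfg, values):
        """Onset gaps respect the refractory; no pulse shorter than the minimum."""
        trace = counts_trace(values, 1e6 / cfg.sampling_frequency)
        train = run_trigger(cfg, trace)
        if len(train.onsets) > 1:
            assert np.all(np.diff(train.onsets) >= cfg.refractory_period - 1e-6)
        assert np.all(train.durations >= cfg.min_pulse_duration - 1e-6)

    @pytest.mark.parametrize("period_us", [20.0, 100.0, 160.0, 37.0])
    @pytest.mark.parametrize("min_ms", [0.5, 1.0, 10.0, 12.34])
    def test_duration_quantization_law(self, period_us, min_ms):
        """Sustained input: duration = T_s * ceil(min / T_s)."""
        min_us = min_ms * 1000.0
        cfg = TriggerConfig(1e6 / period_us, threshold=50,
                            min_pulse_duration=min_us, pulse_increment=0.0)
        n = int(min_us / period_us) + 10
        train = run_trigger(cfg, counts_trace([600] * n, period_us))
        expected = period_us * math.ceil(min_us / period_us - 1e-9)
        assert train.durations[0] == pytest.approx(expected, abs=1e-6)

    def test_onset_latency_uniform_over_sample_period(self, rng):
        """Detection latency for uniform-phase abrupt onsets: S.D. -> T_s/sqrt(12)."""
        period = 160.0
        cfg = TriggerConfig(1e6 / period, threshold=50, min_pulse_duration=160.0)
        n_rep, n_samp = 3000, 6
        lat = np.empty(n_rep)
        for k in range(n_rep):
            phase = rng.uniform(0, period)
            t = np.arange(n_samp) * period
            v = np.where(t >= phase, 600, 0)
            train = run_trigger(cfg, counts_trace(v, period))
            lat[k] = train.onsets[0] - phase
        expected_sd = period / np.sqrt(12.0)
        assert np.all(lat >= 0) and np.all(lat < period)
        assert abs(lat.std() - expected_sd) < 3 * expected_sd / np.sqrt(2 * n_rep)
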