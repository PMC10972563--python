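import numpy as np
import pandas as pd
import pytest

import vesikin as vk
from vesikin.synth import SynthSpec, synth_epsc, synth_epsc_single, synth_iglu
from vesikin.traces import StimProtocol


def make_trace(events, n_frames=200, frame_period=0.01, noise_sd=0.0,
               tau=0.1, n_boutons=1, seed=0):
    """Bouton traces with kernel events at given (bouton, frame, amplitude)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * frame_period
    data = noise_sd * rng.standard_normal((n_boutons, n_frames))
    for b, f, a in events:
        data[b, f:] += a * np.exp(-(t[f:] - t[f]) / tau)
    return vk.FluorescenceTrace(t, data, baseline_window=(0.0, 0.5))


class TestDetectEvents:
    protocol = StimProtocol((0.5,))

    def test_noise_only_trace_is_empty(self):
        trace = make_trace([], noise_sd=0.01, n_boutons=5, seed=3)
        ev = vk.detect_events(trace, self.protocol)
        assert len(ev) == 0

    def test_single_event_at_first_frame_is_synchronous(self):
        # 6×SD event landing on the 10 ms frame after the stimulus
        trace = make_trace([(0, 51, 0.6)], noise_sd=0.1 / 5, seed=1)
        thr = 5 * trace.noise_sd()[0]
        ev = vk.detect_events(trace, self.protocol)
        assert len(ev) == 1
        row = ev.iloc[0]
        assert row.klass == "synchronous" and row.bin == 1
        assert row.peak_ms == pytest.approx(10.0)
        assert row.peak_dff > thr

    def test_dual_peaks_reported_separately(self):
        trace = make_trace([(0, 51, 1.0), (0, 54, 0.8)], noise_sd=0.002, seed=2)
        ev = vk.detect_events(trace, self.protocol, kernel_tau=0.1)
        assert list(ev.klass) == ["synchronous", "asynchronous"]
        assert list(ev.bin) == [1, 4]
        assert list(ev.peak_ms) == [pytest.approx(10.0), pytest.approx(40.0)]

    def test_step_plateau_registers_once_at_rise(self):
        t = np.arange(200) * 0.01
        x = np.zeros((1, 200))
        x[0, 51:] = 0.6  # sustained step, never decays
        trace = vk.FluorescenceTrace(t, x + 0.001 * np.random.default_rng(0).standard_normal(x.shape))
        ev = vk.detect_events(trace, self.protocol)
        assert len(ev) == 1
        assert ev.iloc[0].frame == 51 and ev.iloc[0].klass == "synchronous"

    def test_subthreshold_events_ignored(self):
        trace = make_trace([(0, 51, 0.03)], noise_sd=0.01, seed=4)
        assert len(vk.detect_events(trace, self.protocol)) == 0

    def test_prestimulus_peaks_discarded(self):
        trace = make_trace([(0, 20, 1.0), (0, 51, 1.0)], noise_sd=0.002, seed=5,
                           )
        # baseline window must precede the spurious early event
        trace = vk.FluorescenceTrace(trace.frame_times, trace.data,
                                     baseline_window=(0.0, 0.2))
        ev = vk.detect_events(trace, self.protocol)
        assert list(ev.frame) == [51]

    def test_events_partition_into_two_classes(self):
        spec = SynthSpec(seed=6, n_boutons=50)
        trace, _ = synth_iglu(spec)
        ev = vk.detect_events(trace, spec.protocol, kernel_tau=spec.kernel_tau)
        assert set(ev.klass) <= {"synchronous", "asynchronous"}
        n_sync = (ev.klass == "synchronous").sum()
        n_async = (ev.klass == "asynchronous").sum()
        assert n_sync + n_async == len(ev)


class TestEventStatistics:
    def test_percent_asynchronous_of_known_split(self):
        ev = pd.DataFrame({"klass": ["synchronous"] * 640 + ["asynchronous"] * 360})
        assert vk.percent_asynchronous(ev) == pytest.approx(36.0)

    def test_all_first_bin_gives_zero(self):
        ev = pd.DataFrame({"klass": ["synchronous"] * 10})
        assert vk.percent_asynchronous(ev) == 0.0

    def test_empty_table_undefined(self):
        with pytest.raises(ValueError):
            vk.percent_asynchronous(pd.DataFrame({"klass": []}))

    def test_percent_async_invariant_to_amplitude_scaling(self):
        spec = SynthSpec(seed=7, n_boutons=80)
        trace, _ = synth_iglu(spec)
        scaled = vk.FluorescenceTrace(
            trace.frame_times, trace.data * 7.5,
            baseline_window=trace.baseline_window,
        )
        a = vk.percent_asynchronous(vk.detect_events(trace, spec.protocol))
        b = vk.percent_asynchronous(vk.detect_events(scaled, spec.protocol))
        assert a == b

    def test_train_ar_fraction_counts(self):
        proto = StimProtocol.train(3, 10.0)
        ev = pd.DataFrame(
            {
                "stimulus": [1, 1, 2],
                "klass": ["synchronous", "asynchronous", "synchronous"],
            }
        )
        fr = vk.train_ar_fraction(ev, proto)
        assert list(fr.ar_fraction) == [0.5, 0.0, 0.0]

    def test_paired_pulse_ratio(self):
        assert vk.paired_pulse_ratio([1.0, 1.0]) == 1.0
        assert vk.paired_pulse_ratio([1.0, 0.57]) == pytest.approx(0.57)
        assert vk.paired_pulse_ratio([1.0, 1.3, 0.9]) == pytest.approx(1.3)
        with pytest.raises(ValueError):
            vk.paired_pulse_ratio([0.0, 1.0])
        with pytest.raises(ValueError):
            vk.paired_pulse_ratio([1.0])


class TestChargeDecomposition:
    def test_recovers_known_biexponential(self):
        truth = dict(q_fast=120.0, q_slow=60.0, tau_fast=6e-3, tau_slow=90e-3)
        trace = synth_epsc_single(**truth, fs=50e3, duration=0.6)
        d = vk.cumulative_charge_decomposition(trace, window=0.4)
        assert d.q_fast == pytest.approx(truth["q_fast"], rel=0.01)
        assert d.q_slow == pytest.approx(truth["q_slow"], rel=0.01)
        assert d.tau_fast == pytest.approx(truth["tau_fast"], rel=0.01)
        assert d.tau_slow == pytest.approx(truth["tau_slow"], rel=0.01)
        assert not d.degenerate
        assert d.tau_fast < d.tau_slow

    def test_single_exponential_flags_degenerate_or_empty_slow(self):
        trace = synth_epsc_single(150.0, 1e-9, 8e-3, 8.0001e-3, fs=50e3, duration=0.6)
        d = vk.cumulative_charge_decomposition(trace, window=0.4)
        assert d.degenerate or d.q_slow < 0.05 * d.q_fast

    def test_reduced_slow_component_measured(self):
        # a trace built with 61% less slow charge than a control template
        # reads out a slow-charge ratio of 0.39
        control = synth_epsc_single(120.0, 60.0, 6e-3, 90e-3)
        reduced = synth_epsc_single(120.0, 60.0 * 0.39, 6e-3, 90e-3)
        dc = vk.cumulative_charge_decomposition(control)
        dr = vk.cumulative_charge_decomposition(reduced)
        assert dr.q_slow / dc.q_slow == pytest.approx(0.39, rel=0.02)

    def test_amplitude_is_inward_peak(self):
        trace = synth_epsc_single(120.0, 60.0, 6e-3, 90e-3)
        d = vk.cumulative_charge_decomposition(trace)
        assert d.amplitude == pytest.approx(120.0 / 6e-3 + 60.0 / 90e-3, rel=0.01)


class TestTonicCharge:
    def test_zero_when_current_returns_to_baseline(self):
        spec = SynthSpec(seed=8, protocol=StimProtocol.train(20, 20.0),
                         tonic_shape="none", epsc_tau_decay=5e-3)
        trace, truth = synth_epsc(spec)
        assert vk.tonic_charge(trace) == pytest.approx(0.0, abs=0.5)

    def test_constant_offset_rectangle_area(self):
        # −100 pA sustained across a 2.5 s train → 250 pC
        proto = StimProtocol.train(50, 20.0)
        t = np.arange(0.0, 3.2, 1e-4)
        current = np.where(t >= proto.onsets[0] - 0.01, -100.0, 0.0)
        trace = vk.CurrentTrace(t, current, proto.onsets,
                                baseline_window=(0.0, 0.49))
        assert vk.tonic_charge(trace) == pytest.approx(250.0, rel=1e-6)

    def test_linear_ramp_matches_analytic_area(self):
        spec = SynthSpec(seed=9, protocol=StimProtocol.train(50, 20.0),
                         tonic_shape="ramp", tonic_peak=100.0)
        trace, truth = synth_epsc(spec)
        assert vk.tonic_charge(trace) == pytest.approx(
            truth["tonic_charge_pC"], rel=1e-3
        )

    def test_additive_over_disjoint_segments(self):
        spec = SynthSpec(seed=10, protocol=StimProtocol.train(40, 20.0),
                         tonic_shape="ramp", tonic_peak=80.0)
        trace, _ = synth_epsc(spec)
        whole = vk.tonic_charge(trace)
        first = vk.tonic_charge(trace, StimProtocol(trace.stim_onsets[:20]))
        second = vk.tonic_charge(trace, StimProtocol(trace.stim_onsets[20:]))
        assert first + second == pytest.approx(whole, rel=1e-9)

    def test_tail_outside_record_rejected(self):
        t = np.arange(0.0, 1.0, 1e-3)
        trace = vk.CurrentTrace(t, np.zeros_like(t), (0.5, 0.95))
        with pytest.raises(ValueError):
            vk.tonic_charge(trace)
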