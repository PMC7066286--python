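"""Filtering, epoching, rejection, referencing and component cleanup."""
import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from p3tacs import SimConfig
from p3tacs.io import Recording
from p3tacs.preprocess import (
    average_reference,
    clean_components,
    epoch,
    filter_signal,
    reject_blink_trials,
)
from p3tacs.sim import generate_trial_sequence, synthesize_eeg, _blink_template

from conftest import make_epochs


def sine_recording(freqs, amps, fs=1000.0, dur_s=30.0, n_ch=2):
    t = np.arange(int(dur_s * fs)) / fs
    x = sum(a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs, amps))
    return Recording(
        np.tile(x, (n_ch, 1)), fs, [f"ch{i}" for i in range(n_ch)],
        events=[(int(fs * dur_s / 2), "target")],
    )


class TestFilter:
    def test_passband_amplitude_preserved(self):
        rec = sine_recording([3.0], [10.0])
        out = filter_signal(rec, None, 8.0)
        mid = out.data[0, 5000:25000]
        assert mid.max() == pytest.approx(10.0, rel=0.01)

    def test_zero_phase_no_latency_shift(self):
        fs = 1000.0
        x = np.zeros(20000)
        x[9000:11000] = np.hanning(2000) * 10
        rec = Recording(x[None, :], fs, ["Pz"])
        out = filter_signal(rec, 0.5, 20.0)
        assert int(np.argmax(out.data[0])) == int(np.argmax(x))

    def test_stopband_attenuation(self):
        rec = sine_recording([3.0, 16.0], [10.0, 10.0])
        out = filter_signal(rec, None, 8.0)
        spec_in = np.abs(np.fft.rfft(rec.data[0]))
        spec_out = np.abs(np.fft.rfft(out.data[0]))
        freqs = np.fft.rfftfreq(rec.n_samples, 1 / 1000.0)
        i16 = np.argmin(np.abs(freqs - 16.0))
        atten_db = 20 * np.log10(spec_in[i16] / spec_out[i16])
        assert atten_db >= 20.0

    def test_cutoff_at_nyquist_rejected(self):
        rec = sine_recording([3.0], [1.0])
        with pytest.raises(ValueError):
            filter_signal(rec, None, 500.0)
        with pytest.raises(ValueError):
            filter_signal(rec, 30.0, 8.0)

    def test_filter_then_epoch_commutes_with_epoch_windows(self):
        """Filtering the continuous record then epoching equals epoching
        the filtered record cut at the same events (operation order on
        continuous data, away from record edges)."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 10, size=(2, 30000))
        events = [(10000, "target"), (18000, "target")]
        rec = Recording(x, 1000.0, ["a", "b"], events=events)
        filtered = filter_signal(rec, 0.5, 20.0)
        ep = epoch(filtered, (-1000, 2000), None)
        for k, (s, _) in enumerate(events):
            assert np.allclose(ep.data[k], filtered.data[:, s - 1000 : s + 2001])


class TestEpoch:
    def test_sample_count_closed_window(self):
        rec = sine_recording([3.0], [5.0])
        ep = epoch(rec, (-3000, 4000), (-50, 0))
        assert ep.data.shape[-1] == 7001
        assert ep.times_ms[0] == -3000 and ep.times_ms[-1] == 4000

    def test_constant_channel_becomes_zero(self):
        rec = Recording(np.full((1, 20000), 5.0), 1000.0, ["Pz"],
                        events=[(10000, "target")])
        ep = epoch(rec, (-3000, 4000), (-50, 0))
        assert np.allclose(ep.data, 0.0)

    def test_baseline_mean_numerically_zero(self):
        rng = np.random.default_rng(1)
        rec = Recording(rng.normal(0, 30, (3, 20000)), 1000.0, ["a", "b", "c"],
                        events=[(10000, "target")])
        ep = epoch(rec, (-3000, 4000), (-50, 0))
        bmask = (ep.times_ms >= -50) & (ep.times_ms <= 0)
        assert np.abs(ep.data[:, :, bmask].mean(axis=2)).max() < 1e-9

    def test_edge_event_dropped(self, caplog):
        rec = Recording(np.zeros((1, 20000)), 1000.0, ["Pz"],
                        events=[(100, "target"), (10000, "target")])
        with caplog.at_level("INFO"):
            ep = epoch(rec, (-3000, 4000), (-50, 0))
        assert ep.n_trials == 1

    def test_no_matching_events_rejected(self):
        rec = Recording(np.zeros((1, 20000)), 1000.0, ["Pz"], events=[(10000, "response")])
        with pytest.raises(ValueError):
            epoch(rec, (-3000, 4000), (-50, 0), codes=("target",))


class TestBlinkRejection:
    def _epochs_with_blink(self, at_ms, n_ch=8, amp=300.0):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 5, size=(3, n_ch, 7001))
        tpl = _blink_template(1000.0) * amp
        i0 = int(at_ms + 3000)
        data[1, :, i0 : i0 + len(tpl)] += tpl  # same waveform on all channels
        return make_epochs(data, channels=[f"c{i}" for i in range(n_ch - 1)] + ["Pz"])

    def test_uniform_large_deflection_rejected(self):
        ep = reject_blink_trials(self._epochs_with_blink(500.0), amp_threshold_uv=100.0)
        assert ep.metadata.rejected.tolist() == [False, True, False]
        assert ep.metadata.rejection_reason[1] == "blink"

    def test_deflection_before_onset_retained(self):
        ep = reject_blink_trials(self._epochs_with_blink(-800.0), amp_threshold_uv=100.0)
        assert not ep.metadata.rejected.any()

    def test_retained_trials_untouched(self):
        before = self._epochs_with_blink(500.0)
        after = reject_blink_trials(before, amp_threshold_uv=100.0)
        assert np.array_equal(before.data[0], after.data[0])
        assert np.array_equal(before.data[2], after.data[2])

    def test_rejected_fraction_tracks_blink_probability(self):
        cfg = SimConfig(n_trials=100, blink_prob=0.1, seed=3)
        sched = generate_trial_sequence(100, 0.25, seed=3)
        rec = synthesize_eeg(sched, cfg, seed=3)
        rec = filter_signal(rec, 0.5, 20.0)
        ep = epoch(rec, codes=("standard", "target"))
        ep = reject_blink_trials(ep)
        frac = ep.metadata.rejected.mean()
        se = np.sqrt(0.1 * 0.9 / 100)
        assert abs(frac - 0.1) <= 3 * se


class TestAverageReference:
    def test_mean_zero_and_idempotent(self):
        rng = np.random.default_rng(4)
        ep = make_epochs(rng.normal(0, 10, size=(2, 5, 101)))
        ref = average_reference(ep, exclude_channels=())
        assert np.abs(ref.data.mean(axis=1)).max() < 1e-9
        again = average_reference(ref, exclude_channels=())
        assert np.allclose(again.data, ref.data)

    def test_differences_preserved_exactly(self):
        rng = np.random.default_rng(5)
        ep = make_epochs(rng.normal(0, 10, size=(2, 5, 101)))
        ref = average_reference(ep, exclude_channels=())
        assert np.allclose(
            ep.data[:, 0] - ep.data[:, 1], ref.data[:, 0] - ref.data[:, 1]
        )

    def test_antisymmetric_pair_unchanged(self):
        x = np.random.default_rng(6).normal(size=(1, 1, 101))
        data = np.concatenate([x, -x], axis=1)
        ep = make_epochs(data, channels=["a", "b"])
        ref = average_reference(ep, exclude_channels=())
        assert np.allclose(ref.data, data)

    def test_single_channel_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 11)), channels=["Pz"])
        with pytest.raises(ValueError):
            average_reference(ep, exclude_channels=())


class TestICACleanup:
    def _mixed_epochs(self, seed=0, n_trials=30, blink_gain=1.0):
        """Clean rhythmic EEG + a blink source with known mixing + EOG."""
        rng = np.random.default_rng(seed)
        n_ch, n_t = 6, 1001
        t = np.arange(n_t) / 1000.0
        clean = rng.normal(0, 1.0, size=(n_trials, n_ch, n_t))
        for ch in range(n_ch):
            clean[:, ch, :] += 2 * np.sin(2 * np.pi * (4 + ch) * t)[None, :]
        blink_src = np.zeros((n_trials, n_t))
        for tr in range(0, n_trials, 3):
            i0 = rng.integers(50, 450)
            blink_src[tr, i0 : i0 + 400] = _blink_template(1000.0) * 80
        mixing = np.array([1.0, 0.8, 0.6, 0.5, 0.4, 0.3]) * blink_gain
        data = clean + mixing[None, :, None] * blink_src[:, None, :]
        eog = (blink_src * 1.5 + rng.normal(0, 1.0, blink_src.shape))[:, None, :]
        full = np.concatenate([data, eog], axis=1)
        labels = [f"c{i}" for i in range(n_ch - 1)] + ["Pz", "EOG"]
        # epochs start pre-stimulus so blink averages peak outside the
        # 300-600 ms protection window
        return make_epochs(full, t0_ms=-500.0, channels=labels), clean

    def test_blink_component_removed_toward_ground_truth(self):
        ep, clean = self._mixed_epochs(seed=7)
        out = clean_components(ep, corr_threshold=0.7, seed=0)
        pz = ep.channel_index("Pz")
        err_before = np.sqrt(np.mean((ep.data[:, pz] - clean[:, 4]) ** 2))
        err_after = np.sqrt(np.mean((out.data[:, pz] - clean[:, 4]) ** 2))
        assert err_after < err_before

    def test_no_eog_correlated_component_output_unchanged(self):
        ep, _ = self._mixed_epochs(seed=8, blink_gain=0.0)
        out = clean_components(ep, corr_threshold=0.7, seed=0)
        assert np.allclose(out.data, ep.data, atol=1e-6)

    def test_p300_guard_protects_stimulus_locked_component(self):
        """A P300-like source peaking in the 300-600 ms window survives
        even when it leaks into the EOG channel."""
        rng = np.random.default_rng(9)
        n_trials, n_ch, n_t = 30, 6, 1001
        t = np.arange(n_t)
        p3 = 10 * np.exp(-0.5 * ((t - 450) / 80) ** 2)
        data = rng.normal(0, 1.0, size=(n_trials, n_ch, n_t))
        mixing = np.array([0.3, 0.4, 0.5, 0.7, 0.9, 1.0])
        data += mixing[None, :, None] * p3[None, None, :]
        eog = (p3 * 1.2 + rng.normal(0, 0.5, (n_trials, n_t)))[:, None, :]
        full = np.concatenate([data, eog], axis=1)
        labels = [f"c{i}" for i in range(n_ch - 1)] + ["Pz", "EOG"]
        ep = make_epochs(full, t0_ms=0.0, channels=labels)
        out = clean_components(ep, corr_threshold=0.7, seed=0)
        pz = ep.channel_index("Pz")
        erp_before = ep.data[:, pz].mean(axis=0)
        erp_after = out.data[:, pz].mean(axis=0)
        assert erp_after.max() == pytest.approx(erp_before.max(), rel=0.05)
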