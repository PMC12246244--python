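"""Preprocessing operators: algebraic contracts, filter design, ICA,
peak-to-peak rejection."""

import numpy as np
import pytest
from scipy import signal

import eegmultiverse as emv
from eegmultiverse.containers import SCALP_LAYOUT, ChannelError, PathInvalidError
from eegmultiverse.preprocess import (
    FilterSpec,
    ParameterError,
    design_fir,
    _filter_array,
)
from eegmultiverse.synth import _pink_noise

from conftest import make_epochs


def _toy_recording(data, names, sfreq=128.0, events=None):
    if events is None:
        events = np.empty((0, 2), dtype=int)
    return emv.ContinuousRecording(data=np.asarray(data, float), sfreq=sfreq,
                                   channel_names=list(names), events=events)


# ---------------------------------------------------------------------------
# Bipolar EOG
# ---------------------------------------------------------------------------

class TestBipolarEOG:
    def test_heog_arithmetic_on_three_sample_toy(self):
        names = ["Cz", "Fp2", "P9", "P10", "HEOG_left", "HEOG_right",
                 "VEOG_lower"]
        data = np.zeros((7, 3))
        data[names.index("HEOG_left")] = [1, 2, 3]
        data[names.index("HEOG_right")] = [0, 1, 1]
        rec = emv.derive_bipolar_eog(_toy_recording(data, names))
        assert np.array_equal(rec.data[rec.channel_index("HEOG")], [1, 1, 2])

    def test_equal_sources_give_zero_bipolar_channels(self):
        names = ["Cz", "Fp2", "P9", "P10", "HEOG_left", "HEOG_right",
                 "VEOG_lower"]
        rng = np.random.default_rng(0)
        data = rng.standard_normal((7, 50))
        data[names.index("HEOG_right")] = data[names.index("HEOG_left")]
        data[names.index("VEOG_lower")] = data[names.index("Fp2")]
        rec = emv.derive_bipolar_eog(_toy_recording(data, names))
        assert np.allclose(rec.data[rec.channel_index("HEOG")], 0)
        assert np.allclose(rec.data[rec.channel_index("VEOG")], 0)

    def test_missing_source_channel_raises(self):
        rec = _toy_recording(np.zeros((2, 10)), ["Cz", "Fp2"])
        with pytest.raises(ChannelError):
            emv.derive_bipolar_eog(rec)


# ---------------------------------------------------------------------------
# FIR filtering
# ---------------------------------------------------------------------------

class TestFIRFilter:
    def test_highpass_attenuates_dc_by_53_db(self):
        taps = design_fir(FilterSpec(l_freq=0.5), sfreq=128.0)
        x = np.ones((1, 6000))
        y = _filter_array(x, taps)
        mid = y[0, 2000:4000]
        assert np.abs(mid).max() <= 10 ** (-53 / 20)

    def test_passband_sine_within_ripple(self):
        sf = 128.0
        taps = design_fir(FilterSpec(l_freq=0.5, h_freq=20.0), sfreq=sf)
        t = np.arange(20000) / sf
        x = np.sin(2 * np.pi * 10.0 * t)[None]
        y = _filter_array(x, taps)[0]
        mid = slice(8000, 12000)
        # amplitude via projection onto the quadrature pair
        a = 2 * np.mean(y[mid] * np.sin(2 * np.pi * 10 * t[mid]))
        b = 2 * np.mean(y[mid] * np.cos(2 * np.pi * 10 * t[mid]))
        amp = np.hypot(a, b)
        assert abs(amp - 1.0) <= 0.0194

    def test_zero_net_delay_impulse_symmetric(self):
        taps = design_fir(FilterSpec(h_freq=20.0), sfreq=128.0)
        x = np.zeros((1, 4001))
        x[0, 2000] = 1.0
        y = _filter_array(x, taps)[0]
        assert np.argmax(y) == 2000
        k = np.arange(1, 500)
        assert np.allclose(y[2000 + k], y[2000 - k], atol=1e-12)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            design_fir(FilterSpec(h_freq=70.0), sfreq=128.0)

    def test_signal_shorter_than_filter_rejected(self):
        taps = design_fir(FilterSpec(l_freq=0.5), sfreq=128.0)
        with pytest.raises(ParameterError):
            _filter_array(np.zeros((1, 100)), taps)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        taps = design_fir(FilterSpec(l_freq=1.0, h_freq=30.0), sfreq=128.0)
        a = rng.standard_normal((1, 3000))
        b = rng.standard_normal((1, 3000))
        both = _filter_array(a + 2 * b, taps)
        sep = _filter_array(a, taps) + 2 * _filter_array(b, taps)
        assert np.allclose(both, sep, atol=1e-10)


# ---------------------------------------------------------------------------
# Referencing
# ---------------------------------------------------------------------------

class TestRereference:
    def test_average_reference_zero_mean_over_scalp(self, small_epochs):
        out = emv.rereference(small_epochs, "average")
        scalp = out.scalp_indices
        assert np.allclose(out.data[:, scalp, :].mean(axis=1), 0, atol=1e-10)

    def test_cz_reference_nulls_cz(self, prepared):
        out = emv.rereference(prepared[0], "Cz")
        assert np.allclose(out.data[out.channel_index("Cz")], 0)

    def test_p9p10_zero_reference_is_identity(self):
        names = list(SCALP_LAYOUT)
        rng = np.random.default_rng(2)
        data = rng.standard_normal((len(names), 100))
        data[names.index("P9")] = 0
        data[names.index("P10")] = 0
        rec = _toy_recording(data, names)
        out = emv.rereference(rec, "P9P10")
        assert np.allclose(out.data, rec.data)

    def test_eog_channels_untouched(self, prepared):
        out = emv.rereference(prepared[0], "average")
        h = prepared[0].channel_index("HEOG")
        assert np.array_equal(out.data[h], prepared[0].data[h])


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

class TestEpoch:
    def test_times_convention(self, prepared):
        ep = emv.epoch(prepared[0], (-0.4, 0.8))
        sf = prepared[0].sfreq
        assert ep.n_times == round(1.2 * sf) + 1
        assert ep.times[0] == pytest.approx(-0.4)
        assert np.allclose(np.diff(ep.times), 1 / sf)

    def test_all_interior_events_kept(self, prepared):
        ep = emv.epoch(prepared[0], (-0.2, 0.5))
        assert ep.n_trials == prepared[0].events.shape[0]

    def test_edge_event_dropped(self):
        names = ["Cz", "Pz"]
        events = np.array([[0, 0], [500, 1]])
        rec = _toy_recording(np.zeros((2, 1000)), names, sfreq=100.0,
                             events=events)
        ep = emv.epoch(rec, (-0.1, 0.1))
        assert ep.n_trials == 1
        assert np.array_equal(ep.kept_trial_index, [1])

    def test_no_surviving_events_raises(self):
        rec = _toy_recording(np.zeros((1, 50)), ["Cz"],
                             sfreq=100.0, events=np.array([[5, 0]]))
        with pytest.raises(ParameterError):
            emv.epoch(rec, (-0.5, 0.5))


# ---------------------------------------------------------------------------
# Detrending and baseline correction
# ---------------------------------------------------------------------------

class TestDetrendBaseline:
    def test_exact_ramp_removed(self):
        t = -0.2 + np.arange(50) / 100.0
        ep = make_epochs((3 + 2 * t)[None, None, :])
        out = emv.detrend_linear(ep)
        assert np.allclose(out.data, 0, atol=1e-12)

    def test_detrend_idempotent_and_zero_residual_trend(self):
        rng = np.random.default_rng(3)
        ep = make_epochs(rng.standard_normal((4, 3, 60)))
        once = emv.detrend_linear(ep)
        twice = emv.detrend_linear(once)
        assert np.allclose(once.data, twice.data, atol=1e-10)
        # refitting a line to the residuals yields ~zero slope and intercept
        G = np.column_stack([np.ones_like(once.times), once.times])
        coef = np.linalg.lstsq(G, once.data.reshape(-1, 60).T, rcond=None)[0]
        assert np.abs(coef).max() < 1e-10

    def test_detrend_against_hand_least_squares_five_point_toy(self):
        # x = ramp + sine on t = 0..4 s at 1 Hz sampling; closed-form LS:
        # slope = S_xy / S_xx, intercept = mean(x) - slope * mean(t)
        t = np.arange(5.0)
        x = (3 + 2 * t) + np.sin(t)
        mt, mx = t.mean(), x.mean()
        slope = ((t - mt) * (x - mx)).sum() / ((t - mt) ** 2).sum()
        intercept = mx - slope * mt
        expected = x - (intercept + slope * t)
        ep = make_epochs(x[None, None, :], sfreq=1.0, t0=0.0)
        out = emv.detrend_linear(ep)
        assert np.allclose(out.data[0, 0], expected, atol=1e-12)

    def test_baseline_constant_epoch_zeroed(self):
        ep = make_epochs(7.0 * np.ones((2, 3, 40)))
        out = emv.baseline_correct(ep, (-0.2, 0.0))
        assert np.allclose(out.data, 0)

    def test_baseline_mean_zero_and_idempotent(self):
        rng = np.random.default_rng(4)
        ep = make_epochs(rng.standard_normal((5, 2, 40)))
        out = emv.baseline_correct(ep, (-0.2, 0.0))
        mask = (out.times >= -0.2) & (out.times <= 0.0)
        assert np.allclose(out.data[:, :, mask].mean(axis=2), 0, atol=1e-12)
        again = emv.baseline_correct(out, (-0.2, 0.0))
        assert np.allclose(out.data, again.data, atol=1e-12)

    def test_baseline_window_outside_epoch_raises(self):
        ep = make_epochs(np.zeros((1, 1, 40)))
        with pytest.raises(ParameterError):
            emv.baseline_correct(ep, (-1.0, 0.0))


# ---------------------------------------------------------------------------
# ICA corrections
# ---------------------------------------------------------------------------

def _blink_recording(seed=0, sfreq=128.0, n_samp=20000, effect=True):
    """White+pink background, planted blink source with frontal mixing,
    EOG channels carrying the source, plus an event-locked posterior effect."""
    rng = np.random.default_rng(seed)
    names = list(SCALP_LAYOUT) + ["HEOG", "VEOG"]
    n_sc = len(SCALP_LAYOUT)
    data = 3.0 * _pink_noise(rng, len(names), n_samp)
    # blink source: bumps every ~1 s
    source = np.zeros(n_samp)
    bump = np.sin(np.pi * np.arange(int(0.3 * sfreq)) / int(0.3 * sfreq))
    onsets = np.arange(int(0.5 * sfreq), n_samp - 100, int(1.1 * sfreq))
    for o in onsets:
        source[o:o + bump.size] += bump[:n_samp - o]
    mixing = np.array([np.exp(-np.linalg.norm(np.array(p) - [0, 1.0]) ** 2)
                       for p in SCALP_LAYOUT.values()])
    data[:n_sc] += 60.0 * np.outer(mixing, source)
    data[names.index("VEOG")] += 80.0 * source
    data[names.index("HEOG")] += 10.0 * source
    events = np.column_stack([
        np.arange(int(sfreq), n_samp - int(sfreq),
                  int(1.3 * sfreq)),
        np.arange(len(np.arange(int(sfreq), n_samp - int(sfreq),
                                int(1.3 * sfreq)))) % 2])
    if effect:
        pz = names.index("Pz")
        kern = np.exp(-((np.arange(-32, 33) / sfreq) ** 2) / (2 * 0.05 ** 2))
        for s, lab in events:
            if lab == 1:
                lo = s + 13 - 32
                data[pz, lo:lo + 65] += 5.0 * kern
    return emv.ContinuousRecording(data=data, sfreq=sfreq,
                                   channel_names=names, events=events), source


class TestOcularICA:
    def test_planted_blink_removed_effect_preserved(self):
        rec, source = _blink_recording(seed=1)
        out, rep = emv.correct_ocular(rec, seed=5)
        assert rep.converged and rep.flagged_components
        sc = rec.scalp_indices
        for i in sc:
            c = np.corrcoef(out.data[i], source)[0, 1]
            assert abs(c) < 0.1
        # planted condition effect survives: class-difference evoked at Pz
        def pz_effect(r):
            ep = emv.epoch(r, (-0.2, 0.4))
            pz = ep.channel_index("Pz")
            d = (ep.data[ep.labels == 1, pz].mean(0)
                 - ep.data[ep.labels == 0, pz].mean(0))
            return np.abs(d).max()
        before, after = pz_effect(rec), pz_effect(out)
        assert abs(after - before) / before < 0.10

    def test_eog_channels_and_trial_count_untouched(self):
        rec, _ = _blink_recording(seed=2)
        out, _ = emv.correct_ocular(rec, seed=5)
        for ch in ("HEOG", "VEOG"):
            i = rec.channel_index(ch)
            assert np.array_equal(out.data[i], rec.data[i])
        assert np.array_equal(out.events, rec.events)

    def test_pure_noise_eog_flags_nothing_much(self):
        rng = np.random.default_rng(9)
        names = list(SCALP_LAYOUT) + ["HEOG", "VEOG"]
        data = 3.0 * _pink_noise(rng, len(names), 15000)
        rec = emv.ContinuousRecording(data=data, sfreq=128.0,
                                      channel_names=names,
                                      events=np.array([[100, 0], [400, 1]]))
        out, rep = emv.correct_ocular(rec, seed=5)
        assert len(rep.flagged_components) <= 1
        sc = rec.scalp_indices
        rel = (np.abs(out.data[sc] - rec.data[sc]).max()
               / np.abs(rec.data[sc]).max())
        assert rel < 0.5

    def test_deterministic_under_seed(self):
        rec, _ = _blink_recording(seed=3)
        _, r1 = emv.correct_ocular(rec, seed=11)
        _, r2 = emv.correct_ocular(rec, seed=11)
        assert r1.flagged_components == r2.flagged_components

    def test_missing_eog_raises(self):
        names = list(SCALP_LAYOUT)
        rec = _toy_recording(np.zeros((len(names), 2000)), names)
        with pytest.raises(ChannelError):
            emv.correct_ocular(rec, seed=0)


class TestMuscleICA:
    def _burst_recording(self, seed=0, sfreq=128.0, n_samp=20000):
        rng = np.random.default_rng(seed)
        names = list(SCALP_LAYOUT) + ["HEOG", "VEOG"]
        data = 3.0 * _pink_noise(rng, len(names), n_samp)
        sos = signal.butter(4, [25, 60], btype="band", fs=sfreq, output="sos")
        src = signal.sosfilt(sos, rng.standard_normal(n_samp))
        env = np.zeros(n_samp)
        for o in range(400, n_samp - 200, 600):
            env[o:o + 128] = np.hanning(128)
        src = 20.0 * src / src.std() * env
        w = {"T8": 1.0, "P8": 0.5, "P10": 0.4, "F8": 0.3}
        for ch, g in w.items():
            data[names.index(ch)] += g * src
        return emv.ContinuousRecording(
            data=data, sfreq=sfreq, channel_names=names,
            events=np.array([[100, 0], [400, 1]])), src

    def test_planted_burst_power_halved(self):
        rec, _ = self._burst_recording(seed=4)
        out, rep = emv.correct_muscle(rec, seed=6)
        assert rep.flagged_components
        i = rec.channel_index("T8")
        def band_power(x):
            f, p = signal.welch(x, fs=128.0, nperseg=1024)
            return p[(f >= 20) & (f <= 45)].sum()
        assert band_power(out.data[i]) < 0.5 * band_power(rec.data[i])

    def test_no_peripheral_hf_source_flags_nothing(self):
        rng = np.random.default_rng(12)
        names = list(SCALP_LAYOUT) + ["HEOG", "VEOG"]
        data = 3.0 * _pink_noise(rng, len(names), 15000)
        rec = emv.ContinuousRecording(data=data, sfreq=128.0,
                                      channel_names=names,
                                      events=np.array([[100, 0], [400, 1]]))
        _, rep = emv.correct_muscle(rec, seed=6)
        assert rep.flagged_components == []

    def test_low_sfreq_rejected(self):
        names = list(SCALP_LAYOUT) + ["HEOG", "VEOG"]
        rec = emv.ContinuousRecording(
            data=np.zeros((len(names), 5000)), sfreq=64.0,
            channel_names=names, events=np.array([[10, 0]]))
        with pytest.raises(ParameterError):
            emv.correct_muscle(rec, seed=0)


# ---------------------------------------------------------------------------
# Peak-to-peak rejection
# ---------------------------------------------------------------------------

class TestRejectPeakToPeak:
    def _clean_epochs(self, n_trials=60, n_ch=10, n_times=50, noise=0.05):
        rng = np.random.default_rng(7)
        base = np.sin(np.linspace(0, 2 * np.pi, n_times)) * 5.0
        data = base[None, None, :] + noise * rng.standard_normal(
            (n_trials, n_ch, n_times))
        return make_epochs(data)

    def test_interpolate_mode_preserves_trial_count(self, small_epochs):
        out, log = emv.reject_peak_to_peak(small_epochs, "interpolate", seed=1)
        assert out.n_trials == small_epochs.n_trials
        assert log.dropped_trials == []

    def test_clean_epochs_untouched(self):
        ep = self._clean_epochs()
        out, log = emv.reject_peak_to_peak(ep, "interpolate", seed=1)
        assert all(d["action"] == "keep" for d in log.decisions)
        assert np.array_equal(out.data, ep.data)
        out2, log2 = emv.reject_peak_to_peak(ep, "reject", seed=1)
        assert out2.n_trials == ep.n_trials

    def test_planted_outlier_epoch_dropped_in_reject_mode(self):
        ep = self._clean_epochs(noise=1.0)
        ep.data[7, :9, :] += 1000.0 * np.sin(np.arange(50))
        out, log = emv.reject_peak_to_peak(ep, "reject", seed=1)
        assert 7 in log.dropped_trials
        assert 7 not in out.kept_trial_index

    def test_too_few_survivors_invalidates_path(self):
        ep = self._clean_epochs(n_trials=30, noise=1.0)
        # four class-0 trials are hopeless: huge swings on 9 of 10 channels,
        # so any consensus level drops them and class 0 falls below the
        # downstream fold count
        bad = np.flatnonzero(ep.labels == 0)[:4]
        ep.data[bad, :9, :] += 1000.0 * np.sin(np.arange(50))
        with pytest.raises(PathInvalidError):
            emv.reject_peak_to_peak(ep, "reject", seed=1,
                                    min_trials_per_class=13)

    def test_deterministic_under_seed(self, small_epochs):
        a, la = emv.reject_peak_to_peak(small_epochs, "reject", seed=9)
        b, lb = emv.reject_peak_to_peak(small_epochs, "reject", seed=9)
        assert np.array_equal(a.data, b.data)
        assert la.dropped_trials == lb.dropped_trials
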