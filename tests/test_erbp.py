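"""Signal chain: downsampling, band envelope, epoching, ERBP, artifacts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hglock import erbp as E
from hglock.dataio import Recording, TrialEvent


def _sine_rec(freq, fs=2000.0, dur=2.0, n_ch=1):
    t = np.arange(0, dur, 1 / fs)
    x = np.sin(2 * np.pi * freq * t)
    return Recording(np.tile(x, (n_ch, 1)), fs, [f"c{i}" for i in range(n_ch)])


class TestDownsample:
    def test_length_bookkeeping(self):
        rec = Recording(np.zeros((2, 2001)), 2000.0, ["a", "b"])
        out = E.downsample(rec, 1000.0)
        assert out.samples.shape == (2, int(np.ceil(2001 / 2)))
        assert out.fs == 1000.0

    def test_passband_amplitude_preserved(self):
        out = E.downsample(_sine_rec(40.0), 1000.0)
        mid = out.samples[0][200:-200]
        assert abs(np.abs(mid).max() - 1.0) < 0.01

    def test_alias_band_attenuated(self):
        out = E.downsample(_sine_rec(900.0), 1000.0)
        assert np.abs(out.samples[0][200:-200]).max() < 0.05

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            E.downsample(_sine_rec(10.0, fs=1000.0), 2000.0)


class TestHighGammaEnvelope:
    def test_zero_input_zero_envelope(self):
        env = E.highgamma_envelope(np.zeros(2000), 1000.0)
        np.testing.assert_allclose(env, 0.0)

    def test_midband_tone_unit_envelope(self):
        t = np.arange(0, 5, 1e-3)
        env = E.highgamma_envelope(np.sin(2 * np.pi * 110 * t), 1000.0)
        steady = env[1000:-1000]
        assert np.abs(steady - 1.0).max() < 0.05

    def test_stopband_tone_suppressed(self):
        t = np.arange(0, 5, 1e-3)
        env = E.highgamma_envelope(np.sin(2 * np.pi * 30 * t), 1000.0)
        assert env[1000:-1000].max() < 0.1

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="short"):
            E.highgamma_envelope(np.zeros(150), 1000.0)

    @given(scale=st.floats(min_value=0.01, max_value=1000.0))
    @settings(max_examples=25, deadline=None)
    def test_linearity_in_amplitude(self, scale):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 3000)
        base = E.highgamma_envelope(x, 1000.0)
        scaled = E.highgamma_envelope(scale * x, 1000.0)
        np.testing.assert_allclose(scaled, scale * base, rtol=1e-9, atol=1e-12)


class TestEpoch:
    fs = 1000.0

    def _signals(self, n=10000):
        x = np.arange(n, dtype=float)
        return x, x, x

    def test_row_shape_and_times(self):
        raw, hg, env = self._signals()
        events = [TrialEvent(1.0, "w", True), TrialEvent(3.0, "w", True),
                  TrialEvent(5.0, "w", True)]
        ep = E.epoch(raw, hg, env, self.fs, events, "stimulus", (-500, 2000))
        assert ep.raw.shape == (3, 2500)
        assert ep.times_ms[0] == -500 and ep.times_ms[-1] == 1999
        np.testing.assert_allclose(np.diff(ep.times_ms), 1.0)

    def test_press_alignment_skips_pressless(self):
        raw, hg, env = self._signals()
        events = [TrialEvent(1.0, "w", True, press_s=1.8),
                  TrialEvent(3.0, "w", True),
                  TrialEvent(5.0, "w", True, press_s=5.9)]
        ep = E.epoch(raw, hg, env, self.fs, events, "press", (-750, 500))
        assert ep.n_trials == 2
        assert list(ep.trial_index) == [0, 2]

    def test_impulse_lands_at_expected_column(self):
        raw = np.zeros(8000)
        onset = 2.0
        raw[int((onset + 0.100) * self.fs)] = 1.0
        ep = E.epoch(raw, raw, raw, self.fs, [TrialEvent(onset, "w", True)],
                     "stimulus", (-500, 2000))
        col = int(np.flatnonzero(ep.raw[0])[0])
        assert ep.times_ms[col] == pytest.approx(100.0)

    def test_out_of_bounds_trial_dropped(self):
        raw, hg, env = self._signals(3000)
        events = [TrialEvent(0.2, "w", True), TrialEvent(1.0, "w", True)]
        ep = E.epoch(raw, hg, env, self.fs, events, "stimulus", (-500, 2000))
        assert ep.n_trials == 1 and ep.trial_index[0] == 1


class TestComputeERBP:
    def _epochs(self, env, times_ms, alignment="stimulus"):
        return E.EpochSet(raw=np.zeros_like(env), hg_filtered=np.zeros_like(env),
                          envelope=env, times_ms=times_ms, alignment=alignment,
                          trial_index=np.arange(env.shape[0]))

    def test_constant_envelope_gives_zero(self):
        times = np.arange(-500.0, 2000.0)
        env = np.full((4, times.size), 3.7)
        m = E.compute_erbp(self._epochs(env, times), (-200, -50))
        np.testing.assert_allclose(m.values, 0.0, atol=1e-9)

    @pytest.mark.parametrize("ratio,expected_db", [
        (2.0, 20 * np.log10(2.0)), (np.sqrt(10.0), 10.0), (10.0, 20.0)])
    def test_amplitude_ratio_in_decibels(self, ratio, expected_db):
        times = np.arange(-500.0, 2000.0)
        env = np.ones((2, times.size))
        win = (times >= 50) & (times < 300)
        env[:, win] *= ratio
        m = E.compute_erbp(self._epochs(env, times), (-200, -50))
        measured = m.values[:, win].mean()
        assert measured == pytest.approx(expected_db, abs=1e-6)

    def test_baseline_window_mean_is_zero(self, rng):
        # baseline self-consistency for arbitrary positive envelopes
        times = np.arange(-500.0, 2000.0)
        env = rng.lognormal(0, 1, size=(6, times.size))
        m = E.compute_erbp(self._epochs(env, times), (-200, -50))
        base = (times >= -200) & (times < -50)
        np.testing.assert_allclose(m.values[:, base].mean(axis=1), 0.0,
                                   atol=1e-9)

    def test_pooled_baseline_mode(self, rng):
        times = np.arange(-500.0, 2000.0)
        env = rng.lognormal(0, 1, size=(6, times.size))
        m = E.compute_erbp(self._epochs(env, times), (-200, -50),
                           baseline_mode="pooled")
        base = (times >= -200) & (times < -50)
        # per-trial baselines no longer vanish, but the grand mean does
        assert abs(m.values[:, base].mean()) < 1e-9

    def test_press_alignment_requires_external_baseline(self):
        times = np.arange(-750.0, 500.0)
        env = np.ones((2, times.size))
        with pytest.raises(ValueError, match="baseline"):
            E.compute_erbp(self._epochs(env, times, "press"), (-200, -50))

    def test_zero_envelope_handled_by_floor(self):
        times = np.arange(-500.0, 2000.0)
        env = np.zeros((2, times.size))
        m = E.compute_erbp(self._epochs(env, times), (-200, -50))
        assert np.isfinite(m.values).all()


class TestArtifactRejection:
    def _epochs(self, raw, hg):
        times = np.arange(raw.shape[1], dtype=float)
        return E.EpochSet(raw=raw, hg_filtered=hg, envelope=np.abs(hg),
                          times_ms=times, alignment="stimulus",
                          trial_index=np.arange(raw.shape[0]))

    def test_clean_gaussian_trials_kept(self, rng):
        raw = rng.normal(0, 1, (20, 500))
        raw = np.clip(raw, -4.5, 4.5)
        stats = E.BlockStats(0.0, 1.0, 0.0, 1.0)
        keep = E.reject_artifacts(self._epochs(raw, raw * 0.1), stats)
        assert keep.all()

    def test_raw_spike_above_5sd_excluded(self, rng):
        raw = np.clip(rng.normal(0, 1, (5, 500)), -4, 4)
        raw[2, 100] = 6.0
        stats = E.BlockStats(0.0, 1.0, 0.0, 1.0)
        keep = E.reject_artifacts(self._epochs(raw, raw * 0.01), stats)
        assert list(keep) == [True, True, False, True, True]

    def test_hg_excursion_above_10sd_excluded(self, rng):
        raw = np.clip(rng.normal(0, 1, (5, 500)), -4, 4)
        hg = np.clip(rng.normal(0, 0.5, (5, 500)), -2, 2)
        hg[1, 50] = 5.6  # 11.2 SD of the hg block SD below
        stats = E.BlockStats(0.0, 1.0, 0.0, 0.5)
        keep = E.reject_artifacts(self._epochs(raw, hg), stats)
        assert list(keep) == [True, False, True, True, True]

    def test_zero_block_sd_rejected(self):
        raw = np.zeros((2, 100))
        with pytest.raises(ValueError, match="degenerate"):
            E.reject_artifacts(self._epochs(raw, raw),
                               E.BlockStats(0.0, 0.0, 0.0, 0.0))
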