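"""Sustained-response pipeline: slow-band preprocessing, trial rejection,
DSS denoising, transition statistic and its bootstrap floor."""

import numpy as np
import pytest
from scipy import signal

import multisync as ms
from multisync.sustained_response import (
    bootstrap_transition_floor,
    dss_trial_average,
    lowpass_trials,
    preprocess_sustained,
    reject_high_power_trials,
    sustained_pipeline,
    sustained_timecourse,
    transition_difference,
)

CYCLE_S = 5 / 6.8


def zero_mean_gains(n_ch, seed=1):
    g = np.random.default_rng(seed).standard_normal(n_ch)
    g -= g.mean()
    g /= np.sqrt(np.mean(g ** 2))
    return tuple(np.concatenate([g, [0.0, 0.0]]))


def pattern_block(n_trials, seed=0):
    rng = np.random.default_rng(seed)
    return ms.build_block(rng, condition="target-alone",
                          n_patterns=n_trials, n_random=0)


def simulate(n_trials=8, step_uv=0.0, noise=0.3, seed=3, n_ch=12):
    block = pattern_block(n_trials)
    params = ms.desk_scale_params(
        seed=seed, n_channels=n_ch, noise_scale=noise,
        sustained_step_uv=step_uv, efr_amp=0.0, ecfr_amp=0.0,
        beat_amp=0.0, distractor_efr_amp=0.0,
        channel_gains=zero_mean_gains(n_ch))
    return ms.simulate_block(block, params)


class TestPreprocessSustained:
    def test_output_rate_and_baseline(self):
        res = simulate(n_trials=5)
        trials, times, fs = preprocess_sustained(res.eeg, 12 * CYCLE_S)
        assert fs == 256.0
        assert times[0] == pytest.approx(-1.0)
        n_pre = int(256 * 1.0)
        base = trials[:, :, :n_pre].mean(axis=2)
        assert np.abs(base).max() < 1e-9

    def test_out_of_band_tone_attenuated(self):
        fs = 1024.0
        t = np.arange(int(20 * fs)) / fs
        gains = np.array([1.0, -0.5, 0.8, -1.3, 0.0, 0.0])
        data = gains[:, None] * np.sin(2 * np.pi * 200 * t)  # above 110 Hz
        inband = np.sin(2 * np.pi * 5 * t)
        import pandas as pd

        from multisync.core import EEGData

        events = pd.DataFrame([dict(sample_index=int(3 * fs), kind="trial",
                                    trial_index=0)])
        eeg = EEGData(data, fs, [f"c{i}" for i in range(4)] + ["M1", "M2"],
                      events)
        trials, _, _ = preprocess_sustained(eeg, 10.0)
        data2 = gains[:, None] * inband
        eeg2 = EEGData(data2, fs, eeg.channel_labels, events)
        trials2, _, _ = preprocess_sustained(eeg2, 10.0)
        ratio = np.std(trials) / np.std(trials2)
        assert 20 * np.log10(ratio) < -20

    def test_insufficient_prestim_raises(self):
        res = simulate(n_trials=3)
        with pytest.raises(ValueError):
            preprocess_sustained(res.eeg, 12 * CYCLE_S, prestim_s=10.0)


class TestRejection:
    def test_equal_power_trials_all_kept(self):
        trials = np.ones((10, 2, 8))
        kept, mask = reject_high_power_trials(trials)
        assert mask.all()

    def test_outlier_rejected(self):
        rng = np.random.default_rng(0)
        trials = rng.standard_normal((50, 2, 64))
        trials[13] *= 10.0
        _, mask = reject_high_power_trials(trials)
        assert not mask[13]
        assert mask.sum() >= 48

    def test_gaussian_upper_tail_rate(self):
        # powers ~ N(10, 1): one-sided 2 SD rejection keeps ~97.7%
        rng = np.random.default_rng(1)
        p = 10.0 + rng.standard_normal(5000)
        trials = np.sqrt(p)[:, None, None] * np.ones((5000, 1, 4))
        _, mask = reject_high_power_trials(trials)
        rate = 1 - mask.mean()
        assert rate == pytest.approx(0.0228, abs=0.007)

    def test_quiet_trials_kept(self):
        rng = np.random.default_rng(2)
        trials = rng.standard_normal((40, 2, 64))
        trials[5] *= 0.01  # unusually quiet, but only excesses rejected
        _, mask = reject_high_power_trials(trials)
        assert mask[5]

    def test_minimum_trial_count(self):
        with pytest.raises(ValueError):
            reject_high_power_trials(np.ones((4, 2, 8)))


class TestDss:
    def planted(self, noise=2.0, n_trials=40, n_ch=10, n_samp=256, seed=5):
        rng = np.random.default_rng(seed)
        src = np.sin(2 * np.pi * 3 * np.arange(n_samp) / 256)
        mix = rng.standard_normal(n_ch)
        trials = (src[None, None, :] * mix[None, :, None]
                  + noise * rng.standard_normal((n_trials, n_ch, n_samp)))
        return trials, src

    def test_first_component_beats_every_raw_channel(self):
        trials, src = self.planted()
        _, comps, _, _ = dss_trial_average(trials, n_keep=1,
                                           return_components=True)
        c_dss = abs(np.corrcoef(comps[:, 0].mean(axis=0), src)[0, 1])
        avg = trials.mean(axis=0)
        c_raw = max(abs(np.corrcoef(avg[c], src)[0, 1])
                    for c in range(trials.shape[1]))
        assert c_dss > c_raw

    def test_noise_free_reconstruction(self):
        trials, src = self.planted(noise=0.0, n_trials=6)
        with pytest.warns(UserWarning):  # rank 1 < n_keep
            out = dss_trial_average(trials, n_keep=5)
        err = np.abs(out - trials).max() / np.abs(trials).max()
        assert err < 0.01

    def test_full_rank_keep_is_identity(self):
        trials, _ = self.planted()
        out = dss_trial_average(trials, n_keep=trials.shape[1])
        np.testing.assert_allclose(out, trials, atol=1e-9)


class TestTransitionStatistic:
    def test_stationary_timecourse_zero(self):
        times = np.arange(0, 10, 1 / 256)
        tc = np.full(times.size, 1.7)
        assert transition_difference(tc, times, 4.0, 1.0) == 0.0

    def test_step_recovered_exactly(self):
        times = np.arange(0, 10, 1 / 256)
        h = 0.8
        tc = 1.0 + h * (times >= 4.0)
        assert transition_difference(tc, times, 4.0, 1.0) == pytest.approx(h)

    def test_window_overflow_raises(self):
        times = np.arange(0, 3, 1 / 256)
        with pytest.raises(ValueError):
            transition_difference(np.ones(times.size), times, 2.5, 1.0)


class TestBootstrapFloor:
    def test_stationary_noise_statistic_within_envelope(self):
        rng = np.random.default_rng(0)
        times = np.arange(0, 60, 1 / 256)
        hits = 0
        for rep in range(10):
            tc = 1 + 0.1 * np.cumsum(
                rng.standard_normal(times.size)) / np.sqrt(times.size)
            stat = transition_difference(tc, times, 30.0, CYCLE_S)
            floor = bootstrap_transition_floor(
                tc, times, CYCLE_S, np.random.default_rng(rep), n_boot=200)
            lo, hi = np.percentile(floor, [2.5, 97.5])
            hits += lo <= stat <= hi
        assert hits >= 9

    def test_reproducible_with_seed(self):
        times = np.arange(0, 30, 1 / 256)
        tc = np.sin(times) + 2
        f1 = bootstrap_transition_floor(tc, times, CYCLE_S,
                                        np.random.default_rng(3), n_boot=50)
        f2 = bootstrap_transition_floor(tc, times, CYCLE_S,
                                        np.random.default_rng(3), n_boot=50)
        np.testing.assert_array_equal(f1, f2)

    def test_large_step_outside_envelope(self):
        rng = np.random.default_rng(1)
        times = np.arange(0, 60, 1 / 256)
        tc = 1 + 0.02 * rng.standard_normal(times.size)
        tc += 1.0 * (times >= 30.0)
        stat = transition_difference(tc, times, 30.0, CYCLE_S)
        floor = bootstrap_transition_floor(tc, times, CYCLE_S,
                                           np.random.default_rng(2),
                                           n_boot=400)
        assert stat > np.percentile(floor, 97.5)

    def test_too_short_trial_raises(self):
        times = np.arange(0, 2, 1 / 256)
        with pytest.raises(ValueError):
            bootstrap_transition_floor(np.ones(times.size), times, CYCLE_S,
                                       np.random.default_rng(0))


class TestPipeline:
    def test_stage_order(self):
        res = simulate(n_trials=6)
        trace = []
        sustained_pipeline(res.eeg, 12 * CYCLE_S, 4 * CYCLE_S, CYCLE_S,
                           np.random.default_rng(0), n_boot=20, trace=trace)
        assert trace == ["filter+downsample+reref+baseline", "reject",
                         "lowpass30", "dss", "rms", "statistic", "bootstrap"]

    def test_null_simulator_statistic_within_floor(self):
        """With no pattern-evoked sustained shift in the generator, the
        transition statistic stays inside the bootstrap floor — the
        paradigm's null finding."""
        res = simulate(n_trials=10, step_uv=0.0, noise=0.3)
        out = sustained_pipeline(res.eeg, 12 * CYCLE_S, 4 * CYCLE_S,
                                 CYCLE_S, np.random.default_rng(1),
                                 n_boot=300)
        lo, hi = out.floor_envelope(99.0)
        assert lo <= out.statistic <= hi

    def test_injected_step_matches_filtered_oracle(self):
        """A transition-locked DC shift, noise-free: the pipeline recovers
        exactly the statistic of the known source waveform passed through
        the same filter chain (a DC step is not inside the 0.1-110 Hz
        analysis band, so the in-band response is the reference)."""
        h = 2.0
        res = simulate(n_trials=6, step_uv=h, noise=0.0)
        out = sustained_pipeline(res.eeg, 12 * CYCLE_S, 4 * CYCLE_S,
                                 CYCLE_S, np.random.default_rng(1),
                                 n_boot=20)
        # oracle: the same injected sources (all trials — the slow
        # high-pass rings across trials), same filters, single channel
        from multisync.preprocess import zero_phase_bandpass

        fs = res.eeg.sample_rate_hz
        onsets = res.eeg.events.loc[res.eeg.events["kind"] == "trial",
                                    "sample_index"].to_numpy()
        n_trial = int(round(12 * CYCLE_S * fs))
        src = np.zeros(res.eeg.n_samples)
        for o in onsets:
            t_rel = (np.arange(n_trial)) / fs
            src[o:o + n_trial] += h * np.clip(
                (t_rel - 4 * CYCLE_S) / 0.2, 0, 1)
        filt = zero_phase_bandpass(src, fs, (0.1, 110.0), 5)
        filt = signal.resample_poly(filt, 256, int(fs))
        n_pre = 256
        n_win = n_pre + int(round(12 * CYCLE_S * 256))
        segs = []
        for o in onsets:
            o2 = int(round(o * 256 / fs))
            seg = filt[o2 - n_pre:o2 - n_pre + n_win].copy()
            segs.append(seg - seg[:n_pre].mean())
        avg = np.mean(segs, axis=0)
        sos30 = signal.butter(5, 30.0, btype="lowpass", fs=256.0,
                              output="sos")
        avg = signal.sosfiltfilt(sos30, avg)
        times = (np.arange(n_win) - n_pre) / 256.0
        expected = transition_difference(np.abs(avg), times, 4 * CYCLE_S,
                                         CYCLE_S)
        assert out.statistic == pytest.approx(expected, rel=0.05)
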