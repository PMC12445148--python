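"""Phase-locking value spectra, noise floors, bootstrap equalization and
asymmetry statistics."""

import numpy as np
import pytest

import multisync as ms
from conftest import make_epochs


def sine_epochs(n_epochs, n_ch, n_samp, fs, freq, amp=1.0, phase=0.0,
                noise=0.0, rng=None):
    t = np.arange(n_samp) / fs
    base = amp * np.sin(2 * np.pi * freq * t + phase)
    data = np.tile(base, (n_epochs, n_ch, 1))
    if noise and rng is not None:
        data = data + noise * rng.standard_normal(data.shape)
    return make_epochs(data, fs)


class TestPlvSpectrum:
    def test_identical_epochs_lock_perfectly(self):
        rng = np.random.default_rng(0)
        one = rng.standard_normal((1, 4, 64))
        es = make_epochs(np.repeat(one, 10, axis=0))
        sp = ms.plv_spectrum(es)
        mag = np.abs(np.fft.rfft(one[0, 0]))
        assert np.all(sp.plv[mag > 1e-9] == pytest.approx(1.0))

    def test_opposite_phases_cancel(self):
        fs, n = 512.0, 128
        t = np.arange(n) / fs
        a = np.sin(2 * np.pi * 16 * t)
        data = np.stack([np.tile(a, (2, 1)), np.tile(-a, (2, 1))])
        sp = ms.plv_spectrum(make_epochs(data, fs))
        assert sp.value_at(16.0) == pytest.approx(0.0, abs=1e-12)

    def test_single_epoch_rejected(self):
        with pytest.raises(ValueError):
            ms.plv_spectrum(make_epochs(np.zeros((1, 2, 32))))

    def test_plv_bounded_and_rms_below_max(self, melody_sim, spec):
        eeg, _ = melody_sim
        ep = ms.extract_epochs(eeg, "two-token", spec=spec,
                               channel_mask=eeg.scalp_mask)
        sp = ms.plv_spectrum(ep)
        assert np.all(sp.per_channel >= 0) and np.all(sp.per_channel <= 1)
        assert np.all(sp.plv <= sp.per_channel.max(axis=0) + 1e-12)

    @pytest.mark.parametrize("n_epochs", [50, 300])
    def test_uniform_phase_floor(self, n_epochs):
        """Mean PLV of N noise epochs matches the uniform-phase resultant
        sqrt(pi / 4N) within 5%."""
        rng = np.random.default_rng(n_epochs)
        data = rng.standard_normal((n_epochs, 8, 256))
        sp = ms.plv_spectrum(make_epochs(data))
        measured = sp.per_channel[:, 1:].mean()
        assert measured == pytest.approx(np.sqrt(np.pi / (4 * n_epochs)),
                                         rel=0.05)


class TestFfrPlv:
    def build(self, flip_amp=1.0, inv_amp=1.0, noise=0.05, n=40):
        """Cycle epochs holding a polarity-flipping carrier plus a
        polarity-invariant envelope component."""
        fs, n_samp = 4096.0, int(round(4096 * 5 / 6.8))
        t = np.arange(n_samp) / fs
        carrier = np.sin(2 * np.pi * 516.8 * t)
        envcomp = np.sin(2 * np.pi * 68.0 * t)
        rng = np.random.default_rng(1)
        pos = (flip_amp * carrier + inv_amp * envcomp
               + noise * rng.standard_normal((n, 6, n_samp)))
        neg = (-flip_amp * carrier + inv_amp * envcomp
               + noise * rng.standard_normal((n, 6, n_samp)))
        return make_epochs(pos, fs), make_epochs(neg, fs)

    def test_difference_mode_separates_carrier(self, spec):
        pos, neg = self.build()
        sp = ms.ffr_plv(pos, neg)
        assert sp.value_at(516.8) >= 0.9
        floor = ms.noise_floor(sp, [68.0], spec=spec)[0]
        assert sp.value_at(68.0) < 2 * floor

    def test_noise_free_carrier_locks_fully(self):
        pos, neg = self.build(inv_amp=0.0, noise=0.0, n=4)
        sp = ms.ffr_plv(pos, neg)
        assert sp.value_at(516.8) == pytest.approx(1.0, abs=1e-9)

    def test_literal_mode_near_zero_for_symmetric_stats(self):
        rng = np.random.default_rng(2)
        pos = make_epochs(rng.standard_normal((60, 4, 128)))
        neg = make_epochs(rng.standard_normal((60, 4, 128)))
        sp = ms.ffr_plv(pos, neg, mode="plv-difference")
        # expectation zero; fluctuations at the subsampled floor scale
        assert np.abs(sp.plv).mean() < 2 * np.sqrt(np.pi / (4 * 60))

    def test_unpaired_counts_warn(self):
        pos, neg = self.build(n=5)
        neg = neg.select(np.arange(4))
        with pytest.warns(UserWarning):
            sp = ms.ffr_plv(pos, neg)
        assert sp.n_epochs == 4


class TestNoiseFloor:
    def test_floor_ignores_injected_peak(self, spec):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((80, 4, 150))
        peak_freq = 2 * 512.0 / 150  # exactly the bin nearest 6.8 Hz
        floors = []
        for amp in (0.0, 5.0):
            data = base.copy()
            t = np.arange(150) / 512.0
            data += amp * np.sin(2 * np.pi * peak_freq * t)
            sp = ms.plv_spectrum(make_epochs(data))
            floors.append(ms.noise_floor(sp, [6.8], spec=spec)[0])
        assert floors[1] == pytest.approx(floors[0], rel=1e-6)

    def test_floor_shrinks_with_epoch_count(self, spec):
        # 4x the epochs halve the floor (~ 1/sqrt(N))
        rng = np.random.default_rng(1)
        floors = []
        for n in (50, 200):
            data = rng.standard_normal((n, 4, 150))
            sp = ms.plv_spectrum(make_epochs(data))
            floors.append(ms.noise_floor(sp, [6.8], spec=spec,
                                         half_bins=40)[0])
        assert floors[1] == pytest.approx(floors[0] / 2, rel=0.2)

    def test_all_bins_related_raises(self, spec):
        rng = np.random.default_rng(2)
        sp = ms.plv_spectrum(make_epochs(rng.standard_normal((10, 2, 64))))
        with pytest.raises(ValueError):
            ms.noise_floor(sp, [6.8], related_freqs=sp.freqs_hz)


class TestEqualize:
    def test_equal_counts_passthrough(self):
        rng = np.random.default_rng(0)
        a = make_epochs(rng.standard_normal((30, 3, 64)))
        b = make_epochs(rng.standard_normal((30, 3, 64)))
        out = ms.equalize_and_average({"a": a, "b": b},
                                      np.random.default_rng(1))
        np.testing.assert_allclose(out["a"].plv, ms.plv_spectrum(a).plv)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(0)
        a = make_epochs(rng.standard_normal((20, 3, 64)))
        b = make_epochs(rng.standard_normal((90, 3, 64)))
        o1 = ms.equalize_and_average({"a": a, "b": b},
                                     np.random.default_rng(5), n_iter=50)
        o2 = ms.equalize_and_average({"a": a, "b": b},
                                     np.random.default_rng(5), n_iter=50)
        np.testing.assert_array_equal(o1["b"].plv, o2["b"].plv)

    def test_subsampled_floor_matches_small_set(self):
        """Bootstrap-averaged PLV of a large noise set subsampled to n
        matches the floor of a genuinely n-sized set."""
        rng = np.random.default_rng(3)
        small = make_epochs(rng.standard_normal((40, 4, 128)))
        big = make_epochs(rng.standard_normal((400, 4, 128)))
        out = ms.equalize_and_average({"s": small, "b": big},
                                      np.random.default_rng(7))
        mean_b = out["b"].per_channel[:, 1:].mean()
        expected = np.sqrt(np.pi / (4 * 40))
        assert mean_b == pytest.approx(expected, rel=0.05)
        assert out["b"].n_epochs == 40

    def test_too_few_epochs_raise(self):
        a = make_epochs(np.zeros((1, 2, 16)))
        with pytest.raises(ValueError):
            ms.equalize_and_average({"a": a}, np.random.default_rng(0))


class TestEcfrByDelta:
    def test_eight_classes_with_equalized_counts(self, melody_sim, spec):
        eeg, _ = melody_sim
        ep = ms.extract_epochs(eeg, "two-token", spec=spec,
                               channel_mask=eeg.scalp_mask)
        out = ms.ecfr_by_delta(ep, np.random.default_rng(0), spec,
                               n_iter=100)
        assert len(out) == 8
        assert set(out["delta_hz_nominal"]) == {-54, -41, -27, -14,
                                                14, 27, 41, 54}
        assert out["n_effective"].nunique() == 1

    def test_recovers_monotone_amplitude_scaling(self, spec):
        """With simulated envelope-change amplitude proportional to the AM
        step, class PLVs rise with |step|."""
        rng = np.random.default_rng(0)
        block = ms.build_block(rng, condition="target-alone", n_patterns=10)
        block.trials = block.trials[:20]
        params = ms.desk_scale_params(seed=31, efr_amp=0.0, beat_amp=0.0,
                                      distractor_efr_amp=0.0)
        res = ms.simulate_block(block, params, spec)
        eeg = ms.bandpass_and_reref(res.eeg)
        ep = ms.extract_epochs(eeg, "two-token", spec=spec,
                               channel_mask=eeg.scalp_mask)
        out = ms.ecfr_by_delta(ep, np.random.default_rng(1), spec,
                               n_iter=200)
        by_mag = out.groupby(out["delta_m"].abs())["plv"].mean()
        vals = by_mag.sort_index().to_numpy()
        assert np.all(np.diff(vals) > 0)

    def test_requires_delta_labels(self, melody_sim, spec):
        eeg, _ = melody_sim
        ep = ms.extract_epochs(eeg, "cycle", spec=spec)
        with pytest.raises(ValueError):
            ms.ecfr_by_delta(ep, np.random.default_rng(0), spec)


class TestAsymmetry:
    def test_equal_plvs_zero(self):
        assert ms.asymmetry_index(0.05, 0.05) == 0.0

    def test_absent_incorrect_is_one(self):
        assert ms.asymmetry_index(0.05, 0.0) == 1.0

    def test_arithmetic(self):
        assert ms.asymmetry_index(0.048, 0.030) == pytest.approx(0.2308,
                                                                 abs=1e-4)

    def test_both_zero_undefined(self):
        assert np.isnan(ms.asymmetry_index(0.0, 0.0))

    def test_inclusion_rules(self):
        r = ms.participant_asymmetry("ecfr", 0.08, 0.05, floor=0.03,
                                     error_rate=0.25)
        assert r.included and r.value == pytest.approx(0.2308, abs=1e-3)
        r = ms.participant_asymmetry("ecfr", 0.08, 0.05, floor=0.03,
                                     error_rate=0.10)
        assert not r.included
        r = ms.participant_asymmetry("ecfr", 0.02, 0.01, floor=0.03,
                                     error_rate=0.25)
        assert not r.included
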