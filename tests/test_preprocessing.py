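import numpy as np
import pytest

import vocdecode as vd
from vocdecode.epochs import EpochArray
from vocdecode.preprocessing import detect_vocal_onset
from vocdecode.synth import AUDIO_SFREQ, simulate_audio
from vocdecode.task_design import GO_ONSET_MS, TrialSpec
import pandas as pd


def make_epochs(data, sfreq=300.0, tmin_ms=-500.0):
    return EpochArray(data=data, sfreq=sfreq, tmin_ms=tmin_ms)


class TestJumpRepair:
    def test_clean_input_untouched(self, rng):
        ep = make_epochs(rng.standard_normal((3, 2, 400)))
        out = vd.repair_channel_jumps(ep, jump_sd_factor=20)
        assert np.array_equal(out.data, ep.data)

    @pytest.mark.parametrize("positions", [[150], [100, 250]])
    def test_injected_steps_removed(self, rng, positions):
        base = rng.standard_normal((1, 1, 400))
        sd = np.std(np.diff(base[0, 0]))
        jumped = base.copy()
        for k in positions:
            jumped[0, 0, k:] += 50 * sd
        out = vd.repair_channel_jumps(make_epochs(jumped), jump_sd_factor=20)
        d = np.diff(out.data[0, 0])
        assert np.abs(d).max() < 20 * 1.4826 * np.median(np.abs(d - np.median(d)))
        # repaired trace follows the clean one up to piecewise-constant offsets
        # of sample-noise magnitude (the step itself, ~50 SD, is gone)
        resid = out.data[0, 0] - base[0, 0]
        assert np.abs(np.diff(resid)).max() < 5 * sd

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            vd.repair_channel_jumps(make_epochs(np.zeros((1, 1, 1))))


class TestLowpass:
    def test_passband_preserved(self):
        t = np.arange(0, 3, 1 / 300)
        sig = np.sin(2 * np.pi * 1.0 * t)[None, None, :]
        out = vd.zero_phase_lowpass(make_epochs(sig), 30.0)
        mid = slice(150, -150)
        ratio = np.abs(out.data[0, 0, mid]).max() / np.abs(sig[0, 0, mid]).max()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_stopband_attenuated_40db(self):
        t = np.arange(0, 3, 1 / 300)
        sig = np.sin(2 * np.pi * 100.0 * t)[None, None, :]
        out = vd.zero_phase_lowpass(make_epochs(sig), 30.0)
        atten = 20 * np.log10(np.abs(out.data[0, 0, 300:-300]).max())
        assert atten < -40

    def test_zero_phase_symmetric_impulse_response(self):
        imp = np.zeros((1, 1, 601))
        imp[0, 0, 300] = 1.0
        out = vd.zero_phase_lowpass(make_epochs(imp), 30.0).data[0, 0]
        assert np.allclose(out, out[::-1], atol=1e-10)

    def test_cutoff_above_nyquist_raises(self):
        with pytest.raises(ValueError):
            vd.zero_phase_lowpass(make_epochs(np.zeros((1, 1, 100))), 200.0)


class TestResample:
    def test_length_ratio(self):
        ep = make_epochs(np.random.default_rng(0).standard_normal((2, 3, 7031)),
                         sfreq=2342.75)
        out = vd.resample_to(ep, 300.0)
        expected = 7031 * 300.0 / 2342.75
        assert abs(out.n_samples - expected) <= 2
        assert out.sfreq == pytest.approx(300.0, rel=1e-3)

    def test_identity_when_equal(self, rng):
        ep = make_epochs(rng.standard_normal((1, 1, 100)))
        out = vd.resample_to(ep, 300.0)
        assert np.array_equal(out.data, ep.data)

    def test_dc_preserved(self):
        ep = make_epochs(np.full((1, 1, 3000), 2.5), sfreq=600.0)
        out = vd.resample_to(ep, 300.0)
        assert np.allclose(out.data[0, 0, 10:-10], 2.5, atol=1e-6)

    def test_upsampling_raises(self):
        with pytest.raises(ValueError):
            vd.resample_to(make_epochs(np.zeros((1, 1, 100))), 600.0)


class TestBaseline:
    def test_baseline_mean_zero(self, rng):
        ep = make_epochs(rng.standard_normal((4, 3, 900)) + 5.0)
        out = vd.baseline_correct(ep, (-500.0, 0.0))
        mask = out.time_mask(-500.0, 0.0)
        assert np.allclose(out.data[:, :, mask].mean(axis=-1), 0.0, atol=1e-12)

    def test_constant_trial_zeroed(self):
        ep = make_epochs(np.full((1, 2, 900), 3.3))
        out = vd.baseline_correct(ep)
        assert np.allclose(out.data, 0.0)

    def test_window_outside_epoch_raises(self):
        ep = make_epochs(np.zeros((1, 1, 900)), tmin_ms=0.0)
        with pytest.raises(ValueError):
            vd.baseline_correct(ep, (-500.0, 0.0))


class TestVocalOnsetDetector:
    def _vocalized_trial(self):
        rule = vd.enumerate_rules()[0]
        return TrialSpec(0, rule, "u", "vocalized")

    def _imagined_ref(self, seed=99):
        rule = vd.enumerate_rules()[0]
        return simulate_audio(TrialSpec(0, rule, "u", "imagined"), seed=seed).waveform

    def test_window_size_in_samples(self):
        assert round(42.66e-3 * AUDIO_SFREQ) == 100

    def test_silent_trial_not_detected(self):
        res = detect_vocal_onset(self._imagined_ref(1), self._imagined_ref(2))
        assert not res.detected
        assert np.isnan(res.latency_ms)

    def test_planted_onset_recovered(self):
        tr = simulate_audio(self._vocalized_trial(), seed=21)
        res = detect_vocal_onset(tr.waveform, self._imagined_ref())
        assert res.detected
        assert abs(res.latency_ms - tr.onset_ms) <= 42.66  # one window width

    def test_detection_rate_and_accuracy(self):
        # detector contract on simulated audio: >=99% detection, |error|<=25 ms
        ref = self._imagined_ref()
        errors, detected = [], 0
        for seed in range(150):
            tr = simulate_audio(self._vocalized_trial(), seed=seed)
            res = detect_vocal_onset(tr.waveform, ref)
            if res.detected:
                detected += 1
                errors.append(abs(res.latency_ms - tr.onset_ms))
        assert detected >= 149
        assert np.median(errors) <= 25.0

    def test_empty_audio_raises(self):
        with pytest.raises(ValueError):
            detect_vocal_onset(np.array([]), self._imagined_ref())


class TestTrialSelection:
    def _table(self, **overrides):
        base = dict(production=["imagined", "vocalized", "vocalized", "vocalized"],
                    production_correct=[True, True, True, False],
                    vowel_correct=[True, True, False, True],
                    vocal_onset_ms=[np.nan, 450.0, 500.0, 620.0])
        base.update(overrides)
        return pd.DataFrame(base)

    def test_rule_branches(self):
        mask = vd.select_valid_trials(self._table())
        # imagined+correct kept; vocalized needs vowel correct and onset > 0
        assert mask.tolist() == [True, True, False, False]

    def test_onset_before_go_rejected(self):
        tab = self._table(vocal_onset_ms=[np.nan, -120.0, 500.0, 620.0])
        assert not vd.select_valid_trials(tab)[1]

    def test_audio_missing_session_uses_vowel_only(self):
        tab = self._table().drop(columns=["vocal_onset_ms"])
        mask = vd.select_valid_trials(tab)
        assert mask.tolist() == [True, True, False, False]

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError):
            vd.select_valid_trials(pd.DataFrame({"production": ["imagined"]}))


class TestSensorSubset:
    def test_counts_and_identity(self, rng):
        pos = rng.standard_normal((40, 3))
        idx = vd.select_sensor_subset(pos, 12)
        assert len(idx) == 12 and len(set(idx)) == 12
        assert sorted(vd.select_sensor_subset(pos, 40)) == list(range(40))

    def test_more_than_available_raises(self, rng):
        with pytest.raises(ValueError):
            vd.select_sensor_subset(rng.standard_normal((5, 3)), 6)

    def test_maximin_beats_random_subsets(self, rng):
        pos = rng.standard_normal((60, 3))
        idx = vd.select_sensor_subset(pos, 15)

        def min_dist(ix):
            sub = pos[np.asarray(ix)]
            d = np.linalg.norm(sub[:, None] - sub[None, :], axis=-1)
            return d[~np.eye(len(ix), dtype=bool)].min()

        ours = min_dist(idx)
        random_scores = [min_dist(rng.choice(60, 15, replace=False)) for _ in range(100)]
        assert ours >= np.median(random_scores)


class TestComposedPipeline:
    def test_order_and_shapes(self, rng):
        ep = make_epochs(rng.standard_normal((6, 4, 3000)), sfreq=600.0)
        out = vd.preprocess(ep, lp1_hz=30, resample_hz=300, lp2_hz=10)
        assert out.sfreq == pytest.approx(300.0)
        assert out.n_trials == 6 and out.n_channels == 4
        mask = out.time_mask(-500.0, 0.0)
        assert np.allclose(out.data[:, :, mask].mean(axis=-1), 0.0, atol=1e-10)
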