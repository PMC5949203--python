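"""Preprocessing: filtering, epoching, rejection, rereferencing, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sp_signal

from roismining.errors import (
    EmptyEpochSetError,
    InvalidParameterError,
    InvalidStateError,
)
from roismining.preprocess import (
    Recording,
    average_trials,
    bandpass_filter,
    baseline_correct,
    preprocess_pipeline,
    read_edf,
    read_recording_text,
    read_waveform_text,
    reject_artifacts,
    remove_bad_channels,
    rereference_average,
    segment_epochs,
    write_edf,
    write_recording_text,
    write_waveform_text,
)

from conftest import make_recording


def sinusoid_recording(freq_hz, rate_hz=1000.0, seconds=10.0, amplitude=10.0):
    t = np.arange(int(seconds * rate_hz)) / rate_hz
    data = amplitude * np.sin(2 * np.pi * freq_hz * t)[None, :].repeat(2, axis=0)
    return Recording(data=data, rate_hz=rate_hz, channel_labels=["A", "B"])


class TestBandpassFilter:
    def test_inband_sinusoid_passes(self):
        rec = sinusoid_recording(10.0, seconds=30.0)
        out = bandpass_filter(rec, 0.3, 30.0)
        # the 0.3 Hz highpass edge transient decays over seconds
        mid = slice(8000, -8000)
        assert np.abs(out.data[0, mid]).max() == pytest.approx(10.0, rel=0.05)

    def test_stopband_sinusoid_attenuated(self):
        rec = sinusoid_recording(50.0)
        out = bandpass_filter(rec, 0.3, 30.0)
        mid = slice(2000, -2000)
        rms_in = np.sqrt(np.mean(rec.data[0, mid] ** 2))
        rms_out = np.sqrt(np.mean(out.data[0, mid] ** 2))
        assert rms_out < 0.1 * rms_in

    def test_design_attenuation_at_50hz_exceeds_20db(self):
        # frequency response of the actual design, squared for forward-backward
        sos = sp_signal.butter(4, [0.3, 30.0], btype="bandpass", fs=1000.0, output="sos")
        w, h = sp_signal.sosfreqz(sos, worN=[50.0], fs=1000.0)
        atten_db = -20 * np.log10(np.abs(h[0]) ** 2)
        assert atten_db > 20.0

    def test_passband_center_within_1db(self):
        sos = sp_signal.butter(4, [0.3, 30.0], btype="bandpass", fs=1000.0, output="sos")
        _, h = sp_signal.sosfreqz(sos, worN=[10.0], fs=1000.0)
        gain_db = 20 * np.log10(np.abs(h[0]) ** 2)
        assert abs(gain_db) < 1.0

    def test_zero_input_zero_output(self):
        rec = Recording(np.zeros((3, 5000)), 1000.0, ["A", "B", "C"])
        out = bandpass_filter(rec, 0.3, 30.0)
        assert np.allclose(out.data, 0.0)

    @pytest.mark.parametrize("band", [(0.0, 30.0), (30.0, 0.3), (0.3, 600.0), (-1.0, 10.0)])
    def test_invalid_band_edges(self, band):
        rec = sinusoid_recording(10.0, seconds=1.0)
        with pytest.raises(InvalidParameterError):
            bandpass_filter(rec, *band)

    def test_events_unchanged(self, tiny_recording):
        out = bandpass_filter(tiny_recording, 1.0, 40.0)
        assert out.events == tiny_recording.events
        assert out.data.shape == tiny_recording.data.shape


class TestSegmentEpochs:
    @given(
        rate_hz=st.sampled_from([250.0, 500.0, 1000.0, 2048.0]),
        pre_ms=st.floats(0, 200),
        post_ms=st.floats(100, 800),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_epoch_length_formula(self, rate_hz, pre_ms, post_ms):
        n = int(3 * rate_hz)
        rec = Recording(
            np.zeros((2, n)), rate_hz, ["A", "B"], events=[(n // 2, "sound")]
        )
        ep = segment_epochs(rec, pre_ms, post_ms)
        assert ep.data.shape[2] == int(round((pre_ms + post_ms) / 1000.0 * rate_hz))

    def test_700_samples_at_1khz(self):
        rec = make_recording(events=((2000, "sound"),))
        ep = segment_epochs(rec, 100.0, 600.0)
        assert ep.data.shape[2] == 700
        assert ep.pre_samples == 100

    def test_event_near_edge_dropped(self):
        rec = make_recording(events=((50, "sound"), (2000, "sound")))
        ep = segment_epochs(rec, 100.0, 600.0)
        assert ep.n_trials == 1

    def test_target_events_excluded(self):
        rng = np.random.default_rng(3)
        events = []
        pos = 1000
        for tag in ["sound"] * 100 + ["nonsound"] * 100 + ["target"] * 20:
            events.append((pos, tag))
            pos += 800
        rec = Recording(
            np.zeros((2, pos + 1000)), 1000.0, ["A", "B"], events=events
        )
        ep = segment_epochs(rec, 100.0, 600.0)
        assert ep.n_trials == 200
        assert set(ep.condition_tags) == {"sound", "nonsound"}

    def test_no_events_raises(self):
        rec = make_recording(events=((2000, "target"),))
        with pytest.raises(EmptyEpochSetError):
            segment_epochs(rec, 100.0, 600.0)

    def test_onset_lands_on_pre_sample(self):
        rec = make_recording(events=((2000, "sound"),), amplitude=0.0)
        rec.data[0, 2000] = 42.0
        ep = segment_epochs(rec, 100.0, 600.0)
        assert ep.data[0, 0, ep.pre_samples] == 42.0


class TestRejectArtifacts:
    def _epochs(self, seed=0):
        rec = make_recording(
            n_samples=8000,
            events=tuple((800 * (i + 1), "sound") for i in range(8)),
            seed=seed,
            amplitude=3.0,
        )
        return segment_epochs(rec)

    def test_scalp_excursion_rejected(self):
        ep = self._epochs()
        ep.data[2, 0, 350] = 80.0  # one sample above 75 uV on a scalp channel
        out = reject_artifacts(ep)
        assert not out.accepted[2]
        assert out.accepted.sum() == ep.n_trials - 1

    def test_quiet_trial_accepted(self):
        ep = self._epochs()
        ep.data[:] = np.clip(ep.data, -10, 10)
        out = reject_artifacts(ep)
        assert out.accepted.all()

    def test_eye_movement_rejected(self):
        ep = self._epochs()
        ep.data[:] = np.clip(ep.data, -20, 20)
        eye_row = ep.channel_labels.index("EOG1")
        ep.data[1, eye_row, 100] = 60.0  # above 55 uV movement threshold
        out = reject_artifacts(ep)
        assert not out.accepted[1]
        assert out.accepted.sum() == ep.n_trials - 1

    def test_data_untouched_and_flags_anded(self):
        ep = self._epochs()
        ep.accepted[0] = False
        out = reject_artifacts(ep, amp_uV=1e9, blink_uV=1e9, move_uV=1e9)
        assert not out.accepted[0]
        assert np.array_equal(out.data, ep.data)

    def test_rejection_monotone_in_thresholds(self):
        ep = self._epochs(seed=7)
        counts = []
        for amp in (40.0, 20.0, 10.0, 5.0):
            counts.append(reject_artifacts(ep, amp_uV=amp).n_accepted)
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        for move in (50.0, 10.0, 2.0):
            assert (
                reject_artifacts(ep, move_uV=move).n_accepted
                >= reject_artifacts(ep, move_uV=move / 2).n_accepted
            )


class TestRereference:
    def test_scalp_mean_is_zero(self):
        ep = segment_epochs(make_recording(), 100.0, 600.0)
        out = rereference_average(ep)
        scalp = out.scalp_mask()
        assert np.allclose(out.data[:, scalp, :].mean(axis=1), 0.0, atol=1e-9)

    def test_idempotent(self):
        ep = segment_epochs(make_recording(), 100.0, 600.0)
        once = rereference_average(ep)
        twice = rereference_average(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_two_channel_example(self):
        rec = Recording(
            np.array([[3.0] * 1000, [1.0] * 1000]),
            1000.0,
            ["A", "B"],
            events=[(400, "sound")],
        )
        ep = segment_epochs(rec, 100.0, 300.0)
        out = rereference_average(ep)
        assert np.allclose(out.data[0, 0], 1.0)
        assert np.allclose(out.data[0, 1], -1.0)

    def test_single_scalp_channel_raises(self):
        rec = make_recording(n_channels=2, eye=("EOG1",))
        ep = segment_epochs(rec, 100.0, 600.0)
        with pytest.raises(InvalidStateError):
            rereference_average(ep)


class TestRemoveBadChannels:
    def test_flat_channel_removed(self):
        rec = make_recording()
        rec.data[3, :] = 0.0
        ep = segment_epochs(rec)
        out = remove_bad_channels(ep)
        assert "CH3" not in out.channel_labels
        assert "CH3" in out.removed_channels

    def test_manual_removal(self):
        ep = segment_epochs(make_recording())
        out = remove_bad_channels(ep, manual_list=("CH1",))
        assert "CH1" not in out.channel_labels

    def test_unknown_manual_label_raises(self):
        ep = segment_epochs(make_recording())
        with pytest.raises(InvalidParameterError):
            remove_bad_channels(ep, manual_list=("NOPE",))

    def test_iid_channels_never_flagged(self):
        # 5 x median std rule should essentially never fire on homogeneous noise
        for seed in range(5):
            rng = np.random.default_rng(seed)
            rec = Recording(
                rng.standard_normal((128, 4000)) * 10,
                1000.0,
                [f"E{i}" for i in range(128)],
                events=[(1000, "sound"), (2500, "nonsound")],
            )
            out = remove_bad_channels(segment_epochs(rec))
            assert out.removed_channels == []

    def test_too_few_survivors_raises(self):
        ep = segment_epochs(make_recording(n_channels=4))
        with pytest.raises(InvalidStateError):
            remove_bad_channels(ep, manual_list=("CH0", "CH1"))


class TestAverageTrials:
    def _two_trial_epochs(self, v):
        data = np.stack([v, -v])
        return segment_epochs(
            Recording(
                np.concatenate([v, -v, np.zeros((v.shape[0], 400))], axis=1),
                1000.0,
                [f"C{i}" for i in range(v.shape[0])],
                events=[(100, "sound"), (v.shape[1] + 100, "nonsound")],
            ),
            100.0,
            v.shape[1] / 1000.0 * 1000 - 100.0,
        )

    def test_opposite_trials_cancel(self):
        v = np.full((3, 800), 7.0)
        ep = self._two_trial_epochs(v)
        wf = average_trials(ep)
        assert np.allclose(wf.data, 0.0)
        assert wf.n_trials_averaged == 2

    def test_single_trial_identity(self):
        ep = segment_epochs(make_recording(events=((2000, "sound"),)))
        wf = average_trials(ep)
        scalp = ep.scalp_mask()
        assert np.allclose(wf.data, ep.data[0, scalp, :])

    def test_zero_accepted_raises(self):
        ep = segment_epochs(make_recording())
        ep.accepted[:] = False
        with pytest.raises(EmptyEpochSetError):
            average_trials(ep)

    def test_sqrt_n_noise_reduction(self):
        rng = np.random.default_rng(11)
        n_trials, n_samp = 100, 700
        s = np.sin(2 * np.pi * 6 * np.arange(n_samp) / 1000.0)
        trials = s[None, None, :] + rng.standard_normal((n_trials, 1, n_samp))
        from roismining.preprocess import EpochSet

        ep = EpochSet(
            data=np.concatenate([trials, trials], axis=1),
            pre_ms=100.0,
            post_ms=600.0,
            rate_hz=1000.0,
            condition_tags=np.array(["sound"] * n_trials),
            accepted=np.ones(n_trials, dtype=bool),
            channel_labels=["A", "B"],
        )
        wf = average_trials(ep)
        resid_std = (wf.data[0] - s).std()
        assert resid_std == pytest.approx(1.0 / np.sqrt(n_trials), rel=0.25)

    def test_balanced_mode_weights_conditions_equally(self):
        from roismining.preprocess import EpochSet

        data = np.zeros((3, 1, 700))
        data[0] += 1.0  # sound
        data[1] += 1.0  # sound
        data[2] += 4.0  # nonsound
        ep = EpochSet(
            data=data,
            pre_ms=100.0,
            post_ms=600.0,
            rate_hz=1000.0,
            condition_tags=np.array(["sound", "sound", "nonsound"]),
            accepted=np.ones(3, dtype=bool),
            channel_labels=["A"],
        )
        assert average_trials(ep, mode="pooled").data[0, 0] == pytest.approx(2.0)
        assert average_trials(ep, mode="balanced").data[0, 0] == pytest.approx(2.5)


class TestPipeline:
    def test_matches_straightline_reference(self):
        from roismining.synthetic_data import generate_subject

        rec = generate_subject("positive", n_trials_per_condition=4, n_target_trials=1, seed=5)
        via_pipeline = preprocess_pipeline(rec)

        # straight-line re-implementation of the documented stage order
        r = bandpass_filter(rec, 0.3, 30.0)
        ep = segment_epochs(r, 100.0, 600.0)
        ep = reject_artifacts(ep, 75.0, 140.0, 55.0)
        ep = rereference_average(ep)
        ep = remove_bad_channels(ep)
        ep = rereference_average(ep)
        ref = average_trials(ep)

        assert via_pipeline.channel_labels == ref.channel_labels
        assert np.array_equal(via_pipeline.data, ref.data)

    def test_baseline_correct_zeroes_prestim_mean(self):
        ep = segment_epochs(make_recording())
        out = baseline_correct(ep)
        pre = out.data[:, :, : out.pre_samples]
        assert np.allclose(pre.mean(axis=2), 0.0, atol=1e-9)


class TestFileFormats:
    def test_text_roundtrip(self, tmp_path, tiny_recording):
        write_recording_text(tiny_recording, tmp_path / "rec")
        back = read_recording_text(tmp_path / "rec")
        assert back.channel_labels == tiny_recording.channel_labels
        assert back.events == tiny_recording.events
        assert back.rate_hz == tiny_recording.rate_hz
        assert back.eye_channel_labels == tiny_recording.eye_channel_labels
        assert np.allclose(back.data, tiny_recording.data, rtol=1e-4, atol=1e-4)

    def test_waveform_roundtrip(self, tmp_path):
        ep = segment_epochs(make_recording())
        wf = average_trials(ep)
        write_waveform_text(wf, tmp_path / "wf")
        back = read_waveform_text(tmp_path / "wf")
        assert back.channel_labels == wf.channel_labels
        assert back.n_trials_averaged == wf.n_trials_averaged
        assert np.allclose(back.data, wf.data, rtol=1e-6, atol=1e-6)

    def test_edf_roundtrip_against_mne_reader(self, tmp_path):
        rec = make_recording(n_channels=4, n_samples=2000, eye=(), events=((1000, "sound"),))
        path = tmp_path / "rec.edf"
        write_edf(rec, path)
        back = read_edf(path)
        assert back.rate_hz == rec.rate_hz
        assert back.channel_labels == rec.channel_labels
        # 16-bit quantization of a +-~20 uV range: ~1e-3 uV resolution
        assert np.allclose(back.data[:, :2000], rec.data, atol=0.01)
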