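"""Epoching, windowing, filtering and standardization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegfusion.preprocessing import (
    EpochSet,
    FilterSpec,
    apply_filters,
    eegmmidb_recipe,
    exclude_subjects,
    extract_epochs,
    standardize,
    window_epochs,
)
from eegfusion.synth import SynthConfig, generate_recording


# -- subject exclusion -------------------------------------------------------

def test_exclusion_leaves_103_of_109_subjects():
    kept = exclude_subjects(list(range(1, 110)))
    assert len(kept) == 103
    assert not {38, 82, 88, 89, 100, 104} & set(kept)
    assert kept == sorted(kept)


@pytest.mark.parametrize(
    "ids,expected",
    [([1, 2, 3], [1, 2, 3]), ([38, 88], []), ([], []), ([104, 5, 38], [5])],
)
def test_exclusion_edge_cases(ids, expected):
    assert exclude_subjects(ids) == expected


# -- epoch extraction --------------------------------------------------------

def _recording(fs=160.0, n_trials=6, trial_s=4.0, gap_s=1.0, seed=0):
    return generate_recording(
        SynthConfig(
            n_channels=4, sampling_rate_hz=fs, n_trials=n_trials,
            trial_duration_s=trial_s, inter_trial_gap_s=gap_s, seed=seed,
        )
    )


def test_epoch_width_160hz_4s_is_640():
    rec = _recording()
    es = extract_epochs(rec, ["T1", "T2"], 4.0, 0.0)
    assert es.epochs.shape[1:] == (4, 640)
    assert es.n_epochs == 6


def test_epoch_width_250hz_4p5s_offset_is_1125():
    rec = _recording(fs=250.0, trial_s=8.0)
    es = extract_epochs(rec, ["T1", "T2"], 4.5, 1.5)
    assert es.epoch_len == 1125


def test_epochs_past_record_end_are_dropped():
    rec = _recording(gap_s=0.0)
    es = extract_epochs(rec, ["T1", "T2"], 4.0, 2.0)  # last trial incomplete
    assert es.n_epochs == 5


def test_zero_duration_epoch_rejected():
    with pytest.raises(ValueError, match="positive integer"):
        extract_epochs(_recording(), ["T1"], 0.0, 0.0)


def test_no_matching_events_rejected():
    with pytest.raises(ValueError, match="no events"):
        extract_epochs(_recording(), ["T9"], 4.0, 0.0)


def test_epoch_content_matches_signal_slice():
    rec = _recording()
    es = extract_epochs(rec, ["T1", "T2"], 2.0, 1.0)
    onset = rec.events[0][0]
    np.testing.assert_array_equal(
        es.epochs[0], rec.signal[:, onset + 160 : onset + 160 + 320]
    )


# -- windowing ---------------------------------------------------------------

def test_640_samples_make_eight_80_sample_windows():
    rec = _recording(n_trials=45)
    es = extract_epochs(rec, ["T1", "T2"], 4.0, 0.0)
    wd = window_epochs(es, 80)
    assert wd.n_windows == 45 * 8
    assert wd.windows.shape[1:] == (4, 80)


def test_window_concatenation_reconstructs_epoch():
    es = extract_epochs(_recording(), ["T1", "T2"], 4.0, 0.0)
    wd = window_epochs(es, 80)
    rebuilt = np.concatenate([wd.windows[i] for i in range(8)], axis=1)
    np.testing.assert_array_equal(rebuilt, es.epochs[0])


def test_window_equal_to_epoch_is_identity():
    es = extract_epochs(_recording(), ["T1", "T2"], 4.0, 0.0)
    wd = window_epochs(es, 640)
    np.testing.assert_array_equal(wd.windows, es.epochs)
    np.testing.assert_array_equal(wd.labels, es.labels)


def test_window_longer_than_epoch_rejected():
    es = extract_epochs(_recording(), ["T1", "T2"], 4.0, 0.0)
    with pytest.raises(ValueError, match="window_len"):
        window_epochs(es, 641)


def test_windows_inherit_epoch_labels():
    es = extract_epochs(_recording(), ["T1", "T2"], 4.0, 0.0)
    wd = window_epochs(es, 80)
    np.testing.assert_array_equal(wd.labels, np.repeat(es.labels, 8))


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    n_epochs=st.integers(1, 8),
    w_epoch=st.integers(4, 64),
    data=st.randoms(use_true_random=False),
)
def test_window_provenance_is_a_bijection(n_epochs, w_epoch, data):
    rng = np.random.default_rng(data.randint(0, 2**31))
    window_len = rng.integers(1, w_epoch + 1)
    es = EpochSet(
        rng.standard_normal((n_epochs, 3, w_epoch)),
        rng.integers(0, 2, n_epochs),
        ["a", "b"],
        100.0,
    )
    wd = window_epochs(es, int(window_len))
    pairs = {tuple(p) for p in wd.provenance}
    n_win = w_epoch // int(window_len)
    assert len(pairs) == wd.n_windows == n_epochs * n_win
    assert pairs == {(e, w) for e in range(n_epochs) for w in range(n_win)}


# -- filtering ---------------------------------------------------------------

def _tone(freq, fs=160.0, seconds=8.0):
    t = np.arange(int(fs * seconds)) / fs
    return np.sin(2 * np.pi * freq * t)[None, :]


def test_notch_suppresses_60hz_tone_by_26db():
    x = _tone(60.0)
    spec = FilterSpec(notch_freq_hz=60.0, notch_q=30.0,
                      bandpass_low_hz=2.0, bandpass_high_hz=70.0)
    y = apply_filters(x, spec, sampling_rate_hz=160.0)
    core = slice(160, -160)  # ignore filtfilt edge transients
    ratio = np.sqrt(np.mean(y[0, core] ** 2) / np.mean(x[0, core] ** 2))
    assert ratio < 0.05  # > 26 dB suppression


def test_passband_tone_amplitude_preserved():
    x = _tone(30.0)
    y = apply_filters(x, FilterSpec(), sampling_rate_hz=160.0)
    core = slice(160, -160)
    ratio = np.sqrt(np.mean(y[0, core] ** 2) / np.mean(x[0, core] ** 2))
    assert abs(ratio - 1.0) < 0.05


def test_dc_removed_by_bandpass():
    x = np.full((1, 1280), 7.5)
    y = apply_filters(x, FilterSpec(notch_freq_hz=None), sampling_rate_hz=160.0)
    assert np.abs(y).max() < 1e-6 * 7.5


def test_bandpass_high_at_nyquist_rejected():
    with pytest.raises(ValueError, match="Nyquist"):
        apply_filters(np.zeros((1, 100)), FilterSpec(bandpass_high_hz=80.0),
                      sampling_rate_hz=160.0)


def test_filter_output_shape_and_recording_passthrough():
    rec = _recording()
    out = apply_filters(rec, FilterSpec())
    assert out.signal.shape == rec.signal.shape
    assert out.events == rec.events
    assert out.channel_names == rec.channel_names


@settings(derandomize=True, max_examples=20, deadline=None)
@given(
    a=st.floats(-3, 3, allow_nan=False),
    b=st.floats(-3, 3, allow_nan=False),
    seed=st.integers(0, 2**16),
)
def test_filtering_is_linear(a, b, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((2, 800))
    y = rng.standard_normal((2, 800))
    spec = FilterSpec()
    lhs = apply_filters(a * x + b * y, spec, sampling_rate_hz=160.0)
    rhs = a * apply_filters(x, spec, sampling_rate_hz=160.0) + b * apply_filters(
        y, spec, sampling_rate_hz=160.0
    )
    np.testing.assert_allclose(lhs, rhs, rtol=1e-8, atol=1e-9)


# -- standardization ---------------------------------------------------------

def test_train_set_standardized_to_zero_mean_unit_sd():
    rng = np.random.default_rng(0)
    train = rng.standard_normal((20, 3, 40)) * 5 + 2
    (z_train,), mean, sd = standardize(train)
    assert np.allclose(z_train.mean(axis=(0, 2)), 0, atol=1e-6)
    assert np.allclose(z_train.std(axis=(0, 2)), 1, atol=1e-6)
    assert mean.shape == sd.shape == (3,)


def test_other_partitions_use_train_statistics():
    rng = np.random.default_rng(1)
    train = rng.standard_normal((20, 2, 16)) * 3 + 1
    test = rng.standard_normal((8, 2, 16)) * 3 + 1
    (z_train, z_test), mean, sd = standardize(train, test)
    np.testing.assert_allclose(
        z_test, (test - mean[None, :, None]) / sd[None, :, None]
    )
    # test-set moments need not be exactly 0/1
    assert not np.allclose(z_test.mean(axis=(0, 2)), 0, atol=1e-8)


def test_constant_channel_rejected_by_name():
    train = np.random.default_rng(2).standard_normal((5, 3, 10))
    train[:, 1, :] = 4.2
    with pytest.raises(ValueError, match=r"\[1\]"):
        standardize(train)


def test_standardization_not_idempotent_unless_unit_stats():
    rng = np.random.default_rng(3)
    train = rng.standard_normal((10, 2, 20)) * 2 + 5
    (z1,), mean, sd = standardize(train)
    z2 = (z1 - mean[None, :, None]) / sd[None, :, None]
    assert not np.allclose(z1, z2)


# -- full recipe -------------------------------------------------------------

def test_eegmmidb_recipe_window_count_per_subject():
    rec = _recording(n_trials=45)
    wd = eegmmidb_recipe(rec)
    assert wd.n_windows == 360
    assert wd.windows.shape[1:] == (4, 80)
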