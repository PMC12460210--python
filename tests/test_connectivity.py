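"""Filtering, windowing and ciPLV estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h
from scipy import signal as sps

from netlearn import (
    BANDS,
    CHANNELS_16,
    ConnectivityMatrix,
    EEGRecording,
    average_matrices,
    average_sessions,
    ciplv,
    connectivity_to_frame,
    frame_to_matrices,
    plv,
    pool_windows,
    preprocess,
    read_eeg_csv,
    sliding_windows,
    write_eeg_csv,
)
from netlearn.connectivity import window_count

from conftest import sinusoid_recording


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _cascade_gain(freq, fs=512.0):
    """Oracle: |H(f)| of the designed band-pass+notch cascade, squared
    for the forward-backward application."""
    sos_bp = sps.butter(4, [0.5, 100.0], btype="bandpass", fs=fs, output="sos")
    sos_notch = sps.butter(2, [48.0, 52.0], btype="bandstop", fs=fs, output="sos")
    w = 2 * np.pi * np.asarray(freq) / fs
    _, h1 = sps.sosfreqz(sos_bp, worN=w)
    _, h2 = sps.sosfreqz(sos_notch, worN=w)
    return (np.abs(h1) * np.abs(h2)) ** 2  # filtfilt doubles the order


@pytest.mark.parametrize(
    "freq, expect",
    [(50.0, "notched"), (10.0, "passed")],
)
def test_preprocess_sinusoid_amplitudes(freq, expect):
    fs, dur = 512.0, 20.0
    t = np.arange(int(fs * dur)) / fs
    rec = EEGRecording(
        data=np.sin(2 * np.pi * freq * t)[None, :], fs=fs,
        channel_labels=("ch0",),
    )
    out = preprocess(rec)
    # the narrow notch rings for seconds: compare away from the edges
    sl = slice(int(4 * fs), -int(4 * fs))
    ratio = np.sqrt(
        (out.data[0, sl] ** 2).mean() / (rec.data[0, sl] ** 2).mean()
    )
    oracle = float(_cascade_gain([freq])[0])
    assert ratio == pytest.approx(oracle, abs=0.02)
    if expect == "notched":
        assert ratio < 0.05
    else:
        assert abs(ratio - 1.0) < 0.05


def test_preprocess_removes_dc():
    fs = 512.0
    rec = EEGRecording(
        data=np.full((1, int(fs * 6)), 7.5), fs=fs, channel_labels=("ch0",)
    )
    out = preprocess(rec)
    assert np.abs(out.data).max() < 0.5


def test_preprocess_rejects_low_fs():
    rec = EEGRecording(
        data=np.zeros((1, 1000)), fs=150.0, channel_labels=("ch0",)
    )
    with pytest.raises(ValueError, match="too low"):
        preprocess(rec)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "duration, expected",
    [(60.0, 29), (4.0, 1), (240.0, 119)],
)
def test_window_counts(duration, expected):
    rec = sinusoid_recording([(10.0, 0.0)], duration=duration)
    ws = sliding_windows(rec, 4.0, 2.0)
    assert ws.n_windows == expected
    assert ws.windows.shape == (expected, 1, 2048)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    n=st_h.integers(min_value=1, max_value=5000),
    w=st_h.integers(min_value=1, max_value=500),
    s=st_h.integers(min_value=1, max_value=200),
)
def test_window_count_matches_offset_enumeration(n, w, s):
    brute = sum(1 for off in range(0, n + 1, s) if off + w <= n)
    assert window_count(n, w, s) == brute


def test_windowing_rejects_short_recording_and_bad_params():
    rec = sinusoid_recording([(10.0, 0.0)], duration=2.0)
    with pytest.raises(ValueError, match="shorter"):
        sliding_windows(rec, 4.0, 2.0)
    rec2 = sinusoid_recording([(10.0, 0.0)], duration=10.0)
    with pytest.raises(ValueError, match="stride"):
        sliding_windows(rec2, 4.0, 0.0)
    with pytest.raises(ValueError, match="window_length"):
        sliding_windows(rec2, -1.0, 2.0)


def test_pool_windows_concatenates_provenance():
    r1 = sinusoid_recording([(10.0, 0.0)], duration=10.0)
    r2 = EEGRecording(
        data=r1.data, fs=r1.fs, channel_labels=r1.channel_labels, trial=1
    )
    pooled = pool_windows([sliding_windows(r1), sliding_windows(r2)])
    assert pooled.n_windows == 8
    assert {p[2] for p in pooled.provenance} == {0, 1}


# ---------------------------------------------------------------------------
# ciPLV / PLV
# ---------------------------------------------------------------------------

def test_ciplv_zero_lag_identical_signals_is_zero(zero_lag_windows):
    m = ciplv(zero_lag_windows, "alpha")
    assert abs(m.values[0, 1]) < 1e-6


def test_ciplv_quarter_cycle_lag_is_one(quarter_cycle_windows):
    m = ciplv(quarter_cycle_windows, (9.9, 10.1))
    assert abs(m.values[0, 1] - 1.0) < 1e-6


def test_plv_zero_lag_is_one(zero_lag_windows):
    m = plv(zero_lag_windows, "alpha")
    assert m.values[0, 1] > 0.999


def test_ciplv_white_noise_below_mismatch_null(rng):
    """Independent channels: the observed ciPLV should not exceed the
    95th percentile of a window-pairing-mismatch null."""
    n_win, nsamp, fs = 100, 1024, 256.0
    wins = rng.standard_normal((n_win, 2, nsamp))

    def build(w):
        from netlearn import WindowSet
        return WindowSet(
            windows=w, fs=fs, window_length=nsamp / fs, stride=nsamp / fs,
            channel_labels=("a", "b"),
            provenance=tuple(("s01", "pre", 0) for _ in range(n_win)),
        )

    obs = ciplv(build(wins), "alpha").values[0, 1]
    nulls = []
    for shift in range(1, 21):
        w = wins.copy()
        w[:, 1, :] = np.roll(w[:, 1, :], shift, axis=0)
        nulls.append(ciplv(build(w), "alpha").values[0, 1])
    assert obs <= np.percentile(nulls, 95)


@pytest.mark.parametrize("band", ["theta", "alpha", "beta", "gamma"])
def test_ciplv_symmetry_range_diagonal(band, rng):
    rec = EEGRecording(
        data=rng.standard_normal((6, int(512 * 12))), fs=512.0,
        channel_labels=tuple(f"ch{i}" for i in range(6)),
    )
    m = ciplv(sliding_windows(rec), band)
    assert np.allclose(m.values, m.values.T)
    assert np.all(np.diag(m.values) == 0)
    assert m.values.min() >= 0 and m.values.max() <= 1


def test_ciplv_amplitude_invariance(rng):
    data = rng.standard_normal((3, int(512 * 12)))
    rec = EEGRecording(
        data=data, fs=512.0, channel_labels=("a", "b", "c")
    )
    scaled = EEGRecording(
        data=data * np.array([7.3, 0.01, 1.0])[:, None], fs=512.0,
        channel_labels=("a", "b", "c"),
    )
    m1 = ciplv(sliding_windows(rec), "beta")
    m2 = ciplv(sliding_windows(scaled), "beta")
    assert np.allclose(m1.values, m2.values, atol=1e-10)


def test_ciplv_band_validation(zero_lag_windows):
    with pytest.raises(ValueError, match="unknown band"):
        ciplv(zero_lag_windows, "delta")
    with pytest.raises(ValueError, match="Nyquist"):
        ciplv(zero_lag_windows, (100.0, 300.0))
    one = zero_lag_windows.windows[:1]
    from netlearn import WindowSet
    ws1 = WindowSet(
        windows=one, fs=512.0, window_length=4.0, stride=2.0,
        channel_labels=("a", "b"), provenance=(("s01", "pre", 0),),
    )
    with pytest.raises(ValueError, match="2 windows"):
        ciplv(ws1, "alpha")


# ---------------------------------------------------------------------------
# Aggregation and I/O
# ---------------------------------------------------------------------------

def _matrix(vals, band="alpha", subject="s01", session="pre"):
    return ConnectivityMatrix(
        values=vals, band=band, subject=subject, session=session,
        n_windows=10, channel_labels=("a", "b", "c"),
    )


def test_average_matrices_trivials():
    v = np.array([[0, 1, 0.0], [1, 0, 0], [0, 0, 0]])
    w = np.array([[0, 0, 0.0], [0, 0, 0], [0, 0, 0]])
    assert np.allclose(average_matrices([_matrix(v)]).values, v)
    assert np.allclose(average_matrices([_matrix(v), _matrix(v)]).values, v)
    avg = average_matrices([_matrix(v), _matrix(w)])
    assert avg.values[0, 1] == 0.5


def test_average_matrices_rejects_mixed_bands():
    v = np.zeros((3, 3))
    with pytest.raises(ValueError, match="mixed bands"):
        average_matrices([_matrix(v, band="alpha"), _matrix(v, band="beta")])


def test_average_sessions_groups_by_identity():
    v = np.zeros((3, 3))
    mats = [
        _matrix(v, session="pre"),
        _matrix(v, session="pre"),
        _matrix(v, session="post"),
    ]
    out = average_sessions(mats)
    assert {(m.session, m.n_windows) for m in out} == {("pre", 20), ("post", 10)}


def test_eeg_csv_roundtrip(tmp_path, rng):
    rec = EEGRecording(
        data=rng.standard_normal((16, 256)), fs=512.0,
        subject="s07", session="post", trial=3,
    )
    write_eeg_csv(rec, tmp_path / "trial")
    back = read_eeg_csv(tmp_path / "trial")
    assert back.subject == "s07" and back.session == "post" and back.trial == 3
    assert back.channel_labels == CHANNELS_16
    assert np.allclose(back.data, rec.data, atol=1e-9)


def test_connectivity_frame_roundtrip(rng):
    v = np.zeros((16, 16))
    iu, ju = np.triu_indices(16, k=1)
    vals = rng.uniform(0, 1, iu.shape[0])
    v[iu, ju] = vals
    v[ju, iu] = vals
    m = ConnectivityMatrix(values=v, band="beta", subject="s02",
                           session="post", n_windows=29)
    frame = connectivity_to_frame([m])
    assert len(frame) == 120  # 16 electrodes -> 120 unique connections
    back = frame_to_matrices(frame)[0]
    assert np.allclose(back.values, m.values)
    assert (back.subject, back.session, back.band) == ("s02", "post", "beta")
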