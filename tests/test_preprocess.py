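"""Preprocessing: filtering, bad channels, ocular artifacts, rejection,
referencing and averaging."""

import numpy as np
import pytest
from scipy import signal

from rhythmtag import config as cfg
from rhythmtag import preprocess as pp
from rhythmtag.containers import RawRecording
from rhythmtag.eegsim import SimConfig, blink_topography, simulate_participant


def make_record(data, fs=1000, events=None, ch_names=None):
    data = np.atleast_2d(np.asarray(data, float))
    return RawRecording(
        data=data, fs_hz=fs,
        ch_names=ch_names or cfg.channel_names(data.shape[0]),
        events=events or [(0, "seq_onset")],
        participant="p0", condition="c0")


def make_epochs(data, **kw):
    data = np.asarray(data, float)
    kw.setdefault("ch_names", cfg.channel_names(data.shape[1]))
    return pp.EpochedEEG(data=data, fs_hz=1000, participant="p0",
                         condition="c0", **kw)


# ---------------------------------------------------------------------------
# Band-pass filter
# ---------------------------------------------------------------------------

class TestBandpass:
    def response_at(self, f_hz):
        taps = pp._fir_taps(1000, 0.3, 30.0)
        _, h = signal.freqz(taps, worN=[f_hz], fs=1000)
        return np.abs(h[0])

    def test_passband_is_flat_to_one_percent(self):
        for f in (0.5, 1, 2.5, 5, 10, 20, 30):
            assert self.response_at(f) == pytest.approx(1.0, abs=0.01)

    def test_stopbands_are_40db_down(self):
        assert self.response_at(0.05) <= 0.01
        assert self.response_at(50.0) <= 0.01

    def test_passband_sinusoid_survives_in_time_domain(self):
        t = np.arange(60000) / 1000.0
        rec = make_record(np.sin(2 * np.pi * 5 * t))
        out = pp.bandpass(rec).data[0, 20000:40000]
        assert np.max(np.abs(out)) == pytest.approx(1.0, abs=0.01)

    def test_mains_frequency_sinusoid_is_removed(self):
        t = np.arange(60000) / 1000.0
        rec = make_record(np.sin(2 * np.pi * 50 * t))
        out = pp.bandpass(rec).data[0, 20000:40000]
        assert np.max(np.abs(out)) <= 0.01

    def test_dc_offset_is_rejected(self):
        rec = make_record(np.full(60000, 10.0))
        out = pp.bandpass(rec).data[0, 20000:40000]
        assert np.abs(out).max() < 0.05

    def test_cutoff_above_nyquist_rejected(self):
        rec = make_record(np.zeros(2000))
        with pytest.raises(ValueError, match="Nyquist"):
            pp.bandpass(rec, 0.3, 600.0)


# ---------------------------------------------------------------------------
# Bad channels
# ---------------------------------------------------------------------------

def test_clean_simulation_interpolates_nothing():
    sim = SimConfig(n_epochs=2, blink_rate=0.0, bad_channel_prob=0.0,
                    conditions=("english",))
    recs, _ = simulate_participant(sim, "english", 11, "en00")
    epochs = pp.epoch_record(recs["english"])
    assert pp.detect_bad_channels(epochs) == []


def test_high_variance_channel_is_the_one_detected():
    rng = np.random.default_rng(0)
    data = rng.standard_normal((2, 128, 3000)) * 10
    data[:, 37, :] = rng.standard_normal((2, 3000)) * 100   # 10x SD
    epochs = make_epochs(data)
    assert pp.detect_bad_channels(epochs) == ["E38"]


def test_too_many_bad_channels_flags_participant():
    rng = np.random.default_rng(1)
    data = rng.standard_normal((2, 128, 3000)) * 10
    data[:, :13, :] *= 30
    epochs = make_epochs(data)
    with pytest.raises(pp.ExclusionError, match="bad channels"):
        pp.detect_bad_channels(epochs)


def test_interpolation_is_inverse_distance_weighted_average():
    # 1 bad channel at the origin, 4 good ones at known distances
    positions = np.array([[0.0, 0, 0], [0.01, 0, 0], [0, 0.02, 0],
                          [0, 0, 0.02], [0.04, 0, 0]])
    data = np.zeros((1, 5, 10))
    vals = np.array([0.0, 4.0, 8.0, 12.0, 16.0])
    data[0] = vals[:, None]
    epochs = make_epochs(data, ch_names=["b", "g1", "g2", "g3", "g4"])
    out = pp.interpolate_channels(epochs, ["b"], positions=positions,
                                  n_neighbors=4)
    inv_d2 = 1.0 / np.array([0.01, 0.02, 0.02, 0.04]) ** 2
    expected = np.sum(inv_d2 * vals[1:]) / inv_d2.sum()
    assert np.allclose(out.data[0, 0], expected)
    assert out.interpolated == ["b"]


# ---------------------------------------------------------------------------
# Ocular artifacts
# ---------------------------------------------------------------------------

def blinky_epochs(n_epochs=4, blink_amp=150.0, seed=0):
    """Low noise + rank-1 blinks at known positions in every epoch."""
    rng = np.random.default_rng(seed)
    ch = cfg.channel_names(128)
    topo = blink_topography(ch)
    data = rng.standard_normal((n_epochs, 128, 30000)) * 5.0
    starts = []
    for e in range(n_epochs):
        t0 = 2000 + 3300 * e
        dur = 800
        data[e] += np.outer(blink_amp * topo,
                            np.pad(np.hanning(dur),
                                   (t0, 30000 - t0 - dur)))
        starts.append((t0, dur))
    return make_epochs(data), starts, topo


def test_strategy_none_is_identity():
    epochs, _, _ = blinky_epochs()
    out = pp.remove_ocular_artifacts(epochs, strategy="none")
    assert out.data is epochs.data


def test_blink_free_input_is_untouched_by_regression():
    rng = np.random.default_rng(3)
    data = rng.standard_normal((2, 128, 30000)) * 5.0
    epochs = make_epochs(data)
    out = pp.remove_ocular_artifacts(epochs, strategy="regression")
    assert np.max(np.abs(out.data - data)) < 1.0


def test_regression_brings_blinks_below_rejection_threshold():
    epochs, starts, topo = blinky_epochs(n_epochs=8, blink_amp=150.0)
    out = pp.remove_ocular_artifacts(epochs, strategy="regression")
    frontal = [list(epochs.ch_names).index(c) for c in cfg.FRONTAL_PROXIES]
    ok = 0
    for e, (t0, dur) in enumerate(starts):
        peak = np.abs(out.data[e][frontal][:, t0:t0 + dur]).max()
        ok += peak < 100.0
    assert ok >= 0.9 * len(starts)


# ---------------------------------------------------------------------------
# Rejection / referencing / averaging
# ---------------------------------------------------------------------------

def test_clean_epochs_all_accepted():
    data = np.random.default_rng(0).standard_normal((8, 4, 100)) * 10
    out = pp.reject_epochs(make_epochs(data))
    assert out.accept.sum() == 8


def test_sample_at_exactly_threshold_is_accepted():
    data = np.zeros((1, 4, 100))
    data[0, 2, 50] = 100.0                  # boundary: strictly "exceeding"
    out = pp.reject_epochs(make_epochs(data))
    assert out.accept[0]
    data[0, 2, 50] = 100.01
    assert not pp.reject_epochs(make_epochs(data)).accept[0]


def test_interpolated_channels_do_not_drive_rejection():
    data = np.zeros((1, 4, 100))
    data[0, 1, 10] = 500.0
    epochs = make_epochs(data, interpolated=["E2"])
    assert pp.reject_epochs(epochs).accept[0]


def test_five_good_epochs_exclude_the_dataset():
    data = np.zeros((8, 4, 100))
    data[:3, 0, 0] = 200.0                  # 3 contaminated -> 5 accepted
    epochs = pp.reject_epochs(make_epochs(data))
    assert epochs.accept.sum() == 5
    with pytest.raises(pp.ExclusionError, match="5 accepted"):
        pp.rereference_and_average(epochs)


def test_average_reference_zeroes_the_channel_sum():
    rng = np.random.default_rng(5)
    epochs = make_epochs(rng.standard_normal((8, 16, 500)) * 20)
    ev = pp.rereference_and_average(epochs)
    sums = ev.data.sum(axis=0)
    assert np.max(np.abs(sums)) < 1e-9 * 16


def test_average_of_identical_epochs_is_the_epoch():
    rng = np.random.default_rng(6)
    one = rng.standard_normal((16, 500))
    one -= one.mean(axis=0, keepdims=True)   # already average-referenced
    epochs = make_epochs(np.repeat(one[None], 8, axis=0))
    ev = pp.rereference_and_average(epochs)
    assert np.allclose(ev.data, one, atol=1e-12)
    assert ev.n_epochs_averaged == 8


def test_averaging_shrinks_noise_like_sqrt_n():
    """Monte-Carlo: RMS of an 8-epoch average of white noise ~ single-epoch
    RMS / sqrt(8), within 20%."""
    rng = np.random.default_rng(7)
    ratios = []
    for _ in range(100):
        data = rng.standard_normal((8, 4, 400))
        data -= data.mean(axis=1, keepdims=True)
        avg = data.mean(axis=0)
        ratios.append(np.sqrt(np.mean(avg ** 2))
                      / np.sqrt(np.mean(data[0] ** 2)))
    assert np.mean(ratios) == pytest.approx(1 / np.sqrt(8), rel=0.20)


def test_averaging_preserves_embedded_response_amplitude():
    """The coherent 5 Hz component survives averaging (+/-2%) while the
    incoherent noise floor drops."""
    rng = np.random.default_rng(8)
    t = np.arange(30000) / 1000.0
    a = 2.0
    sig = a * np.cos(2 * np.pi * 5 * t)
    epochs = sig[None, None, :] + rng.standard_normal((8, 1, 30000)) * 5.0
    avg = epochs.mean(axis=0)[0]
    # coherent amplitude estimate: projection onto the cos/sin pair
    c = 2 * np.mean(avg * np.cos(2 * np.pi * 5 * t))
    s = 2 * np.mean(avg * np.sin(2 * np.pi * 5 * t))
    assert np.hypot(c, s) == pytest.approx(a, rel=0.02)
    # noise floor (off-signal projection) shrinks by ~sqrt(8)
    c7 = 2 * np.mean(epochs[0, 0] * np.cos(2 * np.pi * 7.2 * t))
    assert abs(c7) > 0  # single-epoch floor exists; averaging comparison:
    floors_single = [2 * np.mean(epochs[i, 0] * np.cos(2 * np.pi * 7.2 * t))
                     for i in range(8)]
    assert abs(np.mean(floors_single)) <= np.std(floors_single)


# ---------------------------------------------------------------------------
# Pipeline order
# ---------------------------------------------------------------------------

def test_pipeline_stage_order_is_fixed():
    sim = SimConfig(n_epochs=8, conditions=("english",), blink_rate=0.2)
    recs, _ = simulate_participant(sim, "english", 21, "en00")
    ev, log = pp.preprocess_recording(recs["english"])
    assert tuple(log["stages"]) == pp.PIPELINE_ORDER == (
        "bandpass", "epoch", "detect_bad_channels", "ocular",
        "interpolate", "reject", "rereference", "average")
    assert ev.reference == "average"
    assert ev.n_epochs_averaged >= 6
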