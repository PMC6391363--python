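"""Preprocessing stages: filter, reference, resample, segment, reject, baseline."""

import numpy as np
import pandas as pd
import pytest

from primeconflict.containers import Epochs, PipelineOrderError, Recording
from primeconflict.preprocess import (bandpass_filter, baseline_correct,
                                      reject_artifacts, rereference_average,
                                      resample, segment)
from primeconflict.protocol import RejectionCriteria


def make_recording(data, sfreq=500.0, history=(), events=None):
    data = np.atleast_2d(data)
    if events is None:
        events = pd.DataFrame(columns=["trial", "kind", "sample"])
    return Recording(data, sfreq, tuple(f"ch{i}" for i in range(data.shape[0])),
                     events, history=history)


def make_epochs(data, sfreq=256.0, trials=None, history=("bandpass", "average_reference",
                                                         "resample", "segment")):
    data = np.asarray(data, dtype=float)
    n_t = data.shape[2]
    times = (np.arange(n_t) - n_t // 2) / sfreq * 1000.0
    if trials is None:
        trials = pd.DataFrame({"trial": np.arange(data.shape[0]), "correct": True})
    return Epochs(data, times, sfreq, tuple(f"ch{i}" for i in range(data.shape[1])),
                  trials, history=history)


# ---------------------------------------------------------------------------
# band-pass filter

def test_filter_removes_dc():
    rec = make_recording(np.full((2, 5000), 10.0))
    out = bandpass_filter(rec)
    core = out.data[:, 1000:-1000]
    assert np.abs(core).max() < 0.1  # <1% of the input after edge trimming


def test_filter_passband_gain_at_10hz():
    t = np.arange(20000) / 500.0
    rec = make_recording(np.sin(2 * np.pi * 10 * t))
    out = bandpass_filter(rec)
    amp = np.abs(out.data[0, 5000:-5000]).max()
    assert 0.89 <= amp <= 1.12


def test_filter_stopband_attenuation_at_40hz():
    # one octave above the 20 Hz edge: at least 48 dB down
    t = np.arange(20000) / 500.0
    rec = make_recording(np.sin(2 * np.pi * 40 * t))
    out = bandpass_filter(rec)
    amp = np.abs(out.data[0, 5000:-5000]).max()
    assert 20 * np.log10(amp) <= -48.0


def test_filter_rejects_bad_cutoffs():
    rec = make_recording(np.zeros((1, 100)))
    with pytest.raises(ValueError):
        bandpass_filter(rec, lo=20.0, hi=5.0)
    with pytest.raises(ValueError):
        bandpass_filter(rec, lo=0.5, hi=300.0)


# ---------------------------------------------------------------------------
# average reference

def test_rereference_zero_mean_and_idempotent(rng):
    rec = make_recording(rng.normal(size=(6, 400)), history=("bandpass",))
    out = rereference_average(rec)
    assert np.abs(out.data.mean(axis=0)).max() < 1e-9
    again = out.data - out.data.mean(axis=0, keepdims=True)
    np.testing.assert_allclose(out.data, again, atol=1e-12)


def test_rereference_antisymmetric_pair_unchanged():
    rec = make_recording(np.vstack([np.full(50, 5.0), np.full(50, -5.0)]),
                         history=("bandpass",))
    np.testing.assert_allclose(rereference_average(rec).data, rec.data)


def test_rereference_identical_channels_zeroed():
    rec = make_recording(np.full((4, 50), 7.3), history=("bandpass",))
    assert np.abs(rereference_average(rec).data).max() == 0.0


def test_rereference_needs_two_channels():
    with pytest.raises(ValueError):
        rereference_average(make_recording(np.zeros((1, 10)), history=("bandpass",)))


# ---------------------------------------------------------------------------
# resampling

def _pre_resample(data, events=None):
    return make_recording(data, history=("bandpass", "average_reference"), events=events)


def test_resample_sample_count_and_event_retiming():
    ev = pd.DataFrame({"trial": [0], "kind": ["target"], "sample": [500]})
    rec = _pre_resample(np.zeros((1, 500)), events=ev)
    out = resample(rec)
    assert out.data.shape[1] == 256
    assert out.sfreq == 256.0
    assert out.events["sample"].iloc[0] == 256


def test_resample_preserves_band_limited_sine():
    t = np.arange(2500) / 500.0
    rec = _pre_resample(np.sin(2 * np.pi * 5 * t))
    out = resample(rec)
    t_new = np.arange(out.data.shape[1]) / 256.0
    ref = np.sin(2 * np.pi * 5 * t_new)
    core = slice(100, -100)
    r = np.corrcoef(out.data[0, core], ref[core])[0, 1]
    assert r > 0.999


def test_resample_rejects_upsampling():
    with pytest.raises(ValueError):
        resample(_pre_resample(np.zeros((1, 100)), events=None), target_hz=256.0) \
            if False else resample(make_recording(np.zeros((1, 100)), sfreq=128.0,
                                                  history=("bandpass", "average_reference")))


# ---------------------------------------------------------------------------
# segmentation

def _segment_ready(data, events):
    return make_recording(data, sfreq=256.0,
                          history=("bandpass", "average_reference", "resample"),
                          events=events)


def test_segment_counts_alignment_and_edge_drop():
    n = 256 * 12
    data = np.zeros((2, n))
    step_at = 256 * 6
    data[:, step_at:] = 1.0           # step exactly at one target onset
    events = pd.DataFrame({"trial": [0, 1, 2],
                           "kind": ["target"] * 3,
                           "sample": [step_at, 256 * 9, 100]})  # trial 2 near edge
    trials = pd.DataFrame({"trial": [0, 1, 2], "correct": [True, True, True]})
    ep = segment(_segment_ready(data, events), trials)
    assert ep.n_epochs == 2              # edge trial dropped and logged
    assert (ep.rejection_log["rule"] == "edge").sum() == 1
    i0 = np.searchsorted(ep.times_ms, 0.0)
    assert ep.data[0, 0, i0] == 1.0 and ep.data[0, 0, i0 - 1] == 0.0


def test_segment_keeps_only_correct_trials():
    n = 256 * 20
    events = pd.DataFrame({"trial": range(4), "kind": ["target"] * 4,
                           "sample": [256 * 4, 256 * 8, 256 * 12, 256 * 16]})
    trials = pd.DataFrame({"trial": range(4), "correct": [True, False, True, False]})
    ep = segment(_segment_ready(np.zeros((1, n)), events), trials)
    assert ep.n_epochs == 2
    assert list(ep.trials["trial"]) == [0, 2]


# ---------------------------------------------------------------------------
# artifact rejection

def brute_force_reject(x, sfreq, crit):
    """Independent sliding-window oracle: plain python loops."""
    w_max = max(2, int(np.floor(crit.max_diff_window_ms / 1000 * sfreq + 0.5)))
    w_min = max(2, int(np.floor(crit.min_diff_window_ms / 1000 * sfreq + 0.5)))
    for ch in range(x.shape[0]):
        if np.any(np.abs(x[ch]) > crit.absolute_uv):
            return True
        for s in range(x.shape[1] - w_max + 1):
            win = x[ch, s:s + w_max]
            if win.max() - win.min() > crit.max_diff_uv:
                return True
        for s in range(x.shape[1] - w_min + 1):
            win = x[ch, s:s + w_min]
            if win.max() - win.min() < crit.min_diff_uv:
                return True
    return False


def test_reject_spike_absolute_bound(rng):
    data = rng.normal(0, 5, size=(2, 3, 300))
    data[0, 1, 150] = 150.0
    ep = make_epochs(data)
    out = reject_artifacts(ep)
    assert out.n_epochs == 1
    row = out.rejection_log.iloc[0]
    assert row["rule"] == "absolute" and row["channel"] == "ch1"


def test_reject_flatline(rng):
    data = rng.normal(0, 5, size=(2, 2, 300))
    data[1, 0, :] = 0.01 * np.sin(np.arange(300) / 300)   # sub-threshold activity
    out = reject_artifacts(make_epochs(data))
    assert out.n_epochs == 1
    assert (out.rejection_log["rule"] == "min_diff").any()


def test_slow_large_swing_retained():
    # 150 uV swing spread over 400 ms: within +-100 uV and <=200 uV per 200 ms
    n = 512
    t = np.arange(n) / 256.0
    sweep = 75.0 * np.sin(2 * np.pi * t / (2 * 0.4))      # 150 uV p-p over 400 ms
    base = 10.0 * np.sin(2 * np.pi * 7 * t)
    data = (sweep + base)[None, None, :]
    out = reject_artifacts(make_epochs(data))
    assert out.n_epochs == 1


def test_rejection_matches_brute_force_oracle(rng):
    crit = RejectionCriteria()
    n_match = 0
    for i in range(100):
        kind = i % 4
        x = rng.normal(0, 30 if kind == 0 else 10, size=(2, 200))
        if kind == 1:
            x[0, 90:95] += 180.0                     # fast transient
        elif kind == 2:
            x[1] = rng.normal(0, 0.05, size=200)     # near-flat channel
        elif kind == 3:
            x += np.linspace(0, 90, 200)             # slow drift
        ep = make_epochs(x[None, :, :])
        fast = reject_artifacts(ep).n_epochs == 0
        slow = brute_force_reject(x, 256.0, crit)
        assert fast == slow
        n_match += 1
    assert n_match == 100


# ---------------------------------------------------------------------------
# baseline and stage ordering

def _csd_done(data):
    return make_epochs(data, history=("bandpass", "average_reference", "resample",
                                      "segment", "reject", "csd"))


def test_baseline_zero_mean_constant_and_idempotent(rng):
    data = rng.normal(size=(3, 2, 1025)) + 5.0
    ep = _csd_done(data)
    out = baseline_correct(ep)
    sl = out.window_slice((-500.0, -200.0))
    assert np.abs(out.data[:, :, sl].mean(axis=2)).max() < 1e-9
    const = _csd_done(np.full((1, 2, 1025), 4.2))
    assert np.abs(baseline_correct(const).data).max() < 1e-12
    # idempotence (modulo the stage guard)
    again = out.data - out.data[:, :, sl].mean(axis=2, keepdims=True)
    np.testing.assert_allclose(out.data, again, atol=1e-12)


def test_baseline_window_must_lie_inside_epoch():
    ep = _csd_done(np.zeros((1, 2, 100)))
    with pytest.raises(ValueError):
        baseline_correct(ep, window_ms=(-5000.0, -4000.0))


def test_pipeline_order_enforced(rng):
    rec = make_recording(rng.normal(size=(3, 1000)))
    with pytest.raises(PipelineOrderError):
        rereference_average(rec)             # filter not yet run
    with pytest.raises(PipelineOrderError):
        resample(rec)
    filtered = bandpass_filter(rec)
    with pytest.raises(PipelineOrderError):
        bandpass_filter(filtered)            # double application
    ep = make_epochs(rng.normal(size=(1, 3, 500)))
    with pytest.raises(PipelineOrderError):
        baseline_correct(ep)                 # reject + csd missing
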