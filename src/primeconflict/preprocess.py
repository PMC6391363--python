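"""Preprocessing protocol: continuous recording -> clean CSD epochs.

Stage order is fixed and enforced by the containers:

    bandpass_filter -> rereference_average -> resample -> segment
    -> reject_artifacts -> csd_transform -> baseline_correct

All thresholds and windows come from :class:`~primeconflict.protocol.ProtocolSpec`.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal, ndimage

from .containers import Epochs, Recording
from .csd import csd_transform_matrix
from .montage import Montage
from .protocol import RejectionCriteria

__all__ = [
    "bandpass_filter", "rereference_average", "resample", "segment",
    "reject_artifacts", "csd_transform", "baseline_correct", "preprocess_subject",
]

log = logging.getLogger(__name__)

# Order-5 Butterworth applied forward-backward: zero phase, ~60 dB/octave
# combined roll-off beyond the cutoffs (the protocol requires >= 48).
_FILTER_ORDER = 5


def bandpass_filter(rec: Recording, lo: float = 0.5, hi: float = 20.0) -> Recording:
    """Zero-phase band-pass (default 0.5-20 Hz)."""
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    if rec.sfreq <= 2 * hi:
        raise ValueError("sampling rate must exceed twice the upper cutoff")
    rec.check_stage("bandpass")
    sos = signal.butter(_FILTER_ORDER, [lo, hi], btype="band", fs=rec.sfreq, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.evolve("bandpass", data=out)


def rereference_average(rec: Recording) -> Recording:
    """Re-reference to the common average; per-sample channel mean becomes 0."""
    if rec.data.shape[0] < 2:
        raise ValueError("average reference needs at least 2 channels")
    rec.check_stage("average_reference")
    out = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.evolve("average_reference", data=out)


def resample(rec: Recording, target_hz: float = 256.0) -> Recording:
    """Polyphase rational resampling (500 -> 256 Hz is up 128 / down 250).

    Event samples are re-timed to the nearest output sample.
    """
    if rec.sfreq < target_hz:
        raise ValueError("input rate must be at least the target rate")
    rec.check_stage("resample")
    frac = Fraction(target_hz / rec.sfreq).limit_denominator(10000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    events = rec.events.copy()
    events["sample"] = np.rint(events["sample"] * target_hz / rec.sfreq).astype(int)
    return rec.evolve("resample", data=out, sfreq=float(target_hz), events=events)


def segment(rec: Recording, trials: pd.DataFrame, epoch_ms=(-2000.0, 2000.0)) -> Epochs:
    """Cut target-locked epochs; only correct trials are retained.

    Target events without the full epoch margin inside the recording are
    dropped with a logged warning (rule ``edge`` in the rejection log).
    """
    rec.check_stage("segment")
    lo_s = int(np.floor(epoch_ms[0] / 1000.0 * rec.sfreq + 0.5))
    hi_s = int(np.floor(epoch_ms[1] / 1000.0 * rec.sfreq + 0.5))
    times_ms = np.arange(lo_s, hi_s + 1) / rec.sfreq * 1000.0
    targets = rec.events[rec.events["kind"] == "target"].set_index("trial")["sample"]
    correct = trials[trials["correct"]].copy()
    kept, dropped, data = [], [], []
    for _, row in correct.iterrows():
        t = int(targets.loc[row["trial"]])
        if t + lo_s < 0 or t + hi_s >= rec.n_samples:
            dropped.append({"trial": row["trial"], "channel": "*", "rule": "edge"})
            continue
        data.append(rec.data[:, t + lo_s: t + hi_s + 1])
        kept.append(row)
    if dropped:
        log.warning("subject %s: %d epochs dropped at recording edge", rec.subject, len(dropped))
    data = np.stack(data) if data else np.empty((0, len(rec.ch_names), times_ms.size))
    meta = pd.DataFrame(kept).reset_index(drop=True)
    return Epochs(data, times_ms, rec.sfreq, rec.ch_names, meta, subject=rec.subject,
                  unit=rec.unit, history=rec.history + ("segment",),
                  rejection_log=pd.DataFrame(dropped, columns=["trial", "channel", "rule"]))


def _window_samples(ms: float, sfreq: float) -> int:
    """ms -> number of samples covered by the window, rounding half-up."""
    return max(2, int(np.floor(ms / 1000.0 * sfreq + 0.5)))


def reject_artifacts(ep: Epochs, criteria: RejectionCriteria | None = None) -> Epochs:
    """Drop epochs violating amplitude criteria on any channel.

    Rules (boundary samples inclusive): absolute bound |x| > 100 uV;
    peak-to-peak > 200 uV within any 200 ms window; flatline, i.e. some
    100 ms window with peak-to-peak < 0.5 uV.
    """
    ep.check_stage("reject")
    criteria = criteria or RejectionCriteria()
    w_max = _window_samples(criteria.max_diff_window_ms, ep.sfreq)
    w_min = _window_samples(criteria.min_diff_window_ms, ep.sfreq)
    if max(w_max, w_min) > ep.data.shape[2]:
        raise ValueError("criterion window exceeds epoch length")
    keep = np.ones(ep.n_epochs, dtype=bool)
    log_rows = []

    def ptp_windows(x, w):
        # peak-to-peak over every fully contained window of w samples
        mx = ndimage.maximum_filter1d(x, size=w, axis=-1, mode="nearest")
        mn = ndimage.minimum_filter1d(x, size=w, axis=-1, mode="nearest")
        off = (w - 1) // 2
        valid = slice(off, off + x.shape[-1] - w + 1)
        return (mx - mn)[..., valid]

    for i in range(ep.n_epochs):
        x = ep.data[i]
        fired = None
        viol = np.abs(x) > criteria.absolute_uv
        if viol.any():
            fired = ("absolute", int(np.argmax(viol.any(axis=1))))
        if fired is None:
            p = ptp_windows(x, w_max)
            viol = p > criteria.max_diff_uv
            if viol.any():
                fired = ("max_diff", int(np.argmax(viol.any(axis=1))))
        if fired is None:
            p = ptp_windows(x, w_min)
            viol = p < criteria.min_diff_uv
            if viol.any():
                fired = ("min_diff", int(np.argmax(viol.any(axis=1))))
        if fired is not None:
            keep[i] = False
            log_rows.append({"trial": ep.trials.iloc[i]["trial"],
                             "channel": ep.ch_names[fired[1]], "rule": fired[0]})
    new_log = pd.concat([ep.rejection_log,
                         pd.DataFrame(log_rows, columns=["trial", "channel", "rule"])],
                        ignore_index=True)
    return ep.evolve("reject", data=ep.data[keep],
                     trials=ep.trials[keep].reset_index(drop=True), rejection_log=new_log)


def csd_transform(ep: Epochs, montage: Montage, m: int = 4, lam: float = 1e-5,
                  n_legendre: int = 50, head_radius: float = 1.0) -> Epochs:
    """Spherical-spline surface Laplacian; units become uV/m**2 (reference-free)."""
    ep.check_stage("csd")
    missing = [c for c in ep.ch_names if c not in montage]
    if missing:
        raise ValueError(f"montage does not cover channels {missing}")
    idx = [montage.index(c) for c in ep.ch_names]
    P = csd_transform_matrix(montage.positions[idx], m=m, lam=lam,
                             n_legendre=n_legendre, head_radius=head_radius)
    out = np.einsum("ij,tjs->tis", P, ep.data)
    return ep.evolve("csd", data=out, unit="uV/m2")


def baseline_correct(ep: Epochs, window_ms=(-500.0, -200.0)) -> Epochs:
    """Subtract the mean over the baseline window per trial and channel."""
    ep.check_stage("baseline")
    sl = ep.window_slice(window_ms)
    out = ep.data - ep.data[:, :, sl].mean(axis=2, keepdims=True)
    return ep.evolve("baseline", data=out)


def preprocess_subject(rec: Recording, trials: pd.DataFrame, montage: Montage,
                       protocol=None) -> Epochs:
    """Run the whole protocol on one subject's recording."""
    from .protocol import DEFAULT_PROTOCOL
    protocol = protocol or DEFAULT_PROTOCOL
    rec = bandpass_filter(rec, *protocol.bandpass_hz)
    rec = rereference_average(rec)
    rec = resample(rec, protocol.resample_hz)
    ep = segment(rec, trials, protocol.epoch_ms)
    ep = reject_artifacts(ep, protocol.rejection)
    ep = csd_transform(ep, montage)
    return baseline_correct(ep, protocol.baseline_ms)
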