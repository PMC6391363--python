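"""In-memory containers for continuous recordings and target-locked epochs.

The preprocessing protocol is a fixed sequence
(filter -> average reference -> resample -> segment -> reject -> CSD ->
baseline); each container records the stages already applied and every stage
checks its predecessors, so running stages out of order raises
:class:`PipelineOrderError` instead of silently producing wrong numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Recording", "Epochs", "ConditionAverages", "PipelineOrderError", "STAGES",
           "load_recording", "save_epochs", "load_epochs"]

STAGES = ("bandpass", "average_reference", "resample", "segment",
          "reject", "csd", "baseline")


class PipelineOrderError(RuntimeError):
    """A preprocessing stage was invoked out of protocol order."""


def _check_order(history, stage):
    want = STAGES[: STAGES.index(stage)]
    missing = [s for s in want if s not in history]
    if missing:
        raise PipelineOrderError(
            f"stage {stage!r} requires {missing} to have run first (done: {list(history)})")
    if stage in history:
        raise PipelineOrderError(f"stage {stage!r} already applied")


@dataclass
class Recording:
    """Continuous multichannel EEG for one subject.

    data     -- (n_channels, n_samples) float64 in microvolts;
    sfreq    -- sampling rate, Hz;
    ch_names -- channel labels matching the montage;
    events   -- DataFrame with columns ``trial``, ``kind``
                (prime/target/response) and ``sample``;
    """

    data: np.ndarray
    sfreq: float
    ch_names: tuple
    events: pd.DataFrame
    subject: int = 0
    unit: str = "uV"
    history: tuple = ()

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ch_names):
            raise ValueError("data must be (n_channels, n_samples) matching ch_names")
        self.ch_names = tuple(self.ch_names)

    @property
    def n_samples(self):
        return self.data.shape[1]

    def check_stage(self, stage):
        _check_order(self.history, stage)

    def evolve(self, stage, **kw):
        self.check_stage(stage)
        return replace(self, history=self.history + (stage,), **kw)

    def save(self, directory, stem="recording"):
        """Documented container: <stem>.npy (channels x samples), <stem>_meta.tsv
        (sampling rate, channels) and <stem>_events.tsv."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / f"{stem}.npy", self.data)
        meta = pd.DataFrame({"key": ["sfreq", "unit", "subject", "channels", "history"],
                             "value": [self.sfreq, self.unit, self.subject,
                                       ",".join(self.ch_names), ",".join(self.history)]})
        meta.to_csv(directory / f"{stem}_meta.tsv", sep="\t", index=False)
        self.events.to_csv(directory / f"{stem}_events.tsv", sep="\t", index=False)


@dataclass
class Epochs:
    """Target-locked epochs for one subject.

    data     -- (n_trials, n_channels, n_times) in ``unit``;
    times_ms -- time axis relative to target onset (strictly increasing);
    trials   -- per-epoch metadata (trial, compatibility, congruency, correct, rt_ms);
    rejection_log -- rows (trial, channel, rule) for dropped epochs.
    """

    data: np.ndarray
    times_ms: np.ndarray
    sfreq: float
    ch_names: tuple
    trials: pd.DataFrame
    subject: int = 0
    unit: str = "uV"
    history: tuple = ()
    rejection_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["trial", "channel", "rule"]))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (n_trials, n_channels, n_times)")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if self.data.shape[2] != self.times_ms.size:
            raise ValueError("time axis length mismatch")
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("trial metadata length mismatch")
        self.ch_names = tuple(self.ch_names)

    @property
    def n_epochs(self):
        return self.data.shape[0]

    def check_stage(self, stage):
        _check_order(self.history, stage)

    def evolve(self, stage, **kw):
        self.check_stage(stage)
        return replace(self, history=self.history + (stage,), **kw)

    def time_index(self, ms: float) -> int:
        """Sample index of a latency in ms (half-up rounding on the sample grid)."""
        rel = (ms - self.times_ms[0]) * self.sfreq / 1000.0
        return int(np.floor(rel + 0.5))

    def window_slice(self, window_ms) -> slice:
        """Closed window [lo, hi] ms -> slice of samples, endpoints inclusive."""
        lo, hi = window_ms
        if lo < self.times_ms[0] or hi > self.times_ms[-1]:
            raise ValueError(f"window {window_ms} outside epoch "
                             f"[{self.times_ms[0]}, {self.times_ms[-1]}] ms")
        return slice(self.time_index(lo), self.time_index(hi) + 1)


def load_recording(directory, stem="recording") -> Recording:
    """Inverse of :meth:`Recording.save`."""
    directory = Path(directory)
    data = np.load(directory / f"{stem}.npy")
    meta = pd.read_csv(directory / f"{stem}_meta.tsv", sep="\t",
                       dtype=str).set_index("key")["value"]
    events = pd.read_csv(directory / f"{stem}_events.tsv", sep="\t")
    history = tuple(h for h in str(meta.get("history", "")).split(",") if h)
    return Recording(data, float(meta["sfreq"]), tuple(meta["channels"].split(",")),
                     events, subject=int(meta["subject"]), unit=meta["unit"],
                     history=history)


def save_epochs(ep: Epochs, directory, stem="epochs"):
    """Documented epochs container: <stem>.npz (data + time axis), trial
    metadata and rejection log as TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / f"{stem}.npz", data=ep.data, times_ms=ep.times_ms)
    meta = pd.DataFrame({"key": ["sfreq", "unit", "subject", "channels", "history"],
                         "value": [ep.sfreq, ep.unit, ep.subject,
                                   ",".join(ep.ch_names), ",".join(ep.history)]})
    meta.to_csv(directory / f"{stem}_meta.tsv", sep="\t", index=False)
    ep.trials.to_csv(directory / f"{stem}_trials.tsv", sep="\t", index=False)
    ep.rejection_log.to_csv(directory / f"{stem}_rejections.tsv", sep="\t", index=False)


def load_epochs(directory, stem="epochs") -> Epochs:
    directory = Path(directory)
    arrays = np.load(directory / f"{stem}.npz")
    meta = pd.read_csv(directory / f"{stem}_meta.tsv", sep="\t",
                       dtype=str).set_index("key")["value"]
    trials = pd.read_csv(directory / f"{stem}_trials.tsv", sep="\t")
    rej = pd.read_csv(directory / f"{stem}_rejections.tsv", sep="\t")
    if rej.empty:
        rej = pd.DataFrame(columns=["trial", "channel", "rule"])
    history = tuple(h for h in str(meta.get("history", "")).split(",") if h)
    return Epochs(arrays["data"], arrays["times_ms"], float(meta["sfreq"]),
                  tuple(meta["channels"].split(",")), trials,
                  subject=int(meta["subject"]), unit=meta["unit"],
                  history=history, rejection_log=rej)


@dataclass
class ConditionAverages:
    """Per-subject condition-average waveforms for one prime-compatibility
    condition (flanker congruency pooled).

    data -- (n_subjects, n_channels, n_times); the input feature source for
    the data-driven discovery stage.
    """

    condition: str
    subjects: tuple
    data: np.ndarray
    ch_names: tuple
    times_ms: np.ndarray
    sfreq: float
    unit: str = "uV"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.subjects = tuple(self.subjects)
        self.ch_names = tuple(self.ch_names)
        if self.data.shape != (len(self.subjects), len(self.ch_names), self.times_ms.size):
            raise ValueError("data must be (n_subjects, n_channels, n_times)")
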