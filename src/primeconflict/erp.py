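"""Condition averaging and ERP mean-amplitude quantification.

Averages are formed separately per subject for each crossing of prime
compatibility and flanker congruency (or any subset of those factors), mean
amplitudes are taken over closed latency windows and then over the listed
electrodes, and the electrode choice can be validated against the rest of
the montage with Bonferroni-corrected paired tests.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConditionAverages, Epochs
from .protocol import DEFAULT_PROTOCOL

__all__ = ["average_condition", "condition_averages", "mean_amplitude",
           "measure_components", "validate_electrodes"]

log = logging.getLogger(__name__)


def average_condition(ep: Epochs, **conditions) -> np.ndarray:
    """Pointwise mean waveform (n_channels, n_times) over one condition cell.

    ``conditions`` are column=value filters on the epoch metadata, e.g.
    ``compatibility="incompatible"``.  An empty cell raises ``ValueError``
    (callers flag the subject/cell as missing rather than imputing).
    """
    mask = np.ones(ep.n_epochs, dtype=bool)
    for col, val in conditions.items():
        mask &= (ep.trials[col] == val).to_numpy()
    if not mask.any():
        raise ValueError(f"empty condition cell {conditions} for subject {ep.subject}")
    return ep.data[mask].mean(axis=0)


def condition_averages(per_subject_epochs: dict, condition: str) -> ConditionAverages:
    """Stack per-subject averages for one compatibility condition (congruency pooled).

    Subjects whose cell is empty are excluded with a warning.
    """
    subjects, rows = [], []
    ref = None
    for subj, ep in per_subject_epochs.items():
        ref = ref or ep
        try:
            rows.append(average_condition(ep, compatibility=condition))
            subjects.append(subj)
        except ValueError:
            warnings.warn(f"subject {subj}: no retained {condition} trials; excluded")
    return ConditionAverages(condition, tuple(subjects), np.stack(rows),
                             ref.ch_names, ref.times_ms, ref.sfreq, unit=ref.unit)


def mean_amplitude(waveform: np.ndarray, times_ms: np.ndarray, sfreq: float,
                   window_ms, electrodes, ch_names) -> float:
    """Mean over samples in the closed window, then over the listed electrodes."""
    if not electrodes:
        raise ValueError("electrode list is empty")
    lo, hi = window_ms
    if lo < times_ms[0] or hi > times_ms[-1]:
        raise ValueError("window outside waveform")
    i0 = int(np.floor((lo - times_ms[0]) * sfreq / 1000.0 + 0.5))
    i1 = int(np.floor((hi - times_ms[0]) * sfreq / 1000.0 + 0.5))
    names = list(ch_names)
    idx = [names.index(e) for e in electrodes]
    return float(waveform[idx, i0:i1 + 1].mean())


def measure_components(per_subject_epochs: dict, protocol=None) -> pd.DataFrame:
    """ErpMeasure table: one amplitude per subject x component x condition cell.

    The N2 window follows flanker congruency (300-320 ms incongruent,
    290-310 ms congruent); both windows feed the same component column.
    """
    protocol = protocol or DEFAULT_PROTOCOL
    rows = []
    for subj, ep in per_subject_epochs.items():
        for comp in protocol.components:
            for compat in ("compatible", "incompatible"):
                for congr in ("congruent", "incongruent"):
                    try:
                        wf = average_condition(ep, compatibility=compat, congruency=congr)
                    except ValueError:
                        log.warning("subject %s: empty cell %s/%s", subj, compat, congr)
                        continue
                    amp = mean_amplitude(wf, ep.times_ms, ep.sfreq,
                                         comp.window_for(congr), comp.electrodes,
                                         ep.ch_names)
                    rows.append({"subject": subj, "component": comp.name,
                                 "compatibility": compat, "congruency": congr,
                                 "amplitude": amp})
    return pd.DataFrame(rows)


def validate_electrodes(window_means: pd.DataFrame, polarity: int = 1,
                        alpha: float = 0.05) -> list:
    """Electrode-validation procedure for one component.

    ``window_means`` is subjects x electrodes (mean amplitude in the
    component's search window at every electrode).  Each electrode is
    compared to the mean of all remaining electrodes with a paired t-test
    across subjects; an electrode is selected iff its amplitude is
    significantly larger in the component's polarity direction after
    Bonferroni correction over the number of electrodes.
    """
    if window_means.shape[1] < 2:
        raise ValueError("need at least 2 electrodes")
    if window_means.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    n_el = window_means.shape[1]
    selected = []
    for el in window_means.columns:
        own = window_means[el].to_numpy()
        rest = window_means.drop(columns=[el]).mean(axis=1).to_numpy()
        diff = (own - rest) * polarity
        if np.allclose(diff.std(ddof=1), 0.0):
            warnings.warn(f"electrode {el}: zero-variance difference; not selected")
            continue
        t, p = stats.ttest_rel(own, rest)
        if t * polarity > 0 and p * n_el < alpha:
            selected.append(el)
    return selected
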