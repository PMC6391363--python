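"""Synthetic multichannel EEG with event markers.

Each trial inserts Gaussian-envelope component waveforms (P1/N1/N2/P3-like)
at prime- or target-locked latencies with smooth spatial topographies around
their center electrodes; condition modulations are additive amplitude deltas
and a per-subject PCE-linked scaling that couples the size of the
compatibility modulation to the subject's behavioral prime effect.  The
background is 1/f-amplitude noise with a white floor, spatially correlated
across channels through montage distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..containers import ConditionAverages, Recording
from ..montage import Montage
from .design import BehaviorParams, DesignSpec, draw_subject_effects, subject_rng

__all__ = ["ErpComponentSpec", "NoiseParams", "default_components",
           "simulate_eeg", "make_cohort", "Cohort", "simulate_condition_averages"]


@dataclass(frozen=True)
class ErpComponentSpec:
    """One evoked-deflection generator.

    Amplitudes in uV (signed: negative-going components carry negative
    ``amplitude_uv``); latencies in ms relative to the onset of ``locked_to``.
    The compatibility modulation of subject i is

        compat_delta_uv + pce_scaling_uv_per_ms * (pce_i - pce_reference)

    so a nonzero ``pce_scaling_uv_per_ms`` makes the condition difference
    grow with the subject's behavioral prime effect.
    """

    name: str
    locked_to: str              # "prime" | "target"
    peak_ms: float
    width_ms: float
    amplitude_uv: float
    centers: tuple
    spatial_spread_rad: float = 0.45
    compat_delta_uv: float = 0.0
    congr_delta_uv: float = 0.0
    congr_latency_shift_ms: float = 0.0
    pce_scaling_uv_per_ms: float = 0.0

    def __post_init__(self):
        if self.width_ms <= 0:
            raise ValueError("component width must be positive")
        if self.locked_to not in ("prime", "target"):
            raise ValueError("locked_to must be 'prime' or 'target'")

    def spatial_weights(self, montage: Montage) -> np.ndarray:
        missing = [c for c in self.centers if c not in montage]
        if missing:
            raise ValueError(f"component {self.name}: unknown electrodes {missing}")
        w = np.zeros(len(montage))
        for c in self.centers:
            ang = np.arccos(np.clip(
                montage.positions @ montage.positions[montage.index(c)], -1, 1))
            w += np.exp(-ang ** 2 / (2.0 * self.spatial_spread_rad ** 2))
        m = w.max()
        if not np.isfinite(m) or m <= 0:
            raise ValueError("spatial weights must sum to a finite positive value")
        return w / m

    def amplitude_for(self, compatibility: str, congruency: str,
                      pce_ms: float, pce_reference: float) -> float:
        amp = self.amplitude_uv
        if compatibility == "incompatible":
            amp += self.compat_delta_uv + self.pce_scaling_uv_per_ms * (pce_ms - pce_reference)
        if congruency == "incongruent":
            amp += self.congr_delta_uv
        return amp

    def peak_for(self, congruency: str) -> float:
        if congruency == "incongruent":
            return self.peak_ms + self.congr_latency_shift_ms
        return self.peak_ms

    def waveform(self, t_ms: np.ndarray, peak_ms: float) -> np.ndarray:
        """Gaussian envelope, compactly supported on +-4 widths."""
        d = np.asarray(t_ms) - peak_ms
        return np.where(np.abs(d) <= 4.0 * self.width_ms,
                        np.exp(-d ** 2 / (2.0 * self.width_ms ** 2)), 0.0)


def default_components() -> tuple:
    """The standard component set emulating the protocol's ERP windows.

    Latencies put each deflection's peak inside its quantification window
    (prime-locked peaks sit 60 ms earlier relative to the prime).  The N2
    carries the strongest PCE-linked scaling, echoing the conflict-monitoring
    interpretation; N1 components carry weaker scaling.
    """
    return (
        ErpComponentSpec("prime_P1", "prime", 122.5, 10.0, 6.0, ("P7", "P8"),
                         compat_delta_uv=0.8),
        ErpComponentSpec("prime_N1", "prime", 162.5, 12.0, -5.0, ("P7", "P8"),
                         compat_delta_uv=-1.5, pce_scaling_uv_per_ms=-0.03),
        ErpComponentSpec("target_P1", "target", 162.5, 12.0, 6.5, ("P7", "P8"),
                         compat_delta_uv=0.9, congr_delta_uv=2.0),
        ErpComponentSpec("target_N1", "target", 247.5, 12.0, -6.0, ("P9", "P10"),
                         compat_delta_uv=-2.0, congr_delta_uv=-2.0,
                         pce_scaling_uv_per_ms=-0.08),
        ErpComponentSpec("N2", "target", 300.0, 12.0, -5.0, ("FCz",),
                         compat_delta_uv=-3.0, congr_delta_uv=-3.0,
                         congr_latency_shift_ms=10.0, pce_scaling_uv_per_ms=-0.10),
        ErpComponentSpec("P3", "target", 295.0, 25.0, 7.0, ("PO1", "PO2")),
    )


@dataclass(frozen=True)
class NoiseParams:
    """1/f-amplitude background with a white floor, spatially correlated."""

    scale_uv: float = 10.0          # per-channel standard deviation
    knee_hz: float = 1.0            # below this the 1/f amplitude flattens
    white_fraction: float = 0.05    # flat amplitude floor relative to the knee
    spatial_sigma_rad: float = 0.6  # correlation length across the scalp

    def __post_init__(self):
        if self.scale_uv < 0:
            raise ValueError("noise scale must be non-negative")


def _noise_block(rng, n_ch: int, n_samples: int, sfreq: float,
                 noise: NoiseParams, mixing: np.ndarray | None) -> np.ndarray:
    if noise.scale_uv == 0:
        return np.zeros((n_ch, n_samples))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    amp = 1.0 / np.maximum(freqs, noise.knee_hz) * noise.knee_hz + noise.white_fraction
    amp[0] = 0.0
    spec = np.fft.rfft(rng.standard_normal((n_ch, n_samples)), axis=1) * amp
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    # analytic normalization: unit-variance white input -> known output power
    power = (2.0 * (amp[1:-1] ** 2).sum() + amp[-1] ** 2) / n_samples
    x *= noise.scale_uv / np.sqrt(power)
    if mixing is not None:
        x = mixing @ x
    return x


def _spatial_mixing(montage: Montage, noise: NoiseParams) -> np.ndarray | None:
    if noise.spatial_sigma_rad <= 0:
        return None
    ang = np.arccos(montage.cosines())
    C = np.exp(-ang ** 2 / (2.0 * noise.spatial_sigma_rad ** 2))
    L = np.linalg.cholesky(C + 1e-9 * np.eye(len(montage)))
    # preserve per-channel variance
    return L / np.linalg.norm(L, axis=1, keepdims=True)


def simulate_eeg(design: DesignSpec, components, trials: pd.DataFrame,
                 montage: Montage, noise: NoiseParams, seed: int,
                 pce_ms: float | None = None,
                 pce_reference: float | None = None) -> Recording:
    """Continuous recording for one subject's trial table.

    ``pce_ms`` is the subject's latent prime effect used by PCE-scaled
    components (defaults to the reference, i.e. no scaling contribution).
    """
    subjects = trials["subject"].unique()
    if len(subjects) != 1:
        raise ValueError("simulate_eeg expects the trial table of a single subject")
    if pce_reference is None:
        pce_reference = BehaviorParams().prime_effect_mean
    if pce_ms is None:
        pce_ms = pce_reference
    fs = design.sampling_rate_hz
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), int(subjects[0]), 7)))
    weights = {c.name: c.spatial_weights(montage) for c in components}

    # lay out the session timeline
    pad_start, pad_end = 2.2, 2.2   # seconds; epochs need 2 s on both sides
    t = pad_start
    events = []
    placements = []   # (component, amplitude, onset_time_of_locked_stimulus)
    for _, row in trials.sort_values("trial").iterrows():
        # snap stimulus onsets to the sample grid so noise-free epochs
        # reproduce component waveforms exactly
        prime_t = np.rint((t + design.fixation_ms / 1000.0) * fs) / fs
        target_t = prime_t + design.soa_ms / 1000.0
        events.append((row["trial"], "prime", prime_t))
        events.append((row["trial"], "target", target_t))
        rt = row["rt_ms"]
        if np.isfinite(rt):
            events.append((row["trial"], "response", target_t + rt / 1000.0))
            resp_elapsed = rt / 1000.0
        else:
            resp_elapsed = design.response_window_ms / 1000.0
        for comp in components:
            amp = comp.amplitude_for(row["compatibility"], row["congruency"],
                                     pce_ms, pce_reference)
            onset = prime_t if comp.locked_to == "prime" else target_t
            placements.append((comp, amp, onset, row["congruency"]))
        t = target_t + resp_elapsed + rng.uniform(*design.rsi_ms) / 1000.0
    n_samples = int(np.ceil((t + pad_end) * fs))

    data = _noise_block(rng, len(montage), n_samples, fs, noise,
                        _spatial_mixing(montage, noise))
    t_axis = np.arange(n_samples) / fs * 1000.0   # ms
    for comp, amp, onset, congr in placements:
        peak = comp.peak_for(congr)
        lo = int(np.floor((onset * 1000.0 + peak - 4 * comp.width_ms) / 1000.0 * fs))
        hi = int(np.ceil((onset * 1000.0 + peak + 4 * comp.width_ms) / 1000.0 * fs))
        lo, hi = max(lo, 0), min(hi, n_samples - 1)
        wf = amp * comp.waveform(t_axis[lo:hi + 1] - onset * 1000.0, peak)
        data[:, lo:hi + 1] += np.outer(weights[comp.name], wf)

    ev = pd.DataFrame(events, columns=["trial", "kind", "time_s"])
    ev["sample"] = np.rint(ev["time_s"] * fs).astype(int)
    return Recording(data, fs, montage.labels, ev.drop(columns="time_s"),
                     subject=int(subjects[0]))


@dataclass
class Cohort:
    trials: pd.DataFrame
    effects: pd.DataFrame
    recordings: dict
    montage: Montage
    design: DesignSpec


def make_cohort(design: DesignSpec, behavior_params: BehaviorParams,
                components, montage: Montage, noise: NoiseParams,
                seed: int) -> Cohort:
    """Behavior plus per-subject recordings, reproducible piecewise from the
    master seed (subject substreams are independent of cohort size)."""
    from .design import simulate_behavior
    trials, effects = simulate_behavior(design, behavior_params, seed)
    recordings = {}
    for subj, tab in trials.groupby("subject"):
        recordings[subj] = simulate_eeg(
            design, components, tab, montage, noise, seed,
            pce_ms=float(effects.loc[subj, "pce_ms"]),
            pce_reference=behavior_params.prime_effect_mean)
    return Cohort(trials, effects, recordings, montage, design)


def simulate_condition_averages(
        n_subjects: int, montage: Montage, seed: int,
        components=None, behavior_params: BehaviorParams | None = None,
        noise: NoiseParams | None = None, n_trials: int = 384,
        sfreq: float = 256.0, t_range_ms=(-500.0, 1600.0),
) -> tuple[ConditionAverages, ConditionAverages, pd.DataFrame]:
    """Per-subject condition-average waveforms, generated directly.

    This is the cohort generator collapsed to the sufficient statistics the
    feature-discovery stage consumes: for each subject and prime condition
    the deterministic component sum (congruency levels averaged) plus
    residual noise scaled by 1/sqrt(trials per condition).  Subject PCE draws
    reuse the same substreams as :func:`simulate_behavior`, so group labels
    derived from behavior match.
    """
    components = default_components() if components is None else components
    behavior_params = behavior_params or BehaviorParams()
    noise = noise or NoiseParams()
    lo_s = int(np.floor(t_range_ms[0] / 1000.0 * sfreq + 0.5))
    hi_s = int(np.floor(t_range_ms[1] / 1000.0 * sfreq + 0.5))
    times_ms = np.arange(lo_s, hi_s + 1) / sfreq * 1000.0
    weights = {c.name: c.spatial_weights(montage) for c in components}
    mixing = _spatial_mixing(montage, noise)
    n_per_cond = max(n_trials // 2, 1)
    pce_ref = behavior_params.prime_effect_mean

    out = {"compatible": [], "incompatible": []}
    effects = []
    for subj in range(n_subjects):
        rng = subject_rng(seed, subj)
        eff = draw_subject_effects(behavior_params, rng)
        effects.append({"subject": subj, **eff})
        for cond in ("compatible", "incompatible"):
            sig = np.zeros((len(montage), times_ms.size))
            for comp in components:
                # prime-locked peaks expressed on the target-locked axis
                offset = 0.0 if comp.locked_to == "target" else -60.0
                for congr in ("congruent", "incongruent"):
                    amp = comp.amplitude_for(cond, congr, eff["pce_ms"], pce_ref)
                    wf = amp * comp.waveform(times_ms, comp.peak_for(congr) + offset)
                    sig += 0.5 * np.outer(weights[comp.name], wf)
            sig += _noise_block(rng, len(montage), times_ms.size, sfreq,
                                noise, mixing) / np.sqrt(n_per_cond)
            out[cond].append(sig)
    effects = pd.DataFrame(effects).set_index("subject")
    subjects = tuple(range(n_subjects))
    mk = lambda cond: ConditionAverages(cond, subjects, np.stack(out[cond]),
                                        montage.labels, times_ms, sfreq)
    return mk("compatible"), mk("incompatible"), effects
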