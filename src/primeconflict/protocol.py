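"""Fixed analysis-protocol constants.

Everything the downstream stages treat as a given of the measurement
protocol lives here: ERP component windows and electrodes, the preprocessing
thresholds, the behavioral trial filter, and the feature-discovery settings
(k folds, filter alpha, confidence level, cardinality cap).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["ComponentWindow", "RejectionCriteria", "ProtocolSpec", "DEFAULT_PROTOCOL"]


@dataclass(frozen=True)
class ComponentWindow:
    """ERP quantification window: ``(lo_ms, hi_ms)`` after target onset, inclusive.

    ``polarity`` is +1 for positive-going components and -1 for negative-going
    ones; it orients the "larger amplitude" direction in electrode validation.
    For the N2 the window depends on flanker congruency.
    """

    name: str
    electrodes: tuple
    window_ms: tuple
    polarity: int
    window_ms_congruent: tuple | None = None

    def window_for(self, congruency: str | None = None) -> tuple:
        if self.window_ms_congruent is not None and congruency == "congruent":
            return self.window_ms_congruent
        return self.window_ms


@dataclass(frozen=True)
class RejectionCriteria:
    """Amplitude-based epoch rejection thresholds.

    absolute_uv       -- reject when |x| exceeds this anywhere (bound 100 uV);
    max_diff_uv       -- reject when peak-to-peak within ``max_diff_window_ms``
                         exceeds this (200 uV in 200 ms);
    min_diff_uv       -- reject when some ``min_diff_window_ms`` window has
                         peak-to-peak below this (flatline; 0.5 uV in 100 ms).
    """

    absolute_uv: float = 100.0
    max_diff_uv: float = 200.0
    max_diff_window_ms: float = 200.0
    min_diff_uv: float = 0.5
    min_diff_window_ms: float = 100.0

    def __post_init__(self):
        for f in ("absolute_uv", "max_diff_uv", "max_diff_window_ms",
                  "min_diff_uv", "min_diff_window_ms"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def _default_components():
    return (
        ComponentWindow("prime_P1", ("P7", "P8"), (55.0, 70.0), +1),
        ComponentWindow("prime_N1", ("P7", "P8"), (95.0, 110.0), -1),
        ComponentWindow("target_P1", ("P7", "P8"), (155.0, 170.0), +1),
        ComponentWindow("target_N1", ("P9", "P10"), (240.0, 255.0), -1),
        ComponentWindow("N2", ("FCz",), (300.0, 320.0), -1,
                        window_ms_congruent=(290.0, 310.0)),
        ComponentWindow("P3", ("PO1", "PO2"), (285.0, 305.0), +1),
    )


@dataclass(frozen=True)
class ProtocolSpec:
    components: tuple = field(default_factory=_default_components)
    rejection: RejectionCriteria = field(default_factory=RejectionCriteria)
    # preprocessing
    bandpass_hz: tuple = (0.5, 20.0)
    resample_hz: float = 256.0
    epoch_ms: tuple = (-2000.0, 2000.0)
    baseline_ms: tuple = (-500.0, -200.0)
    # behavior
    rt_bounds_ms: tuple = (100.0, 1000.0)
    accuracy_exclusion: float = 0.75
    # feature discovery
    feature_window_s: tuple = (0.0, 1.5)
    soa_ms: float = 60.0
    k_folds: int = 10
    filter_alpha: float = 0.01
    ci_level: float = 0.99
    max_features: int = 20
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    electrode_validation_alpha: float = 0.05

    def component(self, name: str) -> ComponentWindow:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(f"no ERP component named {name!r}")

    def replace(self, **kw) -> "ProtocolSpec":
        return replace(self, **kw)


DEFAULT_PROTOCOL = ProtocolSpec()
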