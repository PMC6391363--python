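"""Trial design and behavioral simulation.

Reaction times follow an ex-Gaussian whose mu is shifted additively by the
trial's condition: each subject draws a prime compatibility effect (PCE)
once, added on incompatible-prime trials, and a flanker congruency effect,
added on incongruent-flanker trials.  With mu = 323 ms, tau = 80 ms and the
38 / 14 ms mean effects the cohort reproduces the target condition means
(compatible about 410 ms, incompatible about 448 ms).  Accuracy is Bernoulli
through a logistic with condition penalties, keeping mean accuracy well
above the 75% exclusion bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignSpec", "BehaviorParams", "simulate_behavior", "subject_rng"]


@dataclass(frozen=True)
class DesignSpec:
    """Trial structure and timing of the masked-prime flanker task (ms)."""

    n_subjects: int = 243
    n_trials: int = 384
    n_blocks: int = 4
    fixation_ms: float = 100.0
    prime_ms: float = 30.0
    mask_ms: float = 30.0
    target_ms: float = 100.0
    response_window_ms: float = 2000.0
    rsi_ms: tuple = (1000.0, 1200.0)
    sampling_rate_hz: float = 500.0

    @property
    def soa_ms(self) -> float:
        """Prime-to-target onset asynchrony: prime + mask duration."""
        return self.prime_ms + self.mask_ms

    def __post_init__(self):
        if self.n_trials % 8 != 0:
            raise ValueError("n_trials must be divisible by the 8 design cells")
        if self.soa_ms != 60.0:
            # the feature latency bookkeeping assumes the canonical 60 ms SOA
            pass


@dataclass(frozen=True)
class BehaviorParams:
    """Ex-Gaussian RT and logistic accuracy parameters (times in ms)."""

    mu: float = 323.0
    sigma: float = 40.0
    tau: float = 80.0
    prime_effect_mean: float = 38.0
    prime_effect_sd: float = 15.0
    flanker_effect_mean: float = 14.0
    flanker_effect_sd: float = 8.0
    interaction_mean: float = 0.0
    interaction_sd: float = 0.0
    accuracy_intercept: float = 3.2
    accuracy_compat_penalty: float = 0.5
    accuracy_congr_penalty: float = 0.5

    def __post_init__(self):
        if min(self.sigma, self.tau) <= 0 or self.mu <= 0:
            raise ValueError("ex-Gaussian scale parameters must be positive")


def subject_rng(master_seed: int, subject: int) -> np.random.Generator:
    """Deterministic per-subject substream: the cohort is reproducible
    subject-by-subject regardless of cohort size or iteration order."""
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), int(subject))))


def draw_subject_effects(params: BehaviorParams, rng) -> dict:
    return {
        "pce_ms": rng.normal(params.prime_effect_mean, params.prime_effect_sd),
        "flanker_ms": rng.normal(params.flanker_effect_mean, params.flanker_effect_sd),
        "interaction_ms": rng.normal(params.interaction_mean, params.interaction_sd)
        if params.interaction_sd > 0 else params.interaction_mean,
    }


def _condition_grid(design: DesignSpec, rng) -> pd.DataFrame:
    reps = design.n_trials // 8
    cells = [(c, g, d) for c in ("compatible", "incompatible")
             for g in ("congruent", "incongruent") for d in ("left", "right")]
    rows = np.repeat(np.arange(8), reps)
    rng.shuffle(rows)
    tab = pd.DataFrame([cells[i] for i in rows],
                       columns=["compatibility", "congruency", "target_dir"])
    tab["prime_dir"] = np.where(tab["compatibility"] == "compatible",
                                tab["target_dir"],
                                np.where(tab["target_dir"] == "left", "right", "left"))
    tab["flanker_dir"] = np.where(tab["congruency"] == "congruent",
                                  tab["target_dir"],
                                  np.where(tab["target_dir"] == "left", "right", "left"))
    return tab


def simulate_behavior(design: DesignSpec, params: BehaviorParams,
                      seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full cohort's behavior.

    Returns ``(trials, subject_effects)``: one trial row per subject x trial
    (subject, trial, block, condition labels, correct, rt_ms) and the
    per-subject latent effect sizes actually drawn.
    """
    all_trials, all_effects = [], []
    for subj in range(design.n_subjects):
        rng = subject_rng(seed, subj)
        eff = draw_subject_effects(params, rng)
        tab = _condition_grid(design, rng)
        n = len(tab)
        shift = np.zeros(n)
        shift += np.where(tab["compatibility"] == "incompatible", eff["pce_ms"], 0.0)
        shift += np.where(tab["congruency"] == "incongruent", eff["flanker_ms"], 0.0)
        shift += np.where((tab["compatibility"] == "incompatible")
                          & (tab["congruency"] == "incongruent"),
                          eff["interaction_ms"], 0.0)
        rt = (params.mu + shift + rng.normal(0.0, params.sigma, n)
              + rng.exponential(params.tau, n))
        rt = np.maximum(rt, 1.0)
        logit = (params.accuracy_intercept
                 - params.accuracy_compat_penalty
                 * (tab["compatibility"] == "incompatible").to_numpy()
                 - params.accuracy_congr_penalty
                 * (tab["congruency"] == "incongruent").to_numpy())
        correct = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
        miss = rt > design.response_window_ms
        correct &= ~miss
        tab.insert(0, "subject", subj)
        tab.insert(1, "trial", np.arange(n))
        tab.insert(2, "block", np.arange(n) // (n // design.n_blocks))
        tab["correct"] = correct
        tab["rt_ms"] = np.where(miss, np.nan, rt)
        all_trials.append(tab)
        all_effects.append({"subject": subj, **eff})
    trials = pd.concat(all_trials, ignore_index=True)
    effects = pd.DataFrame(all_effects).set_index("subject")
    return trials, effects
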