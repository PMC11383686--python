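"""Population discriminability, coding-capacity arithmetic, and behavior.

Covers the stimulus-discriminability time course (one-way ANOVA F across the
12 background stimuli per time bin), the population coding-capacity
back-of-envelope (how long, or how many neurons, to tell M stimuli apart at
a given per-neuron information rate, assuming independent neurons and
additive bits), and memory-guided-saccade behavioral metrics with the
endpoint-window correctness rule and pre-inactivation normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.stats import f_oneway

__all__ = [
    "BehaviorTrial",
    "anova_f_timecourse",
    "discrimination_time",
    "neurons_needed",
    "behavior_metrics",
]

FloatArray = NDArray[np.float64]


@dataclass(frozen=True)
class BehaviorTrial:
    cue_location: tuple[float, float]      # dva
    saccade_endpoint: tuple[float, float]  # dva
    reaction_time: float                   # ms
    completed: bool
    correct: bool | None = None            # derived if None
    session: str = "s0"
    inactivation: str = "pre"              # "pre" | "post"

    def __post_init__(self) -> None:
        if self.reaction_time <= 0:
            raise ValueError("reaction time must be positive")
        if self.correct and not self.completed:
            raise ValueError("a correct trial must be completed")

    @property
    def cue_eccentricity(self) -> float:
        return float(np.hypot(*self.cue_location))

    @property
    def saccade_error(self) -> float:
        """Euclidean endpoint-to-cue distance (dva)."""
        return float(np.hypot(self.saccade_endpoint[0] - self.cue_location[0],
                              self.saccade_endpoint[1] - self.cue_location[1]))

    @property
    def in_window(self) -> bool:
        """Endpoint within the reward window: radius 2 dva for cue
        eccentricity <= 7 dva, 4 dva beyond."""
        radius = 2.0 if self.cue_eccentricity <= 7.0 else 4.0
        return self.saccade_error <= radius


def anova_f_timecourse(rates: FloatArray, labels) -> FloatArray:
    """One-way ANOVA F statistic per time bin.

    ``rates`` is (n_trials, n_bins); ``labels`` assigns each trial one of the
    stimulus classes (12 in the standard design).  Returns F per bin.
    """
    rates = np.asarray(rates, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two stimulus classes")
    groups_idx = [np.where(labels == c)[0] for c in classes]
    if min(len(g) for g in groups_idx) < 2:
        raise ValueError("every stimulus class needs at least two trials")
    out = np.empty(rates.shape[1])
    for j in range(rates.shape[1]):
        out[j] = f_oneway(*[rates[g, j] for g in groups_idx]).statistic
    return out


def discrimination_time(mi_bits_per_100ms: float, n_neurons: int,
                        n_stimuli: int) -> float:
    """Time (ms) for ``n_neurons`` independent neurons to accumulate enough
    information to distinguish ``n_stimuli`` equiprobable stimuli.

    Bits add across neurons and across 100 ms windows, so
    ``t = 100 log2(M) / (n mi)``.
    """
    if mi_bits_per_100ms <= 0:
        raise ValueError("information rate must be positive")
    if n_neurons < 1 or n_stimuli < 2:
        raise ValueError("need >= 1 neuron and >= 2 stimuli")
    return 100.0 * math.log2(n_stimuli) / (n_neurons * mi_bits_per_100ms)


def neurons_needed(mi_bits_per_100ms: float, time_ms: float,
                   n_stimuli: int) -> int:
    """Smallest neuron count whose pooled information over ``time_ms``
    reaches ``log2(n_stimuli)`` bits (independent neurons, additive bits)."""
    if mi_bits_per_100ms <= 0 or time_ms <= 0:
        raise ValueError("information rate and time must be positive")
    if n_stimuli < 2:
        raise ValueError("need >= 2 stimuli")
    need = math.log2(n_stimuli)
    per_neuron = mi_bits_per_100ms * time_ms / 100.0
    n = math.ceil(need / per_neuron - 1e-12)
    return max(n, 1)


def behavior_metrics(trials) -> pd.DataFrame:
    """Percent correct and normalized RT / saccade error per
    (session, inactivation) cell.

    Correctness defaults to the endpoint-in-window rule; percent correct is
    correct / completed trials.  RT and error are normalized by the
    session's median over pre-inactivation completed trials (so the pre
    medians are 1 by construction).  Raises when a session lacks
    pre-inactivation trials.
    """
    trials = list(trials)
    completed = [tr for tr in trials if tr.completed]
    if not completed:
        raise ValueError("no completed trials")
    rows = []
    sessions = sorted({tr.session for tr in completed})
    for sess in sessions:
        sess_trials = [tr for tr in completed if tr.session == sess]
        pre = [tr for tr in sess_trials if tr.inactivation == "pre"]
        if not pre:
            raise ValueError(
                f"session {sess}: no pre-inactivation trials to normalize by")
        rt_med = float(np.median([tr.reaction_time for tr in pre]))
        err_med = float(np.median([tr.saccade_error for tr in pre]))
        if err_med == 0:
            err_med = np.nan
        for phase in ("pre", "post"):
            sub = [tr for tr in sess_trials if tr.inactivation == phase]
            if not sub:
                continue
            correct = [tr.correct if tr.correct is not None else tr.in_window
                       for tr in sub]
            rows.append({
                "session": sess,
                "inactivation": phase,
                "n_completed": len(sub),
                "percent_correct": 100.0 * np.mean(correct),
                "norm_rt": float(np.median([tr.reaction_time for tr in sub])
                                 / rt_med),
                "norm_error": float(np.median([tr.saccade_error
                                               for tr in sub]) / err_med),
            })
    return pd.DataFrame(rows)
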