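"""Stochastic behavioral readout: choice probabilities and population indices.

A fly's choice in the T-maze is modeled as a 1-state Markov (Bernoulli)
process: the probability of avoiding the conditioned odor depends only on
the current MBON activity ``v`` (or, for the unconditioned shock test, on
the shock representation ``s``) through the logistic ``p = 1/(1+exp(-x))``.
The population learning index LI (and performance index PI) is the relative
difference of avoiders vs approachers, with expectation ``2p - 1 = tanh(x/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "BehavioralOutcome",
    "avoidance_probability",
    "expected_index",
    "stay_probability_two_stimuli",
    "empirical_index",
    "simulate_population",
]


def avoidance_probability(x):
    """Logistic avoidance probability ``1/(1+exp(-x))`` of an internal activity."""
    p = expit(np.asarray(x, dtype=float))
    return float(p) if p.ndim == 0 else p


def expected_index(x):
    """Expected choice index ``2p - 1 == tanh(x/2)`` for internal activity x."""
    out = np.tanh(np.asarray(x, dtype=float) / 2.0)
    return float(out) if out.ndim == 0 else out


def stay_probability_two_stimuli(v, s):
    """Probability of not moving when CS and US are offered in opposite arms.

    Depends only on the absolute value difference: ``1/(1+exp(-|v-s|))``,
    equal to 1/2 when the odor value matches the shock representation.
    """
    p = expit(np.abs(np.asarray(v, dtype=float) - np.asarray(s, dtype=float)))
    return float(p) if p.ndim == 0 else p


def empirical_index(n_avoid, n_approach):
    """Relative count difference ``(n_avoid - n_approach)/(n_avoid + n_approach)``."""
    n_avoid = np.asarray(n_avoid, dtype=float)
    n_approach = np.asarray(n_approach, dtype=float)
    total = n_avoid + n_approach
    if np.any(total <= 0):
        raise ValueError("empirical index undefined for empty groups")
    out = (n_avoid - n_approach) / total
    return float(out) if out.ndim == 0 else out


@dataclass
class BehavioralOutcome:
    """Per-trial choice counts of one condition plus pooled index statistics."""

    n_avoid: np.ndarray          # one entry per trial
    n_approach: np.ndarray
    indices: np.ndarray = field(init=False)
    index: float = field(init=False)
    sem: float = field(init=False)

    def __post_init__(self) -> None:
        self.n_avoid = np.atleast_1d(np.asarray(self.n_avoid))
        self.n_approach = np.atleast_1d(np.asarray(self.n_approach))
        self.indices = empirical_index(self.n_avoid, self.n_approach)
        self.indices = np.atleast_1d(self.indices)
        self.index = float(np.mean(self.indices))
        n = len(self.indices)
        self.sem = float(np.std(self.indices, ddof=1) / np.sqrt(n)) if n > 1 else 0.0


def simulate_population(p_avoid: float, n_fly: int, n_trial: int,
                        seed=None) -> BehavioralOutcome:
    """Bernoulli-sample a fly population's choices.

    Each of ``n_fly`` flies in each of ``n_trial`` trials independently avoids
    the conditioned arm with probability ``p_avoid`` (memoryless: no
    dependence on previous trials).  ``seed`` may be an int, a SeedSequence,
    or a Generator; equal seeds give identical counts.
    """
    if not 0.0 < p_avoid < 1.0:
        raise ValueError("p_avoid must lie strictly between 0 and 1")
    if n_fly < 1 or n_trial < 1:
        raise ValueError("n_fly and n_trial must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_avoid = rng.binomial(n_fly, p_avoid, size=n_trial)
    return BehavioralOutcome(n_avoid=n_avoid, n_approach=n_fly - n_avoid)
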