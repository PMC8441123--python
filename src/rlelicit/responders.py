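"""Simulated participants that accept or reject proposed configuration changes.

A responder carries a latent utility over configurations,

    U(c) = sum_i w_i * bit_i(c) + sum_{i<j} w_ij * bit_i(c) * bit_j(c),

with per-factor main weights ``w_i`` (negative values favour level 0)
and optional pairwise interaction weights for non-additive preferences.
Offered a change, the responder compares utilities.  With infinite
choice sharpness the rule is deterministic — accept iff the proposed
configuration strictly beats the current one by more than the status-quo
margin — and indifference defaults to *reject*, mirroring an interface
in which the current option stays selected unless the participant
actively picks the change.  With finite sharpness ``beta`` the accept
probability is ``logistic(beta * (U(proposed) - U(current) - margin))``;
``beta = 0`` gives the coin-flip null responder.

Cohorts draw participant weights from a Gaussian around a population
mean, the simplest model of a shared modal preference plus
between-participant dispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .factor_space import Configuration

__all__ = [
    "PreferenceProfile",
    "CohortSpec",
    "utility",
    "decide",
    "sample_cohort",
    "random_responder",
    "ReplayResponder",
]

ACCEPT = "accept"
REJECT = "reject"


@dataclass
class PreferenceProfile:
    """Latent utility parameters of one simulated participant."""

    main_weights: np.ndarray
    interaction_weights: dict[tuple[int, int], float] = field(default_factory=dict)
    noise_beta: float = math.inf
    status_quo_margin: float = 0.0

    def __post_init__(self) -> None:
        self.main_weights = np.asarray(self.main_weights, dtype=float)
        if self.main_weights.ndim != 1:
            raise ValueError("main_weights must be a 1-d weight vector")
        if self.noise_beta < 0:
            raise ValueError("noise_beta must be >= 0 (may be inf)")
        if self.status_quo_margin < 0:
            raise ValueError("status_quo_margin must be >= 0")
        k = len(self.main_weights)
        for (i, j) in self.interaction_weights:
            if not (0 <= i < k and 0 <= j < k and i != j):
                raise ValueError(f"bad interaction pair ({i}, {j}) for k={k}")

    def utility(self, config: Configuration) -> float:
        bits = config.levels
        u = float(np.dot(self.main_weights, bits))
        for (i, j), w in self.interaction_weights.items():
            u += w * bits[i] * bits[j]
        return u

    def decide(
        self,
        current: Configuration,
        proposed: Configuration,
        rng: np.random.Generator,
    ) -> str:
        return decide(self, current, proposed, rng)


def utility(profile: PreferenceProfile, config: Configuration) -> float:
    """Linear-plus-pairwise utility of a configuration."""
    return profile.utility(config)


def decide(
    profile: PreferenceProfile,
    current: Configuration,
    proposed: Configuration,
    rng: np.random.Generator,
) -> str:
    """Accept or reject a proposed one-factor change.

    Only the utility *difference* matters; adding a constant to all
    utilities leaves the decision distribution unchanged.
    """
    if current.code == proposed.code:
        raise ValueError("proposed configuration must differ from the current one")
    gap = profile.utility(proposed) - profile.utility(current) - profile.status_quo_margin
    if math.isinf(profile.noise_beta):
        return ACCEPT if gap > 0 else REJECT
    p_accept = float(expit(profile.noise_beta * gap))
    return ACCEPT if rng.random() < p_accept else REJECT


@dataclass
class CohortSpec:
    """Population model for a cohort of simulated participants.

    Defaults mirror the study conditions: 20 participants whose modal
    preference is the teleportation / full-body / responsive-crowd /
    realistic configuration (weights ``(-1, +1, +1, -1)``), with mild
    Gaussian dispersion of the weights and moderately sharp choices.
    """

    n_participants: int = 20
    mean_weights: Sequence[float] = (-1.0, 1.0, 1.0, -1.0)
    dispersion: float | Sequence[float] = 0.3
    interaction_weights: Mapping[tuple[int, int], float] | None = None
    noise_beta: float = 4.0
    status_quo_margin: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


def sample_cohort(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> list[PreferenceProfile]:
    """Draw one preference profile per participant.

    Weights are Gaussian around the population mean with the given
    per-factor standard deviation; dispersion 0 gives identical copies
    of the mean profile.  Reproducible from ``spec.seed`` when no
    generator is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mean = np.asarray(spec.mean_weights, dtype=float)
    sd = np.broadcast_to(
        np.asarray(spec.dispersion, dtype=float), mean.shape
    )
    interactions = dict(spec.interaction_weights or {})
    profiles = []
    for _ in range(spec.n_participants):
        w = mean if np.all(sd == 0) else rng.normal(mean, sd)
        profiles.append(
            PreferenceProfile(
                main_weights=np.array(w, dtype=float),
                interaction_weights=dict(interactions),
                noise_beta=spec.noise_beta,
                status_quo_margin=spec.status_quo_margin,
            )
        )
    return profiles


def random_responder(k: int = 4) -> PreferenceProfile:
    """Coin-flip null responder: accepts every proposal with probability 1/2."""
    return PreferenceProfile(main_weights=np.zeros(k), noise_beta=0.0)


class ReplayResponder:
    """Answers proposals by replaying a recorded session's decisions.

    Lets the pipeline process real (logged) participants through the
    same interface as simulated ones.  Raises if the live proposal
    sequence diverges from the recorded one.
    """

    def __init__(self, records):
        self._decisions = [
            (r.state_code, r.proposed_code, r.decision) for r in records
        ]
        self._cursor = 0

    def decide(
        self,
        current: Configuration,
        proposed: Configuration,
        rng: np.random.Generator | None = None,
    ) -> str:
        if self._cursor >= len(self._decisions):
            raise ValueError("replay exhausted: no more recorded decisions")
        state, prop, decision = self._decisions[self._cursor]
        if (current.code, proposed.code) != (state, prop):
            raise ValueError(
                f"replay mismatch at trial {self._cursor}: recorded "
                f"{state}->{prop}, live {current.code}->{proposed.code}"
            )
        self._cursor += 1
        return decision
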