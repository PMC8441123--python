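"""Tabular Q-learning agent that proposes one-factor configuration changes.

Each participant gets their own Q-table, a ``2**k x k`` array of action
values ``Q[s, a]`` initialised to zero.  After the participant accepts
(reward +1) or rejects (reward -1) a proposed change, the entry for the
current state and proposed action is updated by

    Q[s, a] <- l * (r + gamma * max_a' Q[s_p, a']) + (1 - l) * Q[s, a]

where ``s_p`` is the *proposed* state.  The defaults are a learning rate
``l = 0.2`` and discount ``gamma = 0.15`` — a deliberately short-horizon
agent, since a session offers only a couple of dozen proposals.

Action selection is epsilon-greedy with epsilon decaying linearly from
1.0 at the first trial to 0.1 at the last (both endpoints configurable),
so early proposals are random and late proposals exploit what has been
learned; a softmax policy is available as an alternative.  Ties among
equally valued greedy actions are broken uniformly at random to avoid
order bias in a table full of exact zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .factor_space import (
    Configuration,
    FactorSpace,
    ProposalAction,
    apply_action,
)

__all__ = ["AgentParams", "QTable", "Proposal", "select_action", "update_q"]


@dataclass
class AgentParams:
    """Learning and exploration parameters of the proposal agent.

    Parameters
    ----------
    learning_rate
        Step size ``l`` in (0, 1); default 0.2.
    discount
        Discount factor ``gamma`` in [0, 1); must stay below 1 for the
        update to have a stable fixed point.  Default 0.15.
    policy
        ``"epsilon-greedy"`` (default) or ``"softmax"``.
    epsilon_start, epsilon_end
        Linear exploration schedule endpoints; epsilon decays from
        ``epsilon_start`` at trial 0 to ``epsilon_end`` at trial
        ``epsilon_decay_trials`` and stays there.
    epsilon_decay_trials
        Length of the decay window; defaults to ``horizon - 1`` so the
        final trial of a session runs at ``epsilon_end``.
    horizon
        Number of proposals in a session (used only by the default
        decay window); default 24.
    softmax_temperature
        Temperature for the softmax policy.
    successor
        Which row supplies ``max Q`` in the update: ``"proposed"``
        (default; the row of the state the agent offered, whether or not
        the participant accepted) or ``"realized"`` (the row of the
        state actually occupied after the decision).
    """

    learning_rate: float = 0.2
    discount: float = 0.15
    policy: str = "epsilon-greedy"
    epsilon_start: float = 1.0
    epsilon_end: float = 0.1
    epsilon_decay_trials: int | None = None
    horizon: int = 24
    softmax_temperature: float = 0.5
    successor: str = "proposed"

    def __post_init__(self) -> None:
        if not 0.0 < self.learning_rate < 1.0:
            raise ValueError("learning_rate must be in (0, 1)")
        if not 0.0 <= self.discount < 1.0:
            raise ValueError("discount must be in [0, 1)")
        if self.policy not in ("epsilon-greedy", "softmax"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.successor not in ("proposed", "realized"):
            raise ValueError(f"unknown successor mode {self.successor!r}")

    def epsilon(self, trial_index: int) -> float:
        """Exploration probability at a 0-based trial index."""
        if trial_index < 0:
            raise ValueError("trial_index must be >= 0")
        window = self.epsilon_decay_trials
        if window is None:
            window = max(self.horizon - 1, 1)
        if window <= 0:
            return self.epsilon_end
        frac = min(trial_index, window) / window
        return self.epsilon_start + (self.epsilon_end - self.epsilon_start) * frac


class QTable:
    """Per-participant table of action values, ``2**k`` states x ``k`` actions."""

    def __init__(self, space: FactorSpace, values: np.ndarray | None = None):
        self.space = space
        if values is None:
            values = np.zeros((space.n_configurations, space.k))
        else:
            values = np.asarray(values, dtype=float)
            if values.shape != (space.n_configurations, space.k):
                raise ValueError(
                    f"Q-table shape {values.shape} does not match space "
                    f"({space.n_configurations}, {space.k})"
                )
        self.values = values

    def row(self, state: Configuration) -> np.ndarray:
        return self.values[state.code]

    def max_value(self, state: Configuration) -> float:
        return float(self.values[state.code].max())

    def copy(self) -> "QTable":
        return QTable(self.space, self.values.copy())

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, QTable)
            and self.space == other.space
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class Proposal:
    """An offered one-factor change: current state, action, proposed state."""

    state: Configuration
    action: ProposalAction
    proposed_state: Configuration

    def __post_init__(self) -> None:
        if self.proposed_state.code == self.state.code:
            raise ValueError("proposed state must differ from current state")
        if bin(self.proposed_state.code ^ self.state.code).count("1") != 1:
            raise ValueError("proposal must change exactly one factor")


def _greedy_action(q_row: np.ndarray, rng: np.random.Generator) -> int:
    best = np.flatnonzero(q_row == q_row.max())
    return int(best[rng.integers(len(best))]) if len(best) > 1 else int(best[0])


def select_action(
    qtable: QTable,
    state: Configuration,
    params: AgentParams,
    trial_index: int,
    rng: np.random.Generator,
) -> Proposal:
    """Pick which factor to offer to change from the current state.

    Epsilon-greedy: with probability ``epsilon(trial_index)`` a uniform
    random action, otherwise an argmax of ``Q[state, .]`` with uniform
    tie-breaking.  Softmax: action probabilities proportional to
    ``exp(Q / temperature)``.
    """
    space = qtable.space
    q_row = qtable.values[state.code]
    if params.policy == "softmax":
        z = q_row / params.softmax_temperature
        z = z - z.max()
        p = np.exp(z)
        p /= p.sum()
        a = int(rng.choice(space.k, p=p))
    else:
        if rng.random() < params.epsilon(trial_index):
            a = int(rng.integers(space.k))
        else:
            a = _greedy_action(q_row, rng)
    action = ProposalAction(a)
    return Proposal(state, action, apply_action(state, action, space))


def update_q(
    qtable: QTable,
    proposal: Proposal,
    reward: int,
    params: AgentParams,
    realized_state: Configuration | None = None,
) -> float:
    """Apply one value update in place; returns the new entry value.

    Exactly one entry — the (current state, proposed action) cell —
    changes.  The successor row is the proposed state's by default;
    pass ``realized_state`` when ``params.successor == "realized"``.
    """
    if reward not in (-1, 1):
        raise ValueError(f"reward must be +1 (accept) or -1 (reject), got {reward}")
    if params.successor == "realized":
        if realized_state is None:
            raise ValueError(
                "realized successor semantics need the post-decision state"
            )
        succ = realized_state
    else:
        succ = proposal.proposed_state
    l = params.learning_rate
    target = reward + params.discount * qtable.max_value(succ)
    s, a = proposal.state.code, proposal.action.factor_index
    new = l * target + (1.0 - l) * qtable.values[s, a]
    qtable.values[s, a] = new
    return float(new)


def value_bound(params: AgentParams) -> float:
    """Fixed-point magnitude bound ``1 / (1 - gamma)`` for unit rewards."""
    return 1.0 / (1.0 - params.discount)
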