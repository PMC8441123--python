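"""The main-phase trial loop: alternate agent proposals and responder decisions.

A session gives one participant a fixed budget of proposals (default 24).
Each trial the agent offers a one-factor change from the current
configuration; the responder accepts (the configuration changes, reward
+1) or rejects (it stays, reward -1); the agent's Q-table is updated
once.  Every trial contributes exactly one *visit* — to the
configuration occupied after the decision — so a cohort of 20
participants with 24 proposals each yields 480 visits.

Each participant gets a fresh zero Q-table and independent random
streams for the agent and the responder, spawned from one master seed so
either side can be replayed on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .factor_space import Configuration, FactorSpace
from .q_agent import AgentParams, QTable, select_action, update_q
from .responders import ACCEPT, REJECT, CohortSpec, sample_cohort

__all__ = [
    "TrialRecord",
    "SessionLog",
    "run_session",
    "run_cohort",
    "terminal_rejection_run",
]


@dataclass(frozen=True)
class TrialRecord:
    """One proposal-decision-reward event."""

    participant_id: str
    trial_index: int
    state_code: int
    action_factor: int
    proposed_code: int
    decision: str
    reward: int
    next_state_code: int

    def __post_init__(self) -> None:
        if self.decision not in (ACCEPT, REJECT):
            raise ValueError(f"unknown decision {self.decision!r}")
        expected_reward = 1 if self.decision == ACCEPT else -1
        if self.reward != expected_reward:
            raise ValueError(
                f"trial {self.trial_index}: decision {self.decision!r} "
                f"requires reward {expected_reward:+d}, got {self.reward:+d}"
            )
        expected_next = (
            self.proposed_code if self.decision == ACCEPT else self.state_code
        )
        if self.next_state_code != expected_next:
            raise ValueError(
                f"trial {self.trial_index}: next state {self.next_state_code} "
                f"inconsistent with decision {self.decision!r} "
                f"(expected {expected_next})"
            )


@dataclass
class SessionLog:
    """One participant's ordered trial sequence plus their final Q-table."""

    participant_id: str
    initial_code: int
    records: list[TrialRecord] = field(default_factory=list)
    qtable: QTable | None = None

    def validate_chain(self) -> None:
        """Each record's pre-decision state must equal the previous next-state."""
        state = self.initial_code
        for r in self.records:
            if r.state_code != state:
                raise ValueError(
                    f"participant {self.participant_id}, trial {r.trial_index}: "
                    f"state {r.state_code} breaks the chain (expected {state})"
                )
            state = r.next_state_code

    @property
    def final_code(self) -> int:
        return self.records[-1].next_state_code if self.records else self.initial_code


def run_session(
    space: FactorSpace,
    agent_params: AgentParams,
    responder,
    initial: Configuration,
    n_proposals: int = 24,
    agent_rng: np.random.Generator | None = None,
    responder_rng: np.random.Generator | None = None,
    participant_id: str = "p0",
) -> SessionLog:
    """Run one participant's main phase from a fresh zero Q-table.

    ``responder`` is anything with a ``decide(current, proposed, rng)``
    method returning ``"accept"`` or ``"reject"``.
    """
    if n_proposals < 0:
        raise ValueError("n_proposals must be >= 0")
    if agent_rng is None:
        agent_rng = np.random.default_rng()
    if responder_rng is None:
        responder_rng = np.random.default_rng()
    qtable = QTable(space)
    log = SessionLog(participant_id, initial.code, [], qtable)
    state = initial
    for t in range(n_proposals):
        proposal = select_action(qtable, state, agent_params, t, agent_rng)
        decision = responder.decide(state, proposal.proposed_state, responder_rng)
        accepted = decision == ACCEPT
        reward = 1 if accepted else -1
        next_state = proposal.proposed_state if accepted else state
        update_q(qtable, proposal, reward, agent_params, realized_state=next_state)
        log.records.append(
            TrialRecord(
                participant_id=participant_id,
                trial_index=t,
                state_code=state.code,
                action_factor=proposal.action.factor_index,
                proposed_code=proposal.proposed_state.code,
                decision=decision,
                reward=reward,
                next_state_code=next_state.code,
            )
        )
        state = next_state
    log.validate_chain()
    return log


def run_cohort(
    space: FactorSpace,
    cohort: CohortSpec | list,
    agent_params: AgentParams | None = None,
    n_proposals: int = 24,
    seed: int = 0,
    initial_codes: list[int] | None = None,
) -> list[SessionLog]:
    """Run one independent session per participant.

    ``cohort`` is either a :class:`CohortSpec` (profiles sampled from
    its own seed) or an explicit list of responders.  Session
    randomness flows from ``seed`` through named per-participant
    streams (agent, responder, initial state), so either side of the
    interaction can be replayed independently.  Initial configurations
    default to uniform random per participant — heterogeneous starts
    are what mitigates local maxima — but a fixed assignment may be
    passed.
    """
    if agent_params is None:
        agent_params = AgentParams(horizon=n_proposals)
    responders = (
        sample_cohort(cohort) if isinstance(cohort, CohortSpec) else list(cohort)
    )
    n = len(responders)
    if initial_codes is not None and len(initial_codes) != n:
        raise ValueError("initial_codes must have one entry per participant")
    master = np.random.SeedSequence(seed)
    children = master.spawn(n)
    logs = []
    for i, responder in enumerate(responders):
        agent_ss, resp_ss, init_ss = children[i].spawn(3)
        agent_rng = np.random.default_rng(agent_ss)
        responder_rng = np.random.default_rng(resp_ss)
        if initial_codes is None:
            code = int(
                np.random.default_rng(init_ss).integers(space.n_configurations)
            )
        else:
            code = initial_codes[i]
        logs.append(
            run_session(
                space,
                agent_params,
                responder,
                space.configuration(code),
                n_proposals=n_proposals,
                agent_rng=agent_rng,
                responder_rng=responder_rng,
                participant_id=f"p{i}",
            )
        )
    return logs


def replay_qtables(
    logs: list[SessionLog],
    space: FactorSpace,
    agent_params: AgentParams | None = None,
) -> list[QTable]:
    """Rebuild each participant's final Q-table from their recorded trials.

    The value update is deterministic given the learning parameters, so
    a log is all that is needed to reconstruct the table — this is how
    the analysis stage recovers Q-tables from archived CSV logs, and it
    doubles as the replay-determinism check for live runs.
    """
    if agent_params is None:
        agent_params = AgentParams()
    from .factor_space import ProposalAction, apply_action
    from .q_agent import Proposal

    tables = []
    for log in logs:
        log.validate_chain()
        qtable = QTable(space)
        for r in log.records:
            state = space.configuration(r.state_code)
            action = ProposalAction(r.action_factor)
            proposal = Proposal(state, action, apply_action(state, action, space))
            update_q(
                qtable,
                proposal,
                r.reward,
                agent_params,
                realized_state=space.configuration(r.next_state_code),
            )
        tables.append(qtable)
    return tables


def terminal_rejection_run(log: SessionLog) -> int:
    """Length of the maximal suffix of consecutive rejections.

    A long terminal rejection run signals convergence of the
    elicitation: the participant refuses to leave the configuration
    they have settled in.  Returns 0 if the last decision was an accept
    (or the log is empty).
    """
    count = 0
    for record in reversed(log.records):
        if record.decision != REJECT:
            break
        count += 1
    return count
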