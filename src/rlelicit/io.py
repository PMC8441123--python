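"""File formats, the bundled study fixture, and run configuration.

Session logs travel as plain CSV, one row per trial, with decisions
spelled out as the literal tokens ``accept`` / ``reject`` so they can
never be confused with level bits.  The reader validates what the
writer guarantees: chain consistency, decision/reward coherence, and
decision/next-state coherence, reporting the offending line number.

Q-tables travel as rectangular whitespace-separated text (one row per
state, one column per action) under comment headers recording the
learning parameters.

The bundled fixture is the study's pooled per-configuration visit
totals — 480 visits over the 16 configurations, dominated by
configuration 6 (``0110``) with 168 — which reproduce the published
posterior summaries when fed to the analysis module.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .analysis import VisitTable
from .factor_space import FactorSpace, default_space, space_from_dict
from .q_agent import AgentParams, QTable
from .responders import CohortSpec
from .session import SessionLog, TrialRecord

__all__ = [
    "SESSION_LOG_COLUMNS",
    "STUDY_VISIT_COUNTS",
    "write_session_log",
    "read_session_log",
    "write_qtable",
    "read_qtable",
    "load_study_counts",
    "load_config",
    "config_hash",
]

SESSION_LOG_COLUMNS = [
    "participant_id",
    "trial_index",
    "state_code",
    "action_factor",
    "proposed_code",
    "decision",
    "reward",
    "next_state_code",
]

# Pooled visit totals of the published 20-participant study, by
# configuration code; they sum to 24 choices x 20 participants = 480.
STUDY_VISIT_COUNTS: dict[int, int] = {
    0: 42, 1: 2, 2: 53, 3: 9, 4: 49, 5: 14, 6: 168, 7: 6,
    8: 14, 9: 4, 10: 14, 11: 3, 12: 13, 13: 7, 14: 72, 15: 10,
}


def write_session_log(
    logs: list[SessionLog], path, metadata: dict | None = None
) -> None:
    """Write cohort session logs as CSV (optional ``# key=value`` header)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        if metadata:
            for key, value in metadata.items():
                fh.write(f"# {key}={value}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SESSION_LOG_COLUMNS)
        for log in logs:
            for r in log.records:
                writer.writerow(
                    [
                        r.participant_id,
                        r.trial_index,
                        r.state_code,
                        r.action_factor,
                        r.proposed_code,
                        r.decision,
                        r.reward,
                        r.next_state_code,
                    ]
                )


def read_session_log(path) -> list[SessionLog]:
    """Read and validate a session-log CSV.

    Malformed rows are rejected with their line number; per-participant
    chains are re-validated after assembly.
    """
    path = Path(path)
    logs: dict[str, SessionLog] = {}
    with path.open(newline="") as fh:
        lineno = 0
        header = None
        reader = csv.reader(fh)
        for row in reader:
            lineno += 1
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = row
                if header != SESSION_LOG_COLUMNS:
                    raise ValueError(
                        f"{path}:{lineno}: unexpected header {header!r}"
                    )
                continue
            if len(row) != len(SESSION_LOG_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(SESSION_LOG_COLUMNS)} "
                    f"fields, got {len(row)}"
                )
            try:
                record = TrialRecord(
                    participant_id=row[0],
                    trial_index=int(row[1]),
                    state_code=int(row[2]),
                    action_factor=int(row[3]),
                    proposed_code=int(row[4]),
                    decision=row[5],
                    reward=int(row[6]),
                    next_state_code=int(row[7]),
                )
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from err
            pid = record.participant_id
            if pid not in logs:
                logs[pid] = SessionLog(pid, record.state_code, [])
            logs[pid].records.append(record)
        if header is None:
            raise ValueError(f"{path}: missing header row")
    for log in logs.values():
        log.validate_chain()
    return list(logs.values())


def write_qtable(
    qtable: QTable, path, params: AgentParams | None = None, seed=None
) -> None:
    """Write a Q-table as rectangular text with a parameter header."""
    path = Path(path)
    lines = []
    if params is not None:
        lines.append(
            f"# l={params.learning_rate} gamma={params.discount} "
            f"policy={params.policy}"
        )
    if seed is not None:
        lines.append(f"# seed={seed}")
    lines.append("# rows: state code 0..%d; columns: action factor 0..%d" % (
        qtable.space.n_configurations - 1, qtable.space.k - 1))
    for row in qtable.values:
        lines.append(" ".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_qtable(path, space: FactorSpace | None = None) -> QTable:
    """Read a Q-table written by :func:`write_qtable` (lossless floats)."""
    if space is None:
        space = default_space()
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rows.append([float(tok) for tok in line.split()])
    return QTable(space, np.array(rows))


def load_study_counts(space: FactorSpace | None = None) -> VisitTable:
    """The bundled pooled visit totals as a pooled-only :class:`VisitTable`.

    Per-participant counts were not published, so only the pooled
    vector is available; under the shared-probability multinomial model
    the pooled totals are a sufficient statistic, which is what makes
    this fixture enough to reproduce the published posteriors.
    """
    if space is None:
        space = default_space()
    pooled = np.array(
        [STUDY_VISIT_COUNTS[c] for c in range(space.n_configurations)]
    )
    return VisitTable(space=space, pooled=pooled)


def config_hash(doc: dict) -> str:
    """Short stable hash of a run-configuration document."""
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> dict:
    """Load a run configuration (factor space, agent, cohort, session).

    Returns a dict with keys ``space`` (:class:`FactorSpace`),
    ``agent`` (:class:`AgentParams`), ``cohort`` (:class:`CohortSpec`),
    ``n_proposals`` (int), ``raw`` (the document) and ``hash``.
    Every section is optional; defaults are the study conditions.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    space = (
        space_from_dict(doc["factors"]) if "factors" in doc else default_space()
    )
    n_proposals = int(doc.get("session", {}).get("n_proposals", 24))
    agent_doc = dict(doc.get("agent", {}))
    agent_doc.setdefault("horizon", n_proposals)
    agent = AgentParams(**agent_doc)
    cohort_doc = dict(doc.get("cohort", {}))
    if "interaction_weights" in cohort_doc and cohort_doc["interaction_weights"]:
        cohort_doc["interaction_weights"] = {
            tuple(int(i) for i in str(key).split(",")): float(w)
            for key, w in cohort_doc["interaction_weights"].items()
        }
    cohort = CohortSpec(**cohort_doc)
    return {
        "space": space,
        "agent": agent,
        "cohort": cohort,
        "n_proposals": n_proposals,
        "raw": doc,
        "hash": config_hash(doc),
    }
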