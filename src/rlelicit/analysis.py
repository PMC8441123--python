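"""Preference measures and Bayesian analysis of configuration visits.

Three descriptive measures summarise a cohort of sessions:

* **visits** — how often participants occupied each configuration after
  a proposal was resolved (one visit per trial);
* **stay ratio** — of the proposals offered while occupying a
  configuration, the fraction rejected (undefined where no proposal was
  ever offered);
* **RLscore(s)** — the sum of Q-table entries ``Q_p[s, a]`` over
  participants and actions; the lower the score, the more strongly
  participants refused to leave ``s``.

The inferential model treats the pooled visit counts ``n_j`` as a
multinomial draw with configuration probabilities ``p_j`` under a
jointly uniform (all-ones) Dirichlet prior, so the posterior is the
conjugate ``Dirichlet(1 + n_j)``.  Each component's marginal is a Beta
distribution, as is any factor-level marginal (the sum of ``p_j`` over
the configurations sharing a level), which yields closed-form means,
standard deviations and equal-tailed 95% credible intervals.  An MCMC
path — adaptive-scale random-walk Metropolis on the log-gamma
representation of the Dirichlet, with split-Rhat diagnostics — retains
the sampling-based workflow as a cross-check of the closed form.

A subsampling sensitivity analysis re-ranks configurations by RLscore
over random participant subsets, asking how stable the winner is to
who happened to be recruited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from .factor_space import FactorSpace, default_space
from .q_agent import QTable
from .responders import REJECT
from .session import SessionLog

__all__ = [
    "VisitTable",
    "PosteriorSummary",
    "McmcPosterior",
    "visit_counts",
    "stay_ratios",
    "rlscore",
    "qtables_of",
    "ranking_table",
    "dirichlet_posterior",
    "marginal_factor_posterior",
    "factor_marginals_table",
    "prob_simultaneous_max",
    "mcmc_posterior",
    "subsample_sensitivity",
]


@dataclass
class VisitTable:
    """Per-participant and pooled post-decision occupancy counts."""

    space: FactorSpace
    pooled: np.ndarray
    per_participant: np.ndarray | None = None
    participant_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.pooled = np.asarray(self.pooled)
        if self.pooled.shape != (self.space.n_configurations,):
            raise ValueError(
                f"pooled counts must have length {self.space.n_configurations}"
            )
        if np.any(self.pooled < 0):
            raise ValueError("visit counts must be non-negative")
        if self.per_participant is not None:
            self.per_participant = np.asarray(self.per_participant)
            if not np.array_equal(self.per_participant.sum(axis=0), self.pooled):
                raise ValueError("per-participant counts do not sum to pooled totals")

    @property
    def total(self) -> int:
        return int(self.pooled.sum())


@dataclass(frozen=True)
class PosteriorSummary:
    """Mean, sd and central 95% credible interval of one probability."""

    label: str
    mean: float
    sd: float
    lower: float
    upper: float
    source: str = "closed-form"

    def __post_init__(self) -> None:
        if not self.lower <= self.mean <= self.upper:
            raise ValueError(
                f"{self.label}: interval [{self.lower}, {self.upper}] "
                f"does not bracket the mean {self.mean}"
            )


def visit_counts(
    logs: list[SessionLog],
    space: FactorSpace | None = None,
    half: str = "all",
) -> VisitTable:
    """Tally post-decision visits per participant and pooled.

    Each trial contributes one visit to the configuration occupied after
    its decision; the pre-session initial state is not counted.
    ``half="first"`` truncates every session to its first half before
    counting — the truncation used to check whether a shorter
    experiment would have ranked configurations the same way.
    """
    if space is None:
        space = default_space()
    if half not in ("all", "first"):
        raise ValueError(f"half must be 'all' or 'first', got {half!r}")
    table = np.zeros((len(logs), space.n_configurations), dtype=int)
    ids = []
    for i, log in enumerate(logs):
        log.validate_chain()
        ids.append(log.participant_id)
        records = log.records
        if half == "first":
            records = records[: len(records) // 2]
        for r in records:
            table[i, r.next_state_code] += 1
    return VisitTable(
        space=space,
        pooled=table.sum(axis=0),
        per_participant=table,
        participant_ids=ids,
    )


def stay_ratios(
    logs: list[SessionLog], space: FactorSpace | None = None
) -> np.ndarray:
    """Per-configuration rejection fraction of the proposals offered there.

    The denominator is proposals *received* while occupying the
    configuration, not visits; the two differ whenever a participant
    accepts a move.  Configurations never offered a proposal get NaN
    (missing), not zero.
    """
    if space is None:
        space = default_space()
    offered = np.zeros(space.n_configurations)
    rejected = np.zeros(space.n_configurations)
    for log in logs:
        for r in log.records:
            offered[r.state_code] += 1
            if r.decision == REJECT:
                rejected[r.state_code] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(offered > 0, rejected / np.maximum(offered, 1), np.nan)
    return out


def qtables_of(logs: list[SessionLog]) -> list[QTable]:
    """Collect the final Q-tables attached to session logs."""
    tables = []
    for log in logs:
        if log.qtable is None:
            raise ValueError(
                f"participant {log.participant_id} has no Q-table attached"
            )
        tables.append(log.qtable)
    return tables


def rlscore(qtables: list[QTable]) -> np.ndarray:
    """Per-configuration sum of Q values over participants and actions.

    Additive in participants: the cohort score is exactly the sum of
    single-participant scores.
    """
    if not qtables:
        raise ValueError("need at least one Q-table")
    shape = qtables[0].values.shape
    for qt in qtables[1:]:
        if qt.values.shape != shape:
            raise ValueError(
                f"Q-table shapes differ: {qt.values.shape} vs {shape}"
            )
    return np.sum([qt.values.sum(axis=1) for qt in qtables], axis=0)


def ranking_table(
    visits: VisitTable,
    stay: np.ndarray,
    scores: np.ndarray,
) -> pd.DataFrame:
    """Configurations sorted ascending by RLscore (most preferred first).

    Ties break by higher visit count, then by configuration code.
    """
    space = visits.space
    n = space.n_configurations
    if len(stay) != n or len(scores) != n:
        raise ValueError("stay ratios and scores must align with the space")
    df = pd.DataFrame(
        {
            "code": np.arange(n),
            "configuration": [space.configuration(c).bits for c in range(n)],
            "visits": visits.pooled,
            "stay_ratio": stay,
            "rlscore": scores,
        }
    )
    df = df.sort_values(
        ["rlscore", "visits", "code"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return df


def _posterior_alphas(visits: VisitTable) -> np.ndarray:
    return 1.0 + np.asarray(visits.pooled, dtype=float)


def _beta_summary(a: float, b: float, label: str, source: str) -> PosteriorSummary:
    mean = a / (a + b)
    sd = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
    lower, upper = stats.beta.ppf([0.025, 0.975], a, b)
    return PosteriorSummary(label, mean, sd, float(lower), float(upper), source)


def dirichlet_posterior(visits: VisitTable) -> list[PosteriorSummary]:
    """Closed-form conjugate posterior of the configuration probabilities.

    Under the uniform Dirichlet prior the posterior is
    ``Dirichlet(1 + n_j)``; each component's marginal is
    ``Beta(1 + n_j, J - 1 + N - n_j)``.
    """
    alphas = _posterior_alphas(visits)
    total = alphas.sum()
    return [
        _beta_summary(a, total - a, f"config_{j}", "closed-form")
        for j, a in enumerate(alphas)
    ]


def marginal_factor_posterior(
    visits: VisitTable, factor_index: int, level: int = 1
) -> PosteriorSummary:
    """Posterior of the total probability of one factor level.

    By Dirichlet aggregation the sum of ``p_j`` over the configurations
    with the given level is ``Beta(sum alphas in the set, sum of the
    rest)``.  The level-0 and level-1 means are complementary.
    """
    space = visits.space
    if not 0 <= factor_index < space.k:
        raise ValueError(f"factor index {factor_index} out of range [0, {space.k - 1}]")
    if level not in (0, 1):
        raise ValueError(f"level must be 0 or 1, got {level}")
    alphas = _posterior_alphas(visits)
    in_set = np.array(
        [space.decode(j)[factor_index] == level for j in range(space.n_configurations)]
    )
    a = float(alphas[in_set].sum())
    b = float(alphas[~in_set].sum())
    label = space.factors[factor_index].label(level)
    return _beta_summary(a, b, label, "closed-form")


def factor_marginals_table(visits: VisitTable) -> pd.DataFrame:
    """Level-1 marginal summaries for every factor, one row per factor."""
    rows = []
    for i, factor in enumerate(visits.space.factors):
        s = marginal_factor_posterior(visits, i, level=1)
        rows.append(
            {
                "factor": factor.name,
                "level1": factor.level1,
                "mean": s.mean,
                "sd": s.sd,
                "lower": s.lower,
                "upper": s.upper,
                "level0": factor.level0,
                "level0_mean": 1.0 - s.mean,
            }
        )
    return pd.DataFrame(rows)


def prob_simultaneous_max(
    visits: VisitTable,
    config_code: int,
    n_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Posterior probability that one configuration beats all others at once.

    Monte-Carlo over Dirichlet posterior draws: the fraction of draws in
    which the named component is strictly the largest.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    space = visits.space
    if not 0 <= config_code < space.n_configurations:
        raise ValueError(f"configuration code {config_code} out of range")
    if rng is None:
        rng = np.random.default_rng()
    alphas = _posterior_alphas(visits)
    draws = rng.dirichlet(alphas, size=n_draws)
    target = draws[:, config_code]
    others = np.delete(draws, config_code, axis=1)
    return float(np.mean(target > others.max(axis=1)))


@dataclass
class McmcPosterior:
    """Posterior draws of the configuration probabilities plus diagnostics."""

    draws: np.ndarray  # (chains, retained draws, n_configurations)
    rhat: np.ndarray  # per configuration
    summaries: list[PosteriorSummary]
    accept_rate: float

    @property
    def max_rhat(self) -> float:
        return float(np.max(self.rhat))

    def mcse_mean(self) -> np.ndarray:
        """Monte-Carlo standard error of each posterior mean (ESS-based)."""
        ds = az.convert_to_dataset(self.draws)
        ess = az.ess(ds)["x"].values
        sd = self.draws.reshape(-1, self.draws.shape[-1]).std(axis=0)
        return sd / np.sqrt(ess)


def mcmc_posterior(
    visits: VisitTable,
    iterations: int = 2000,
    chains: int = 4,
    rng: np.random.Generator | None = None,
) -> McmcPosterior:
    """Sample the Dirichlet posterior by Markov chain Monte Carlo.

    The sampler works on ``x_j = log g_j`` of the gamma representation
    ``p = g / sum(g)``, ``g_j ~ Gamma(1 + n_j)``, whose coordinates are
    independent in the target.  Each coordinate runs an independence
    Metropolis-Hastings chain whose proposal is the moment-matched
    normal ``N(digamma(alpha_j), trigamma(alpha_j))`` — the Laplace
    approximation of the log-gamma density — so acceptance is high and
    autocorrelation low.  The first half of each chain is warmup and is
    discarded.  Split-Rhat is computed per configuration; values far
    from 1 raise, since they mean the retained draws cannot be trusted.
    """
    if iterations < 4:
        raise ValueError("iterations must be >= 4")
    if chains < 2:
        raise ValueError("need >= 2 chains for Rhat")
    if rng is None:
        rng = np.random.default_rng()
    alphas = _posterior_alphas(visits)
    n_par = len(alphas)
    warmup = iterations // 2
    keep = iterations - warmup

    from scipy.special import digamma, polygamma

    prop_mean = digamma(alphas)[None, :]
    prop_sd = np.sqrt(polygamma(1, alphas))[None, :]
    x = prop_mean + rng.normal(0.0, 1.0, size=(chains, n_par)) * prop_sd
    kept = np.empty((chains, keep, n_par))
    accepts = 0
    proposals_total = 0

    def log_ratio_terms(xv: np.ndarray) -> np.ndarray:
        # log target (alpha*x - exp(x)) minus log proposal density, up to consts
        return (
            alphas[None, :] * xv
            - np.exp(xv)
            + 0.5 * ((xv - prop_mean) / prop_sd) ** 2
        )

    w = log_ratio_terms(x)
    for it in range(iterations):
        prop = prop_mean + rng.normal(size=(chains, n_par)) * prop_sd
        w_prop = log_ratio_terms(prop)
        accept = np.log(rng.random(size=(chains, n_par))) < (w_prop - w)
        x = np.where(accept, prop, x)
        w = np.where(accept, w_prop, w)
        if it >= warmup:
            kept[:, it - warmup, :] = x
            accepts += int(accept.sum())
            proposals_total += accept.size

    g = np.exp(kept)
    p = g / g.sum(axis=-1, keepdims=True)
    rhat = az.rhat(az.convert_to_dataset(p))["x"].values
    if np.any(rhat > 1.2):
        raise RuntimeError(
            f"MCMC failed to converge: max Rhat = {np.max(rhat):.3f} "
            f"(per-parameter Rhat: {np.round(rhat, 3).tolist()})"
        )
    flat = p.reshape(-1, n_par)
    summaries = []
    for j in range(n_par):
        mean = float(flat[:, j].mean())
        sd = float(flat[:, j].std(ddof=1))
        lower, upper = np.quantile(flat[:, j], [0.025, 0.975])
        summaries.append(
            PosteriorSummary(f"config_{j}", mean, sd, float(lower), float(upper), "MCMC")
        )
    return McmcPosterior(
        draws=p,
        rhat=rhat,
        summaries=summaries,
        accept_rate=accepts / max(proposals_total, 1),
    )


def subsample_sensitivity(
    qtables: list[QTable],
    m: int,
    n_resamples: int = 10_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """How often each configuration wins the RLscore ranking in subsamples.

    Draws ``m`` of the participants without replacement ``n_resamples``
    times, recomputes the RLscore from the selected Q-tables, and
    records the argmin configuration; returns the frequency each
    configuration was the winner.  With ``m`` equal to the cohort size
    every resample reproduces the full-data winner.
    """
    n = len(qtables)
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, {n}], got {m}")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    per_participant = np.array([qt.values.sum(axis=1) for qt in qtables])
    n_config = per_participant.shape[1]
    counts = np.zeros(n_config)
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        scores = per_participant[idx].sum(axis=0)
        counts[int(np.argmin(scores))] += 1
    return counts / n_resamples
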