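# Methods

## The elicitation procedure

`rlelicit` models an adaptive preference-elicitation experiment over a
factorial design space. An interactive experience is configured by `k`
binary factors (the default space has four: navigation
teleportation/WiP, body representation hands/body, social feedback
ignored/feedback, rendering realistic/cartoon), giving `2^k`
*configurations*. A configuration's integer code is its level tuple
read as a big-endian bit string — the first-listed factor is the most
significant bit, so code 6 is `0110`.

Each participant interacts with their own tabular Q-learning agent.
The state `s` is the current configuration; an action `a` proposes
toggling one factor; the participant accepts (the configuration
changes, reward `r = +1`) or rejects (it stays, `r = -1`). After every
decision the agent updates one cell of its `2^k x k` Q-table:

    Q[s, a] <- l (r + gamma max_a' Q[s_p, a']) + (1 - l) Q[s, a]

with `s_p` the *proposed* state (an alternative that bootstraps from
the realized post-decision state is available behind
`AgentParams.successor="realized"`). Defaults: learning rate
`l = 0.2`, discount `gamma = 0.15`, zero-initialized tables. The small
discount reflects the short horizon — a session has only 24 proposals,
too few to estimate long-range returns; `gamma < 1` also bounds every
entry by `1/(1-gamma)`, which the property tests exercise.

The elicitation literature this models does not pin down the agent's
exploration rule, only that proposals start random and come to reflect
what was learned. We use epsilon-greedy with epsilon decaying linearly
from 1.0 at the first trial to 0.1 at the last (both endpoints and the
decay window configurable; a softmax policy is the configurable
alternative). Ties among equal-valued greedy actions break uniformly
at random: a fresh table is all zeros, so any deterministic tie-break
would bias early proposals toward low-indexed factors.

A session is a fixed budget of 24 proposals. Each decision contributes
exactly one *visit*, to the configuration occupied after the decision
resolves; the pre-session initial state is not counted. This is the
only convention under which 24 choices by 20 participants give 480
visits, which the bookkeeping tests pin down. Initial configurations
default to uniform random per participant (heterogeneous starts
mitigate local maxima); a fixed assignment can be passed. Panel timing
is not modelled — trials are an ordered sequence.

Convergence of the elicitation shows up as a terminal run of
rejections (`terminal_rejection_run`): the participant refuses to
leave the configuration they have settled in.

## Preference measures

- **visits** `n_j`: pooled post-decision occupancy counts.
- **stay ratio**: of the proposals *received* while occupying a
  configuration, the fraction rejected. The denominator is proposals
  received, not visits — the two differ whenever a participant accepts
  a move away. Configurations never offered a proposal are missing
  (NaN), not zero.
- **RLscore(s)** `= sum_p sum_a Q_p[s, a]`: the more strongly
  participants rejected changes out of `s`, the more negative the
  score; the ranking sorts ascending, with ties broken by higher visit
  count then by code. RLscore is exactly additive in participants,
  which is what makes the subsampling analysis cheap.

## The Bayesian model

Pooled visits are modelled as a multinomial draw with configuration
probabilities `p_j` under the jointly uniform Dirichlet prior (all
concentrations 1). The posterior is the conjugate
`Dirichlet(1 + n_j)`; each component's marginal is
`Beta(1 + n_j, J - 1 + N - n_j)`, and any factor-level marginal — the
sum of `p_j` over the configurations sharing one level — aggregates to
a Beta as well. Means, standard deviations and equal-tailed 95%
credible intervals (2.5%/97.5% Beta quantiles) are closed-form; report
tables round to 2 decimals, half away from zero.

The closed form is the primary inference path: the per-participant
multinomials with a shared `p` collapse to a single Dirichlet update
of the pooled counts, so pooled totals are sufficient — which is also
why the bundled fixture of pooled study counts is enough to reproduce
the published posterior summaries. A sampling path is retained to keep
the Stan-style workflow (and its Rhat check) reproducible without a
compiled sampler: per-coordinate independence Metropolis–Hastings on
the log-gamma representation `p = g / sum(g)`,
`g_j ~ Gamma(1 + n_j)`, whose coordinates are independent in the
target. The proposal is the moment-matched normal
`N(digamma(alpha_j), trigamma(alpha_j))`; acceptance runs around 95%
and autocorrelation is low, so 2000 iterations x 4 chains (first half
warmup) give split-Rhat ≈ 1.00 and means within Monte-Carlo error of
the closed form — asserted as the conjugacy oracle in the tests.
Chains whose split-Rhat exceeds 1.2 raise rather than return draws.

`prob_simultaneous_max` estimates, by Monte-Carlo over Dirichlet
draws, the posterior probability that one component strictly exceeds
all others at once; 1e5 draws give a binomial standard error below
0.0016 everywhere.

The subsampling sensitivity analysis re-draws `m` of the `n`
participants without replacement (default 15 of 20, 10 000 resamples),
recomputes RLscore from the selected Q-tables and records the argmin,
reporting how often each configuration wins. Argmin ties (rare,
exact-zero scores) resolve to the lowest code.

## The simulated cohort

The study this package operationalizes used human participants and
published no behavioural model of them, so the simulated responders
are stand-ins judged only by whether the pipeline recovers their
planted preferences. A responder scores configurations with a
linear-plus-pairwise utility
`U(c) = sum_i w_i bit_i + sum_{i<j} w_ij bit_i bit_j` and accepts a
proposal with probability
`logistic(beta (U(proposed) - U(current) - margin))`; `beta = inf` is
the deterministic rule, and indifference defaults to *reject* because
the interface keeps the current option selected unless the participant
actively picks the change (`status_quo_margin` defaults to 0).
`beta = 0` is the coin-flip null responder.

Cohort defaults mirror the study conditions: 20 participants, 24
proposals each. The population preference defaults to main weights
`(-1, +1, +1, -1)` — modal configuration `0110`, the study's winner —
with Gaussian between-participant dispersion `sigma = 0.3` and choice
sharpness `beta = 4` (a 1-unit utility gap is accepted ~98% of the
time). Dispersion and sharpness have no empirical anchor; they were
chosen once as "shared modal preference plus mild heterogeneity", the
weakest structure under which inter-participant consistency is a
finding rather than an artifact. Recovery tests that need exact
replicas use dispersion 0 and `beta = inf`.

What the generator does *not* emulate: fatigue, cybersickness, order
and novelty effects, drifting preferences, and any dependence of
acceptance on the factor being changed rather than the configurations
compared. Passing recovery tests therefore show the pipeline extracts
planted stationary preferences from accept/reject sequences; they do
not validate the agent against real human behaviour.

## Known limitations

- The Dirichlet–multinomial model treats the 480 visits as iid given
  `p`, but visits from an accept/reject walk are autocorrelated within
  participants (a rejected proposal repeats the previous visit). For
  strongly preferred configurations this matters little — sessions
  converge and stay — but under the coin-flip null the visit sequence
  is a lazy random walk on the hypercube whose factor-level counts
  carry several times the multinomial variance, so the model's
  credible intervals are anticonservative there. The null-calibration
  check in the acceptance suite documents this: marginal intervals
  centred on 0.5 cover it far less often than nominal under null
  responders. Conclusions about *which* configuration wins are robust
  (the simultaneous-maximum probability rarely exceeds 0.95 under the
  null); the interval widths under model misspecification are not.
- Only binary factors are implemented; the types do not preclude
  multi-level factors but no operation handles them.
- Stay ratios are descriptive; no uncertainty is attached to them.
- The replay responder requires the live proposal sequence to match
  the recorded one exactly; it replays sessions, it does not
  generalize a logged participant to new proposals.
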