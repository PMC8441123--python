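import numpy as np
import pytest

import rlelicit as rl
from rlelicit.analysis import (
    VisitTable,
    dirichlet_posterior,
    factor_marginals_table,
    marginal_factor_posterior,
    mcmc_posterior,
    prob_simultaneous_max,
    qtables_of,
    ranking_table,
    rlscore,
    stay_ratios,
    subsample_sensitivity,
    visit_counts,
)
from rlelicit.q_agent import QTable
from rlelicit.responders import ACCEPT, REJECT
from rlelicit.session import SessionLog, TrialRecord


def rec(t, state, action, proposed, decision, pid="p0"):
    return TrialRecord(
        pid, t, state, action, proposed,
        decision, 1 if decision == ACCEPT else -1,
        proposed if decision == ACCEPT else state,
    )


class TestVisitCounts:
    def test_pooled_total_matches_cohort_size(self, space, planted_cohort_logs):
        v = visit_counts(planted_cohort_logs, space)
        assert v.total == 480
        assert np.all(v.per_participant.sum(axis=1) == 24)

    def test_post_decision_convention_on_handcrafted_log(self, space):
        # accept to 8, then reject twice: three visits to 8, none to 0
        log = SessionLog("p0", 0, [
            rec(0, 0, 0, 8, ACCEPT),
            rec(1, 8, 1, 12, REJECT),
            rec(2, 8, 2, 10, REJECT),
        ])
        v = visit_counts([log], space)
        assert v.pooled[8] == 3
        assert v.pooled[0] == 0
        assert v.total == 3

    def test_all_reject_session_counts_only_the_start(self, space):
        log = SessionLog("p0", 5, [
            rec(t, 5, t % 4, 5 ^ (1 << (3 - t % 4)), REJECT) for t in range(24)
        ])
        v = visit_counts([log], space)
        assert v.pooled[5] == 24 and v.total == 24

    def test_first_half_truncation(self, space):
        log = SessionLog("p0", 0, [
            rec(0, 0, 0, 8, ACCEPT),
            rec(1, 8, 1, 12, ACCEPT),
            rec(2, 12, 2, 14, ACCEPT),
            rec(3, 14, 3, 15, REJECT),
        ])
        v = visit_counts([log], space, half="first")
        assert v.total == 2
        assert v.pooled[8] == 1 and v.pooled[12] == 1

    def test_negative_counts_rejected(self, space):
        with pytest.raises(ValueError):
            VisitTable(space=space, pooled=np.array([-1] + [0] * 15))


class TestStayRatiosAndScores:
    def test_stay_ratio_uses_proposals_received_as_denominator(self, space):
        log = SessionLog("p0", 0, [
            rec(0, 0, 0, 8, REJECT),
            rec(1, 0, 1, 4, REJECT),
            rec(2, 0, 2, 2, ACCEPT),
            rec(3, 2, 3, 3, REJECT),
        ])
        ratios = stay_ratios([log], space)
        assert ratios[0] == pytest.approx(2 / 3)
        assert ratios[2] == 1.0
        assert np.isnan(ratios[5])  # never offered a proposal there

    def test_all_reject_start_state_has_ratio_one(self, space):
        log = SessionLog("p0", 7, [
            rec(t, 7, t % 4, 7 ^ (1 << (3 - t % 4)), REJECT) for t in range(8)
        ])
        assert stay_ratios([log], space)[7] == 1.0

    def test_rlscore_sums_over_participants_and_actions(self, space):
        q1, q2 = QTable(space), QTable(space)
        q1.values[6] = [-0.2, 0.0, 0.0, 0.0]
        q2.values[6] = [-0.2, -0.36, 0.0, 0.0]
        scores = rlscore([q1, q2])
        assert scores[6] == pytest.approx(-0.76)
        assert rlscore([q1])[6] == pytest.approx(-0.2)
        assert np.all(rlscore([QTable(space)]) == 0)

    def test_rlscore_is_additive_in_participants(self, space, planted_cohort_logs):
        tables = qtables_of(planted_cohort_logs)
        combined = rlscore(tables)
        summed = np.sum([rlscore([t]) for t in tables], axis=0)
        assert np.allclose(combined, summed, atol=0)

    def test_rlscore_rejects_mismatched_dimensions(self, space):
        from rlelicit.factor_space import Factor, FactorSpace

        other = FactorSpace(factors=(Factor("x", "a", "b"),))
        with pytest.raises(ValueError):
            rlscore([QTable(space), QTable(other)])

    def test_ranking_puts_planted_preference_first(self, space, planted_cohort_logs):
        v = visit_counts(planted_cohort_logs, space)
        df = ranking_table(
            v,
            stay_ratios(planted_cohort_logs, space),
            rlscore(qtables_of(planted_cohort_logs)),
        )
        assert df.iloc[0]["code"] == 6
        assert df.iloc[0]["rlscore"] == df["rlscore"].min()

    def test_ranking_tie_break_by_visits_then_code(self, space):
        v = VisitTable(space=space, pooled=np.arange(16))
        df = ranking_table(v, np.full(16, np.nan), np.zeros(16))
        assert df.iloc[0]["code"] == 15  # all scores tie; most visits first
        flat = VisitTable(space=space, pooled=np.zeros(16, dtype=int))
        df2 = ranking_table(flat, np.full(16, np.nan), np.zeros(16))
        assert list(df2["code"]) == list(range(16))

    def test_sole_refuser_is_the_unique_negative_score(self, space, rng):
        from rlelicit.q_agent import AgentParams

        class RejectAll:
            def decide(self, current, proposed, rng):
                return REJECT

        log = rl.run_session(
            space, AgentParams(), RejectAll(), space.configuration(9),
            n_proposals=24, agent_rng=rng, responder_rng=rng,
        )
        scores = rlscore([log.qtable])
        assert scores[9] < 0
        assert np.all(np.delete(scores, 9) == 0)


class TestConjugatePosterior:
    def test_uniform_prior_with_no_data(self, space):
        empty = VisitTable(space=space, pooled=np.zeros(16, dtype=int))
        sums = dirichlet_posterior(empty)
        assert all(s.mean == pytest.approx(1 / 16) for s in sums)
        for i in range(4):
            assert marginal_factor_posterior(empty, i).mean == pytest.approx(0.5)

    def test_component_mean_from_study_counts(self, study_visits):
        sums = dirichlet_posterior(study_visits)
        assert sums[6].mean == pytest.approx(169 / 496, abs=1e-12)
        assert sums[6].mean == pytest.approx(0.341, abs=5e-4)

    def test_component_means_normalise(self, study_visits):
        sums = dirichlet_posterior(study_visits)
        assert sum(s.mean for s in sums) == pytest.approx(1.0, abs=1e-12)

    def test_marginal_complementarity_and_interval_order(self, study_visits):
        for i in range(4):
            hi = marginal_factor_posterior(study_visits, i, level=1)
            lo = marginal_factor_posterior(study_visits, i, level=0)
            assert hi.mean + lo.mean == pytest.approx(1.0, abs=1e-12)
            assert hi.lower <= hi.mean <= hi.upper

    def test_marginal_matches_beta_oracle(self, study_visits):
        # independent check: simulate the aggregated Beta marginal directly
        from scipy import stats

        s = marginal_factor_posterior(study_visits, 1, level=1)
        a, b = 339 + 8, 141 + 8  # level-1 body counts + 8 prior pseudo-counts
        assert s.mean == pytest.approx(a / (a + b), abs=1e-12)
        assert s.sd == pytest.approx(stats.beta.std(a, b), abs=1e-12)
        assert s.lower == pytest.approx(stats.beta.ppf(0.025, a, b), abs=1e-12)

    def test_invalid_factor_or_level_rejected(self, study_visits):
        with pytest.raises(ValueError):
            marginal_factor_posterior(study_visits, 4)
        with pytest.raises(ValueError):
            marginal_factor_posterior(study_visits, 0, level=2)


class TestSimultaneousMax:
    def test_dominant_component_wins_always(self, space, rng):
        counts = np.zeros(16, dtype=int)
        counts[0] = 100
        v = VisitTable(space=space, pooled=counts)
        assert prob_simultaneous_max(v, 0, 20_000, rng) > 0.99

    def test_two_equal_components_split_evenly(self, space):
        counts = np.zeros(16, dtype=int)
        counts[3] = counts[12] = 200
        v = VisitTable(space=space, pooled=counts)
        p3 = prob_simultaneous_max(v, 3, 40_000, np.random.default_rng(0))
        p12 = prob_simultaneous_max(v, 12, 40_000, np.random.default_rng(1))
        se = np.sqrt(0.25 / 40_000)
        assert abs(p3 - 0.5) < 4 * se
        assert abs(p12 - 0.5) < 4 * se

    def test_two_seeds_agree_within_binomial_error(self, study_visits):
        counts = np.zeros(16, dtype=int)
        counts[6], counts[14] = 30, 25
        v = VisitTable(space=study_visits.space, pooled=counts)
        n = 50_000
        p1 = prob_simultaneous_max(v, 6, n, np.random.default_rng(10))
        p2 = prob_simultaneous_max(v, 6, n, np.random.default_rng(11))
        se = np.sqrt(p1 * (1 - p1) / n)
        assert abs(p1 - p2) <= 3 * np.sqrt(2) * se


class TestMcmc:
    def test_mcmc_agrees_with_closed_form(self, study_visits):
        res = mcmc_posterior(study_visits, rng=np.random.default_rng(99))
        cf = dirichlet_posterior(study_visits)
        mcse = res.mcse_mean()
        for j, (m, c) in enumerate(zip(res.summaries, cf)):
            assert abs(m.mean - c.mean) < 3 * mcse[j]
            assert abs(m.sd - c.sd) < 0.1 * c.sd
        assert res.max_rhat < 1.005

    def test_mcmc_on_empty_counts_recovers_uniform(self, space):
        empty = VisitTable(space=space, pooled=np.zeros(16, dtype=int))
        res = mcmc_posterior(empty, rng=np.random.default_rng(7))
        mcse = res.mcse_mean()
        for j, s in enumerate(res.summaries):
            assert abs(s.mean - 1 / 16) < 4 * mcse[j]

    def test_mcmc_is_deterministic_given_the_seed(self, study_visits):
        a = mcmc_posterior(study_visits, rng=np.random.default_rng(5))
        b = mcmc_posterior(study_visits, rng=np.random.default_rng(5))
        assert np.array_equal(a.draws, b.draws)


class TestSubsampleSensitivity:
    def test_full_sample_resampling_is_degenerate(self, planted_cohort_logs):
        tables = qtables_of(planted_cohort_logs)
        freq = subsample_sensitivity(tables, m=len(tables), n_resamples=50,
                                     rng=np.random.default_rng(2))
        full = np.argmin(rlscore(tables))
        assert freq[full] == 1.0

    def test_dominant_preference_survives_subsampling(self, planted_cohort_logs):
        tables = qtables_of(planted_cohort_logs)
        freq = subsample_sensitivity(tables, m=15, n_resamples=1000,
                                     rng=np.random.default_rng(3))
        assert freq[6] == 1.0

    def test_null_cohort_has_no_stable_winner(self, space):
        profiles = [rl.random_responder() for _ in range(20)]
        logs = rl.run_cohort(space, profiles, n_proposals=24, seed=77)
        freq = subsample_sensitivity(qtables_of(logs), m=15, n_resamples=500,
                                     rng=np.random.default_rng(4))
        assert freq.max() < 0.95

    def test_m_out_of_range_rejected(self, planted_cohort_logs):
        tables = qtables_of(planted_cohort_logs)
        with pytest.raises(ValueError):
            subsample_sensitivity(tables, m=0, n_resamples=10)
        with pytest.raises(ValueError):
            subsample_sensitivity(tables, m=21, n_resamples=10)


def test_factor_marginals_table_shape_and_complements(study_visits):
    df = factor_marginals_table(study_visits)
    assert list(df["factor"]) == [
        "navigation", "body_representation", "social_feedback", "rendering",
    ]
    assert np.allclose(df["mean"] + df["level0_mean"], 1.0)
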