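"""Hybrid agent choice rule, value updates and session simulation."""

import numpy as np
import pytest
from scipy.special import expit

from retroval.agents import (
    AgentParams,
    ParamDistribution,
    QState,
    RatingModel,
    generate_cohort,
    plan_model_based,
    simulate_session,
    stage1_choice_probs,
    update_model_free,
)
from retroval.stats import choice_indices, stay_table, subject_indices
from retroval.task import TaskConfig


class TestChoiceRule:
    def test_zero_precision_is_uniform(self):
        qs = QState(q_mf_s1=np.array([5.0, -3.0]), q_s2=np.array([1.0, 0.0, 0.5, 0.2]))
        p = stage1_choice_probs(qs, AgentParams(beta=0.0, pi=0.0), None, 0.7)
        assert np.allclose(p, [0.5, 0.5])

    def test_greedy_limit(self):
        qs = QState(q_s2=np.array([1.0, 0.0, 0.0, 0.0]))
        p = stage1_choice_probs(
            qs, AgentParams(omega=1.0, beta=100.0, pi=0.0), None, 0.7
        )
        assert p[0] > 0.999

    def test_softmax_matches_direct_evaluation(self):
        """ω=0.5 mixture with hand-set values equals the logistic of the
        β-scaled net-value difference."""
        qs = QState(q_mf_s1=np.array([0.2, 0.8]))
        qs.q_s2 = np.array([0.6, 0.0, 0.4, 0.0])  # planning values (0.6*.7+0.4*.3, ...)
        params = AgentParams(omega=0.5, beta=2.0, pi=0.0)
        q_mb = plan_model_based(qs, 0.7)
        q_net = 0.5 * q_mb + 0.5 * qs.q_mf_s1
        expected = expit(2.0 * (q_net[0] - q_net[1]))
        p = stage1_choice_probs(qs, params, None, 0.7)
        assert p[0] == pytest.approx(expected, abs=1e-12)

    def test_perseverance_biases_previous_colour(self):
        qs = QState()
        p = stage1_choice_probs(qs, AgentParams(beta=0.0, pi=1.0), 1, 0.7)
        assert p[1] > 0.5


class TestModelFreeUpdate:
    def test_zero_learning_rate_freezes_values(self):
        qs = QState(q_mf_s1=np.array([0.3, 0.1]), q_s2=np.array([0.2, 0.0, 0.5, 0.9]))
        before = qs.copy()
        update_model_free(qs, 0, 3, 1, AgentParams(alpha=0.0))
        assert np.array_equal(qs.q_mf_s1, before.q_mf_s1)
        assert np.array_equal(qs.q_s2, before.q_s2)

    def test_full_credit_limit(self):
        qs = QState()
        update_model_free(qs, 0, 0, 1, AgentParams(alpha=1.0, lam=1.0))
        assert qs.q_s2[0] == 1.0 and qs.q_mf_s1[0] == 1.0

    def test_single_step_arithmetic_oracle(self):
        """α=0.5, λ=0.5, q2=0.4, q1=0.2, r=1: the two-step update computed by
        hand — q1 += .5(.4−.2) + .25(1−.4) = 0.45; q2 += .5(1−.4) = 0.7."""
        qs = QState(q_mf_s1=np.array([0.2, 0.0]), q_s2=np.array([0.4, 0.0, 0.0, 0.0]))
        update_model_free(qs, 0, 0, 1, AgentParams(alpha=0.5, lam=0.5))
        assert qs.q_mf_s1[0] == pytest.approx(0.45)
        assert qs.q_s2[0] == pytest.approx(0.7)
        assert qs.q_mf_s1[1] == 0.0 and np.all(qs.q_s2[1:] == 0.0)


class TestPlanning:
    def test_zero_values(self):
        assert np.allclose(plan_model_based(QState(), 0.7), [0.0, 0.0])

    def test_forced_by_formula(self):
        qs = QState(q_s2=np.array([1.0, 0.0, 0.0, 0.0]))
        q_mb = plan_model_based(qs, 0.7)
        assert q_mb[0] == pytest.approx(0.7) and q_mb[1] == pytest.approx(0.3)

    def test_enumeration_oracle(self):
        """Planning value equals the explicit expectation over transitions of
        the per-state max, enumerated directly."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            q2 = rng.uniform(-1, 1, 4)
            qs = QState(q_s2=q2)
            q_mb = plan_model_based(qs, 0.7)
            for c in (0, 1):
                expect = sum(
                    p * max(q2[2 * s], q2[2 * s + 1])
                    for p, s in [(0.7, c), (0.3, 1 - c)]
                )
                assert q_mb[c] == pytest.approx(expect, abs=1e-12)


class TestSimulation:
    def test_no_learning_ratings_sit_at_midpoint(self, config):
        rm = RatingModel(rule="none", noise_sd=0.0)
        sess = simulate_session(AgentParams(), rm, config, seed=5)
        ratings = [tr.rating_raw for tr in sess.trials if tr.rating_raw is not None]
        assert len(ratings) == config.n_trials - config.rating_warmup
        assert np.allclose(ratings, rm.map_to_scale(0.5))

    def test_determinism_under_seed(self, config):
        a = simulate_session(AgentParams(), RatingModel(), config, seed=9)
        b = simulate_session(AgentParams(), RatingModel(), config, seed=9)
        assert [tr.chosen_colour for tr in a.trials] == [tr.chosen_colour for tr in b.trials]
        assert [tr.rating_raw for tr in a.trials] == [tr.rating_raw for tr in b.trials]

    def test_aborted_trials_carry_no_stage2(self):
        cfg = TaskConfig(p_abort=0.3)
        sess = simulate_session(AgentParams(), RatingModel(), cfg, seed=11)
        aborted = [tr for tr in sess.trials if tr.aborted]
        assert aborted, "expected some aborted trials at p_abort=0.3"
        for tr in aborted:
            assert tr.s2_state is None and tr.reward is None and tr.rating_raw is None

    def test_beta_zero_stay_near_half(self, config):
        """Random responders show ~0.5 stay probability in all four cells."""
        cohort, _ = generate_cohort(
            12, AgentParams(beta=0.0, pi=0.0), RatingModel(), config, seed=13
        )
        cells = np.array(
            [[stay_table(s).cell(c) for c in ("CR", "CU", "RR", "RU")] for s in cohort]
        )
        assert np.all(np.abs(np.nanmean(cells, axis=0) - 0.5) < 0.06)

    def test_choice_mb_monotone_in_omega(self, config):
        """Across a cohort with ω spanning [0,1], the model-based choice index
        increases with the generating ω (rank correlation > 0)."""
        from scipy.stats import spearmanr

        cohort, truths = generate_cohort(
            30, ParamDistribution(), RatingModel(), config, seed=17
        )
        idx = [choice_indices(stay_table(s))[0] for s in cohort]
        omegas = [p.omega for p in truths]
        rho = spearmanr(omegas, idx).statistic
        assert rho > 0.3

    def test_mbdq_cohort_shows_positive_ratings_mb(self, config):
        """Retrospective MBΔQ training of shape values yields the model-based
        transfer signature in the ratings index."""
        cohort, _ = generate_cohort(
            20, ParamDistribution(), RatingModel(rule="MBdQ", noise_sd=10.0),
            config, seed=19,
        )
        si = subject_indices(cohort)
        assert si.ratings_mb.mean() > 5.0

    def test_cohort_records_generating_params(self, config):
        cohort, truths = generate_cohort(
            5, ParamDistribution(), RatingModel(), config, seed=23
        )
        assert len(cohort) == len(truths) == 5
        assert len({s.subject_id for s in cohort}) == 5
        for p in truths:
            p.validate()
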