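"""Unit tests for the active-inference engine."""

import numpy as np
import pytest
from scipy.special import digamma

from attachinf import AttachmentConfig, builders, engine
from attachinf.engine import (
    BeliefState,
    DirichletFamily,
    EmptyPolicyError,
    InvalidConcentrationError,
    ModelExpectations,
    PrecisionDivergenceError,
)

from conftest import brute_force_policy_value, random_small_model


class TestExpectedLogParams:
    def test_symmetric_pair(self):
        # psi(1) - psi(2) = -1 by the digamma recurrence
        np.testing.assert_allclose(
            engine.expected_log_params([1.0, 1.0]), [-1.0, -1.0], atol=1e-12
        )

    def test_large_concentration_limit(self):
        out = engine.expected_log_params([1e6] * 3)
        np.testing.assert_allclose(out, np.log(1 / 3), atol=1e-5)

    def test_extreme_asymmetry(self):
        out = engine.expected_log_params([1e3, 1e-10])
        assert abs(out[0]) < 1e-6
        assert out[1] < -1e9  # psi(x) ~ -1/x as x -> 0

    def test_rejects_nonpositive(self):
        with pytest.raises(InvalidConcentrationError):
            engine.expected_log_params([1.0, 0.0])

    def test_exp_sums_below_one(self, rng):
        c = rng.gamma(1.0, 2.0, size=6) + 0.01
        assert np.exp(engine.expected_log_params(c)).sum() <= 1.0 + 1e-12


def _exact_log_expectations(logA, logD, logC=None):
    """ModelExpectations with exactly specified log parameters."""
    logA = np.asarray(logA, dtype=float)
    A = np.exp(logA)
    A = A / A.sum(axis=0, keepdims=True)
    return ModelExpectations(
        log_likelihood=logA,
        log_transitions=np.zeros((1, logA.shape[1], logA.shape[1])),
        log_initial=np.asarray(logD, dtype=float),
        likelihood=A,
        transitions=np.zeros((1, logA.shape[1], logA.shape[1])),
        log_preferences=np.zeros(logA.shape[0]) if logC is None else logC,
    )


class TestInferStates:
    def test_uniform_inputs_give_uniform_belief(self):
        exps = _exact_log_expectations(
            np.log(np.full((3, 4), 0.25)), np.log(np.full(4, 0.25))
        )
        out = engine.infer_states(None, 1, 1, expectations=exps)
        np.testing.assert_allclose(out, 0.25, atol=1e-12)

    def test_matches_exact_bayes(self):
        # P(o|s) = [0.9, 0.2], prior [0.5, 0.5] -> 0.45 / 0.55 split
        exps = _exact_log_expectations(
            np.log([[0.9, 0.2], [0.1, 0.8]]), np.log([0.5, 0.5])
        )
        out = engine.infer_states(None, 0, 1, expectations=exps)
        np.testing.assert_allclose(out, [0.45 / 0.55, 0.10 / 0.55], atol=1e-9)

    def test_confident_likelihood_pins_state(self, config):
        # accurate likelihood + flat initial prior: observing (Seek, I1)
        # leaves essentially all mass on (Seek, Attend)
        process = builders.build_interoceptive_process(config)
        model = builders.build_perfect_model(process, config)
        model.posteriors.initial = np.ones(6)
        out = engine.infer_states(model, 0, 1)
        assert out[0] > 0.999

    def test_requires_history_after_step_one(self, perfect_intero):
        _, model = perfect_intero
        with pytest.raises(ValueError):
            engine.infer_states(model, 0, 2)

    def test_rejects_bad_observation(self, perfect_intero):
        _, model = perfect_intero
        with pytest.raises(IndexError):
            engine.infer_states(model, 99, 1)


class TestEnumeratePolicies:
    def test_singletons_at_last_decision_step(self):
        ps = engine.enumerate_policies(3, 4, 4)
        assert ps.count == 3 and ps.depth == 1

    def test_full_depth_at_first_step(self):
        ps = engine.enumerate_policies(3, 1, 4, decisions_per_episode=3)
        assert ps.count == 27
        # lexicographic: first action varies slowest
        assert ps.policies[0].tolist() == [0, 0, 0]
        assert ps.policies[1].tolist() == [0, 0, 1]
        assert ps.policies[-1].tolist() == [2, 2, 2]

    def test_degenerate_control_set(self):
        assert engine.enumerate_policies(1, 2, 4).count == 1

    def test_past_last_decision_step(self):
        with pytest.raises(EmptyPolicyError):
            engine.enumerate_policies(3, 4, 4, decisions_per_episode=3)

    def test_stable_across_calls(self):
        a = engine.enumerate_policies(2, 1, 3).policies
        b = engine.enumerate_policies(2, 1, 3).policies
        np.testing.assert_array_equal(a, b)


class TestPredictBeliefs:
    @staticmethod
    def _exps_with_transition(B):
        B = np.asarray(B, dtype=float)[None]
        J = B.shape[1]
        A = np.eye(J)
        return ModelExpectations(
            log_likelihood=np.log(np.maximum(A, 1e-300)),
            log_transitions=np.log(np.maximum(B, 1e-300)),
            log_initial=np.log(np.full(J, 1 / J)),
            likelihood=A,
            transitions=B,
            log_preferences=np.log(np.full(J, 1 / J)),
        )

    def test_single_matrix_vector_product(self):
        exps = self._exps_with_transition([[0.7, 0.4], [0.3, 0.6]])
        preds = engine.predict_beliefs(None, [1.0, 0.0], [0], expectations=exps)
        np.testing.assert_allclose(preds[0][0], [0.7, 0.3], atol=1e-12)

    def test_deterministic_permutation(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        exps = self._exps_with_transition(P)
        preds = engine.predict_beliefs(None, [1.0, 0.0], [0, 0, 0], expectations=exps)
        expected = [[0, 1], [1, 0], [0, 1]]
        for (s, _), want in zip(preds, expected):
            np.testing.assert_allclose(s, want, atol=1e-12)

    def test_uniform_transitions_wash_out_belief(self, rng):
        exps = self._exps_with_transition(np.full((3, 3), 1 / 3))
        belief = rng.dirichlet(np.ones(3))
        preds = engine.predict_beliefs(None, belief, [0, 0], expectations=exps)
        for s, o in preds:
            np.testing.assert_allclose(s, 1 / 3, atol=1e-12)


class TestPolicyQuality:
    def test_no_uncertainty_no_epistemic_value(self):
        # degenerate belief, deterministic transition, identity likelihood
        B = np.array([[0.0, 1.0], [1.0, 0.0]])
        C = np.array([0.8, 0.2])
        exps = ModelExpectations(
            log_likelihood=np.log(np.maximum(np.eye(2), 1e-300)),
            log_transitions=np.log(np.maximum(B[None], 1e-300)),
            log_initial=np.log([0.5, 0.5]),
            likelihood=np.eye(2),
            transitions=B[None],
            log_preferences=np.log(C),
        )
        q, ext, epi = engine.policy_quality(None, [1.0, 0.0], [0], expectations=exps)
        assert epi == pytest.approx(0.0, abs=1e-12)
        assert ext == pytest.approx(np.log(0.2), abs=1e-12)

    def test_observation_resolving_two_states_gains_ln2(self):
        # uniform 2-state prediction, identity likelihood: the outcome
        # fully resolves the state -> epistemic value ln 2 per step
        B = np.full((2, 2), 0.5)
        exps = ModelExpectations(
            log_likelihood=np.log(np.maximum(np.eye(2), 1e-300)),
            log_transitions=np.log(B[None]),
            log_initial=np.log([0.5, 0.5]),
            likelihood=np.eye(2),
            transitions=B[None],
            log_preferences=np.log([0.5, 0.5]),
        )
        q, ext, epi = engine.policy_quality(None, [0.3, 0.7], [0], expectations=exps)
        assert epi == pytest.approx(np.log(2), abs=1e-9)

    def test_matches_brute_force_on_random_models(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            model = random_small_model(rng)
            exps = engine.compute_expectations(model)
            belief = rng.dirichlet(np.ones(model.num_states))
            depth = int(rng.integers(1, model.horizon + 1))
            policy = rng.integers(0, model.num_actions, size=depth)
            q, ext, epi = engine.policy_quality(
                model, belief, policy, expectations=exps
            )
            assert q == pytest.approx(ext + epi, abs=1e-12)
            assert q == pytest.approx(
                brute_force_policy_value(exps, belief, policy), abs=1e-8
            )

    def test_tree_evaluation_matches_per_policy(self):
        rng = np.random.default_rng(3)
        model = random_small_model(rng)
        exps = engine.compute_expectations(model)
        belief = rng.dirichlet(np.ones(model.num_states))
        depth = 2
        ext, epi = engine._evaluate_policy_tree(
            exps, belief, model.num_actions, depth
        )
        ps = engine.enumerate_policies(
            model.num_actions, 1, depth + 1, decisions_per_episode=depth
        )
        for k, pol in enumerate(ps.policies):
            _, e, i = engine.policy_quality(model, belief, pol, expectations=exps)
            assert ext[k] == pytest.approx(e, abs=1e-10)
            assert epi[k] == pytest.approx(i, abs=1e-10)


class TestPolicyPosteriorAndPrecision:
    def test_single_policy(self):
        np.testing.assert_allclose(
            engine.update_policy_posterior(np.array([-3.0]), 2.0), [1.0]
        )

    def test_equal_qualities_uniform(self):
        out = engine.update_policy_posterior(np.full(5, -2.0), 10.0)
        np.testing.assert_allclose(out, 0.2, atol=1e-12)

    def test_hand_computed_softmax(self):
        out = engine.update_policy_posterior(np.array([-1.0, -2.0]), 2.0)
        e = np.exp([-2.0, -4.0])
        np.testing.assert_allclose(out, e / e.sum(), atol=1e-4)
        assert out[0] == pytest.approx(0.8808, abs=1e-4)

    def test_shift_invariance(self, rng):
        q = rng.normal(size=6)
        a = engine.update_policy_posterior(q, 3.0)
        b = engine.update_policy_posterior(q + 17.3, 3.0)
        np.testing.assert_allclose(a, b, atol=1e-12)

    @pytest.mark.parametrize(
        "qdot,expected", [(0.0, 250.0), (-1.0, 125.0), (-9.0, 25.0)]
    )
    def test_precision_reference_values(self, qdot, expected):
        out = engine.update_precision(
            250.0, 1.0, np.array([qdot]), np.array([1.0])
        )
        assert out == pytest.approx(expected)

    def test_precision_divergence_raises(self):
        with pytest.raises(PrecisionDivergenceError):
            engine.update_precision(250.0, 1.0, np.array([2.0]), np.array([1.0]))


class TestVariationalStep:
    def test_fixed_point_stable(self, perfect_intero):
        process, model = perfect_intero
        exps = engine.compute_expectations(model)
        belief = BeliefState(precision=model.precision_shape / model.precision_rate)
        policies = engine.enumerate_policies(3, 1, 4)
        for _ in range(60):
            engine.variational_step(
                model, 14, 1, belief, policies=policies, expectations=exps
            )
        before = (
            belief.state_beliefs[0].copy(),
            belief.policy_beliefs.copy(),
            belief.precision,
        )
        engine.variational_step(
            model, 14, 1, belief, policies=policies, expectations=exps
        )
        np.testing.assert_allclose(belief.state_beliefs[0], before[0], atol=1e-9)
        np.testing.assert_allclose(belief.policy_beliefs, before[1], atol=1e-9)
        assert belief.precision == pytest.approx(before[2], abs=1e-9)

    def test_four_sweeps_near_converged(self, perfect_intero):
        process, model = perfect_intero

        def run(n):
            b = BeliefState(precision=model.precision_shape / model.precision_rate)
            policies = engine.enumerate_policies(3, 1, 4)
            exps = engine.compute_expectations(model)
            for _ in range(n):
                engine.variational_step(
                    model, 14, 1, b, policies=policies, expectations=exps
                )
            return b

        b4, b100 = run(4), run(100)
        np.testing.assert_allclose(
            b4.policy_beliefs, b100.policy_beliefs, atol=1e-6
        )
        assert b4.precision == pytest.approx(b100.precision, abs=1e-6 * b100.precision)

    def test_quality_decomposition_holds_after_sweep(self, perfect_intero):
        _, model = perfect_intero
        belief = BeliefState(precision=250.0)
        engine.variational_step(model, 14, 1, belief)
        np.testing.assert_allclose(
            belief.quality, belief.extrinsic + belief.epistemic, atol=1e-9
        )
        assert np.all(belief.epistemic >= -1e-12)
        assert np.all(belief.extrinsic <= 1e-12)


class TestActionSelection:
    def test_singleton_policies_pass_through(self):
        ps = engine.enumerate_policies(3, 4, 4)
        pi = np.array([0.2, 0.5, 0.3])
        np.testing.assert_allclose(engine.action_posterior(pi, ps), pi)

    def test_uniform_policies_uniform_actions(self):
        ps = engine.enumerate_policies(3, 1, 4, decisions_per_episode=3)
        out = engine.action_posterior(np.full(27, 1 / 27), ps)
        np.testing.assert_allclose(out, 1 / 3, atol=1e-12)

    def test_first_action_marginalisation(self):
        ps = engine.PolicySet(
            policies=np.array([[0], [0], [2]]), num_actions=3
        )
        out = engine.action_posterior(np.array([0.5, 0.3, 0.2]), ps)
        np.testing.assert_allclose(out, [0.8, 0.0, 0.2], atol=1e-12)

    def test_degenerate_distribution(self, rng):
        assert engine.sample_action(np.array([0.0, 1.0, 0.0]), rng) == 1

    def test_seeded_reproducibility(self):
        p = np.array([0.3, 0.3, 0.4])
        draws1 = [engine.sample_action(p, np.random.default_rng(5)) for _ in range(1)]
        rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
        seq1 = [engine.sample_action(p, rng1) for _ in range(50)]
        seq2 = [engine.sample_action(p, rng2) for _ in range(50)]
        assert seq1 == seq2

    def test_law_of_large_numbers(self):
        rng = np.random.default_rng(17)
        p = np.array([0.8, 0.0, 0.2])
        draws = np.array([engine.sample_action(p, rng) for _ in range(100_000)])
        freq = np.bincount(draws, minlength=3) / draws.size
        np.testing.assert_allclose(freq, p, atol=0.01)


class TestLearning:
    @pytest.fixture
    def episode(self, config):
        process = builders.build_interoceptive_process(config)
        model = builders.build_uninformative_model(config)
        rng = np.random.default_rng(2)
        return model, engine.run_episode(model, process, rng)

    def test_disabled_flags_leave_model_unchanged(self, episode):
        model, rec = episode
        frozen = model.copy()
        frozen.learn_likelihood = False
        frozen.learn_transitions = False
        frozen.learn_initial = False
        out = engine.learn_from_episode(frozen, rec)
        np.testing.assert_array_equal(
            out.posteriors.transitions, frozen.posteriors.transitions
        )
        np.testing.assert_array_equal(
            out.posteriors.likelihood, frozen.posteriors.likelihood
        )
        np.testing.assert_array_equal(out.posteriors.initial, frozen.posteriors.initial)

    def test_dirichlet_mass_conservation(self, episode):
        model, rec = episode
        out = engine.learn_from_episode(model, rec)
        d_trans = out.posteriors.transitions - model.posteriors.transitions
        # each outer product of two normalised beliefs adds total mass 1
        assert d_trans.sum() == pytest.approx(model.horizon - 1, abs=1e-9)
        d_init = out.posteriors.initial - model.posteriors.initial
        assert d_init.sum() == pytest.approx(1.0, abs=1e-12)

    def test_likelihood_mass_when_enabled(self, episode):
        model, rec = episode
        m = model.copy()
        m.learn_likelihood = True
        out = engine.learn_from_episode(m, rec)
        d = out.posteriors.likelihood - m.posteriors.likelihood
        assert d.sum() == pytest.approx(m.horizon, abs=1e-9)

    def test_original_untouched_without_inplace(self, episode):
        model, rec = episode
        before = model.posteriors.transitions.copy()
        engine.learn_from_episode(model, rec)
        np.testing.assert_array_equal(model.posteriors.transitions, before)


class TestEpisodes:
    def test_bit_identical_records_same_seed(self, perfect_intero):
        process, model = perfect_intero
        r1 = engine.run_episode(model, process, np.random.default_rng(42))
        r2 = engine.run_episode(model, process, np.random.default_rng(42))
        np.testing.assert_array_equal(r1.observations, r2.observations)
        np.testing.assert_array_equal(r1.actions, r2.actions)
        np.testing.assert_array_equal(r1.true_states, r2.true_states)
        np.testing.assert_array_equal(r1.state_beliefs, r2.state_beliefs)

    def test_record_shapes_follow_conventions(self, perfect_intero):
        process, model = perfect_intero
        rec = engine.run_episode(model, process, np.random.default_rng(0))
        T, D = model.horizon, model.decisions_per_episode
        assert len(rec.observations) == T
        assert len(rec.actions) == D
        assert rec.state_beliefs.shape == (T, model.num_states)
        assert rec.final_efe.shape == (model.num_actions, 3)

    def test_record_flattens_to_one_row_per_step(self, perfect_intero):
        process, model = perfect_intero
        rec = engine.run_episode(model, process, np.random.default_rng(0))
        frame = rec.to_frame()
        assert len(frame) == model.horizon
        for col in ("step", "observation", "true_state", "action", "precision"):
            assert col in frame.columns

    @pytest.mark.parametrize(
        "q,expected_action",
        [(0.9, builders.SEEK), (0.1, builders.AVOID)],
    )
    def test_perfect_model_modal_action(self, q, expected_action):
        cfg = AttachmentConfig(q=q)
        process = builders.build_interoceptive_process(cfg)
        model = builders.build_perfect_model(process, cfg)
        exps = engine.compute_expectations(model)
        counts = np.zeros(3)
        for r in range(100):
            rec = engine.run_episode(
                model, process, np.random.default_rng(r), expectations=exps
            )
            counts += np.bincount(rec.actions, minlength=3)
        assert counts.argmax() == expected_action

    def test_single_iteration_equals_composition(self, config):
        process = builders.build_interoceptive_process(config)
        model = builders.build_uninformative_model(config)
        recs, learned = engine.run_learning(
            model, process, 1, np.random.default_rng(6)
        )
        rec = engine.run_episode(model, process, np.random.default_rng(6))
        composed = engine.learn_from_episode(model, rec)
        np.testing.assert_array_equal(rec.actions, recs[0].actions)
        np.testing.assert_allclose(
            learned.posteriors.transitions, composed.posteriors.transitions
        )

    def test_transition_parameter_recovery(self):
        # the learned Seek kernel should recover the true responsiveness
        cfg = AttachmentConfig(q=0.9)
        process = builders.build_interoceptive_process(cfg)
        model = builders.build_uninformative_model(cfg)
        _, learned = engine.run_learning(
            model, process, 500, np.random.default_rng(0), keep_records=False
        )
        added = (
            learned.posteriors.transitions[builders.SEEK]
            - model.posteriors.transitions[builders.SEEK]
        )
        q_hat = added[2 * builders.SEEK].sum() / added.sum()
        assert q_hat == pytest.approx(0.9, abs=0.05)
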