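"""Engine unit tests: perception, free energies, decision and learning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sociometer.engine import (
    Categorical,
    DirichletStore,
    LikelihoodModel,
    TransitionModel,
    compute_efe,
    compute_vfe,
    compute_vfe_joint,
    enumerate_policies,
    expected_model,
    infer_states,
    policy_posterior,
    prune_policies,
    select_action,
    softmax,
    update_dirichlet,
)
from sociometer.validation import efe_direct, enumerate_posterior, random_model


# ---------------------------------------------------------------------------
# softmax and Categorical
# ---------------------------------------------------------------------------


class TestSoftmax:
    def test_uniform_logits(self):
        np.testing.assert_allclose(softmax([0.0, 0.0, 0.0]), np.full(3, 1 / 3))

    def test_shift_invariance(self):
        base = softmax([0.0, 0.7, 1.4])
        for shift in (-100.0, -3.2, 5.0, 1e4):
            np.testing.assert_allclose(softmax(np.array([0.0, 0.7, 1.4]) + shift), base, atol=1e-12)

    def test_direct_exponentiation(self):
        # exp-normalisation of [ln 1, ln 2, ln 3] is [1/6, 2/6, 3/6]
        np.testing.assert_allclose(
            softmax(np.log([1.0, 2.0, 3.0])), np.array([1, 2, 3]) / 6, atol=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            softmax([])

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8))
    @settings(max_examples=200, derandomize=True)
    def test_output_is_categorical(self, logits):
        Categorical(softmax(logits))  # validates non-negativity and unit sum


class TestCategorical:
    @pytest.mark.parametrize("bad", [[0.5, 0.4], [-0.1, 1.1], [], [0.5, np.nan, 0.5]])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            Categorical(np.asarray(bad, dtype=float))

    def test_entropy_uniform(self):
        assert Categorical(np.full(4, 0.25)).entropy() == pytest.approx(np.log(4), abs=1e-9)


# ---------------------------------------------------------------------------
# Perception
# ---------------------------------------------------------------------------


class TestInferStates:
    def test_noiseless_likelihood_pins_state(self, make_tiny_model):
        m = make_tiny_model(np.eye(3), np.full((3, 3), 1 / 3), np.zeros(3), np.full(3, 1 / 3), 2)
        res = infer_states(m, m.policies[0], [2])
        assert res.converged
        assert np.argmax(res.beliefs[0]) == 2
        assert res.beliefs[0][2] > 1 - 1e-9

    def test_uninformative_likelihood_gives_prior_chain(self, make_tiny_model):
        B = np.array([[0.7, 0.2], [0.3, 0.8]])
        D = np.array([0.6, 0.4])
        m = make_tiny_model(np.full((2, 2), 0.5), B, np.zeros(2), D, 3)
        res = infer_states(m, m.policies[0], [0, 1, 0])
        chain = [D, B @ D, B @ (B @ D)]
        for b, c in zip(res.beliefs, chain):
            np.testing.assert_allclose(b, c, atol=1e-8)

    def test_deterministic_model_recovers_true_sequence(self, rng):
        # with a noiseless likelihood and observations at every timestep the
        # inferred MAP sequence equals the generating sequence exactly
        for _ in range(20):
            m = random_model(rng, n_states=3, n_obs=3, horizon=3)
            m.A = LikelihoodModel(np.eye(3))
            pol = m.policies[rng.integers(m.n_policies)]
            states = [int(rng.choice(3, p=m.D))]
            for u in pol:
                states.append(int(rng.choice(3, p=m.B.tables[:, states[-1], u])))
            res = infer_states(m, pol, states)
            assert [int(np.argmax(b)) for b in res.beliefs] == states

    def test_matches_enumeration_with_partial_observations(self, rng):
        worst = 0.0
        for _ in range(50):
            T = int(rng.integers(2, 4))
            m = random_model(rng, horizon=T)
            pol = m.policies[rng.integers(m.n_policies)]
            obs = [int(rng.integers(m.n_obs)) for _ in range(int(rng.integers(1, T + 1)))]
            exact = enumerate_posterior(m, pol, obs)
            res = infer_states(m, pol, obs)
            worst = max(
                worst,
                max(0.5 * np.abs(b - e).sum() for b, e in zip(res.beliefs, exact.marginals)),
            )
        assert worst <= 0.05

    def test_too_many_observations_rejected(self, make_tiny_model):
        m = make_tiny_model(np.eye(2), np.eye(2), np.zeros(2), [0.5, 0.5], 2)
        with pytest.raises(ValueError):
            infer_states(m, m.policies[0], [0, 1, 0])


# ---------------------------------------------------------------------------
# Variational free energy
# ---------------------------------------------------------------------------


class TestVFE:
    def test_joint_at_exact_posterior_is_neg_log_evidence(self, rng):
        for _ in range(20):
            T = int(rng.integers(2, 4))
            m = random_model(rng, horizon=T)
            pol = m.policies[rng.integers(m.n_policies)]
            obs = [int(rng.integers(m.n_obs)) for _ in range(T)]
            exact = enumerate_posterior(m, pol, obs)
            vfe = compute_vfe_joint(m, pol, exact.joint, obs)
            assert vfe.total == pytest.approx(-exact.log_evidence, abs=1e-8)

    def test_deterministic_agreement_gives_zero(self, make_tiny_model):
        # prior, likelihood and beliefs all put probability 1 on one path
        m = make_tiny_model(np.eye(2), np.eye(2), np.zeros(2), [1.0, 0.0], 2)
        beliefs = [np.array([1.0, 0.0]), np.array([1.0, 0.0])]
        vfe = compute_vfe(m, m.policies[0], beliefs, [0, 0])
        assert vfe.total == pytest.approx(0.0, abs=1e-9)
        assert vfe.complexity == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("K", [2, 3, 5])
    def test_uninformative_likelihood_costs_log_k(self, K, make_tiny_model):
        # beliefs equal to the prior, uniform A over K outcomes, one observation
        # (uniform B keeps the prior chain uncorrelated, so complexity is 0)
        m = make_tiny_model(np.full((K, 2), 1 / K), np.full((2, 2), 0.5), np.zeros(K), [0.5, 0.5], 2)
        beliefs = [np.array([0.5, 0.5]), np.array([0.5, 0.5])]
        vfe = compute_vfe(m, m.policies[0], beliefs, [0])
        assert vfe.total == pytest.approx(np.log(K), abs=1e-9)


# ---------------------------------------------------------------------------
# Expected free energy
# ---------------------------------------------------------------------------


class TestEFE:
    def test_matched_preferences_zero(self, make_tiny_model):
        # deterministic A (zero ambiguity) and predicted outcomes equal to
        # the normalised preference distribution: G vanishes
        B = np.array([[0.3, 0.3], [0.7, 0.7]])
        m = make_tiny_model(np.eye(2), B, np.zeros(2), [0.5, 0.5], 2)
        res = infer_states(m, m.policies[0], [0])
        o_pred = m.A.table @ res.beliefs[1]
        m2 = make_tiny_model(np.eye(2), B, np.log(o_pred), [0.5, 0.5], 2)
        efe = compute_efe(m2, m2.policies[0], res.beliefs)
        assert abs(efe.total) < 1e-9
        assert abs(efe.risk).max() < 1e-9 and abs(efe.ambiguity).max() < 1e-9

    @pytest.mark.parametrize("K", [2, 4])
    def test_uniform_likelihood_ambiguity_is_log_k(self, K, make_tiny_model):
        m = make_tiny_model(np.full((K, 3), 1 / K), np.full((3, 3), 1 / 3),
                            np.zeros(K), np.full(3, 1 / 3), 2)
        for belief in (np.array([1.0, 0.0, 0.0]), np.full(3, 1 / 3), np.array([0.2, 0.5, 0.3])):
            efe = compute_efe(m, m.policies[0], [belief, belief])
            assert efe.ambiguity[0] == pytest.approx(np.log(K), abs=1e-9)

    def test_dual_route_agreement(self, rng):
        worst = 0.0
        for _ in range(50):
            T = int(rng.integers(2, 4))
            m = random_model(rng, n_states=3, n_obs=3, horizon=T)
            pol = m.policies[rng.integers(m.n_policies)]
            res = infer_states(m, pol, [int(rng.integers(3))])
            efe = compute_efe(m, pol, res.beliefs, n_observed=1)
            worst = max(worst, abs(efe.total - efe_direct(m, pol, res.beliefs, n_observed=1)))
        assert worst <= 1e-8


# ---------------------------------------------------------------------------
# Decision
# ---------------------------------------------------------------------------


class TestPolicyPosterior:
    def test_habit_only_limit(self, rng):
        for _ in range(20):
            m = random_model(rng, n_actions=3, horizon=2)
            post = policy_posterior(m, 0.0, rng.normal(size=m.n_policies), 0.0)
            np.testing.assert_allclose(post.probs, m.E, atol=1e-12)

    def test_symmetry_gives_uniform(self, make_tiny_model):
        m = make_tiny_model(np.eye(2), np.stack([np.eye(2)] * 3, axis=2),
                            np.zeros(2), [0.5, 0.5], 2)
        post = policy_posterior(m, np.full(3, 1.7), np.full(3, 0.4), 2.0)
        np.testing.assert_allclose(post.probs, np.full(3, 1 / 3), atol=1e-12)

    def test_hand_computation(self, make_tiny_model):
        m = make_tiny_model(np.eye(2), np.stack([np.eye(2)] * 3, axis=2),
                            np.zeros(2), [0.5, 0.5], 2, E=[0.5, 0.25, 0.25])
        G = np.array([1.0, 2.0, 3.0])
        post = policy_posterior(m, 0.0, G, 1.0)
        w = np.array([0.5, 0.25, 0.25]) * np.exp(-G)  # direct exponentiation
        np.testing.assert_allclose(post.probs, w / w.sum(), atol=1e-10)


class TestSelectAction:
    def test_one_hot_posterior(self, rng):
        policies = np.array([[0], [1], [2]])
        for mode in ("map", "sample"):
            assert select_action(np.array([0.0, 1.0, 0.0]), policies, mode=mode, rng=rng) == 1

    def test_shared_first_action_marginalises(self, rng):
        policies = np.array([[2, 0], [2, 1]])
        assert select_action(np.array([0.4, 0.6]), policies, mode="sample", rng=rng) == 2

    def test_sampling_frequency(self):
        rng = np.random.default_rng(7)
        policies = np.array([[0], [1]])
        p = np.array([0.7, 0.3])
        draws = [select_action(p, policies, mode="sample", rng=rng) for _ in range(10_000)]
        assert np.mean(np.asarray(draws) == 0) == pytest.approx(0.7, abs=0.02)

    def test_argmax_tie_breaks_low(self):
        policies = np.array([[1], [0]])
        assert select_action(np.array([0.5, 0.5]), policies, mode="map") == 0


# ---------------------------------------------------------------------------
# Learning
# ---------------------------------------------------------------------------


def _store(S=2, O=2, U=2):
    return DirichletStore(
        a=np.full((O, S), 0.5), b=np.full((S, S, U), 0.5), d=np.full(S, 0.5), e=np.full(3, 0.5)
    )


class TestDirichlet:
    def test_one_hot_counting(self):
        store = _store()
        beliefs = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
        out = update_dirichlet(store, beliefs, [0, 1], [1], policy_posterior=np.array([1.0, 0, 0]))
        assert out.a[0, 0] == 1.5 and out.a[1, 1] == 1.5
        assert out.b[1, 0, 1] == 1.5 and out.b[1, 0, 0] == 0.5
        assert out.d[0] == 1.5
        assert out.e[0] == 1.5
        # input untouched
        assert store.a[0, 0] == 0.5

    def test_learning_rate_validation_and_linearity(self):
        store = _store()
        beliefs = [np.array([1.0, 0.0]), np.array([1.0, 0.0])]
        with pytest.raises(ValueError):
            update_dirichlet(store, beliefs, [0], [0], learning_rate=0.0)
        half = update_dirichlet(store, beliefs, [0], [0], learning_rate=0.5)
        assert half.d[0] == 1.0  # half a count added

    def test_transition_frequency_convergence(self, rng):
        # repeated identical trials: the normalised column approaches the
        # empirical transition frequency at rate 1/N
        store = _store()
        belief_pairs = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
        N = 200
        for _ in range(N):
            store = update_dirichlet(store, belief_pairs, [0, 1], [0])
        col = expected_model(store).B.tables[:, 0, 0]
        assert abs(col[1] - 1.0) <= 1 / N + 0.01

    def test_concentrations_stay_positive(self):
        with pytest.raises(ValueError):
            DirichletStore(a=np.zeros((2, 2)), b=np.ones((2, 2, 1)), d=np.ones(2), e=np.ones(1))


class TestExpectedModel:
    def test_equal_concentrations_give_uniform(self):
        em = expected_model(_store())
        np.testing.assert_allclose(em.A.table, 0.5)
        np.testing.assert_allclose(em.D, 0.5)

    def test_normalisation(self):
        store = _store()
        store.d = np.array([9.0, 1.0])
        np.testing.assert_allclose(expected_model(store).D, [0.9, 0.1])

    def test_monotone_shift_toward_evidence(self):
        store = _store()
        beliefs = [np.array([1.0, 0.0]), np.array([1.0, 0.0])]
        prev = expected_model(store).D[0]
        for _ in range(100):
            store = update_dirichlet(store, beliefs, [0, 0], [0])
            cur = expected_model(store).D[0]
            assert cur > prev
            prev = cur


class TestPolicies:
    def test_enumeration_is_exhaustive(self):
        pols = enumerate_policies(2, 3)
        assert pols.shape == (4, 2)
        assert len({tuple(p) for p in pols}) == 4

    def test_pruning_by_habit_mass(self):
        pols = enumerate_policies(2, 2)
        kept, E = prune_policies(pols, np.array([1e-9, 1.0]))
        assert kept.shape[0] == 1 and E[0] == 1.0
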