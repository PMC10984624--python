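"""Two-level self-esteem model: builders, trait link, summaries, agent loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sociometer.engine import TransitionModel
from sociometer.esteem import (
    ACTIONS,
    TRAITS,
    HierarchicalAgent,
    StateLevelSpec,
    TraitLevelSpec,
    TraitLink,
    build_state_level,
    build_trait_level,
    apply_trait_modulation,
    run_agent,
    self_image_marginal,
    summarize_trial,
    trait_step,
)
from sociometer.niche import NicheConfig, make_scenario


class TestBuildStateLevel:
    def test_noiseless_feedback_is_deterministic(self):
        m = build_state_level(StateLevelSpec(), reliability=1.0)
        assert np.all(np.max(m.A.table, axis=0) == 1.0)
        assert np.all(m.A.ambiguity < 1e-12)

    def test_binary_reduction_at_half_reliability_is_uninformative(self):
        m = build_state_level(StateLevelSpec(n_feedback=2), reliability=0.5)
        np.testing.assert_allclose(m.A.table, 0.5, atol=1e-12)
        np.testing.assert_allclose(m.A.ambiguity, np.log(2), atol=1e-9)

    @pytest.mark.parametrize("bad", [0.4, 1.01])
    def test_reliability_range_enforced(self, bad):
        with pytest.raises(ValueError):
            build_state_level(StateLevelSpec(), reliability=bad)

    @pytest.mark.parametrize("collapse", [False, True])
    def test_joint_flattening_is_consistent(self, collapse):
        spec = StateLevelSpec(collapse_ideal=collapse)
        m = build_state_level(spec)
        assert m.n_states == int(np.prod(spec.factor_shape))
        assert m.n_actions == len(ACTIONS)
        # the model passes all engine validators by construction; marginals sum to 1
        np.testing.assert_allclose(self_image_marginal(m.D, m).sum(), 1.0, atol=1e-12)


class TestTraitModulation:
    def test_identity_at_one(self):
        B = build_state_level(StateLevelSpec()).B
        np.testing.assert_allclose(apply_trait_modulation(B, 1.0).tables, B.tables, atol=1e-12)

    def test_hand_computation(self):
        B = TransitionModel(np.array([[0.8, 0.2], [0.2, 0.8]])[:, :, None])
        out = apply_trait_modulation(B, 2.0).tables[:, 0, 0]
        np.testing.assert_allclose(out, [0.64 / 0.68, 0.04 / 0.68], atol=1e-12)

    def test_flattening_limit(self):
        B = TransitionModel(np.array([[0.8, 0.2], [0.2, 0.8]])[:, :, None])
        out = apply_trait_modulation(B, 1e-3).tables[:, 0, 0]
        assert np.max(np.abs(out - 0.5)) < 5e-4

    @given(st.integers(0, 5000), st.floats(0.1, 5.0))
    @settings(max_examples=150, derandomize=True)
    def test_stochasticity_and_permutation_commute(self, seed, omega):
        rng = np.random.default_rng(seed)
        tables = rng.dirichlet(np.ones(4), size=(4, 2)).transpose(2, 0, 1)
        B = TransitionModel(tables)
        out = apply_trait_modulation(B, omega)
        np.testing.assert_allclose(out.tables.sum(axis=0), 1.0, atol=1e-12)
        perm = rng.permutation(4)
        permuted = TransitionModel(tables[np.ix_(perm, perm)])
        np.testing.assert_allclose(
            apply_trait_modulation(permuted, omega).tables,
            out.tables[np.ix_(perm, perm)],
            atol=1e-12,
        )

    def test_nonpositive_omega_rejected(self):
        B = build_state_level(StateLevelSpec()).B
        with pytest.raises(ValueError):
            apply_trait_modulation(B, 0.0)


class TestTraitLink:
    def test_omega_ordering_enforced(self):
        with pytest.raises(ValueError):
            TraitLink(omega={"low": 2.0, "medium": 1.0, "high": 0.5})

    def test_neutral_link_is_flat(self):
        link = TraitLink.neutral()
        assert set(link.omega.values()) == {1.0} and set(link.gamma0.values()) == {1.0}


class TestSummaries:
    def test_positive_trace(self):
        v, b, flat = summarize_trial([0.2, 0.3, 0.1], np.array([0.1, 0.2, 0.7]))
        assert v == 2 and b == 2 and flat == 2 * 3 + 2

    def test_balanced_trace_is_neutral(self):
        v, _, _ = summarize_trial([0.5, -0.5], np.array([1.0, 0.0, 0.0]))
        assert v == 1

    def test_argmax_binning(self):
        _, b, _ = summarize_trial([0.0], np.array([0.1, 0.2, 0.7]))
        assert b == 2
        _, b5, _ = summarize_trial([0.0], np.array([0.1, 0.5, 0.2, 0.1, 0.1]))
        assert b5 == 0  # level 1 of 5 coarsens into the lowest of 3 bins


class TestTraitStep:
    def _agent(self):
        return HierarchicalAgent.build(trait_spec=TraitLevelSpec(slow_horizon=10))

    def test_degenerate_prior_pins_map_trait(self):
        agent = self._agent()
        prior = np.zeros(9)
        prior[2 * 3 + 2] = 1.0  # trait high, valence positive
        agent.upper_prior = prior
        info = trait_step(agent, [2 * 3 + 2] * 10)
        assert info["map_trait"] == "high"
        assert agent.link.omega["high"] == info["omega"]

    def test_balanced_evidence_has_reflection_symmetry(self):
        # the upper model is exactly symmetric under reversing both the trait
        # and valence axes, so mirrored summary blocks must give
        # mirror-image trait posteriors, and averaging a block with its
        # mirror shows no systematic high-vs-low drift
        summaries = [2 * 3 + 2, 0 * 3 + 0] * 5  # alternate positive/top, negative/bottom
        mirrored = [0 * 3 + 0, 2 * 3 + 2] * 5
        agent_a, agent_b = self._agent(), self._agent()
        for _ in range(3):
            trait_step(agent_a, summaries)
            trait_step(agent_b, mirrored)
        post_a, post_b = agent_a.trait_posterior(), agent_b.trait_posterior()
        np.testing.assert_allclose(post_a, post_b[::-1], atol=1e-8)
        assert abs((post_a + post_b)[2] - (post_a + post_b)[0]) < 1e-8

    def test_consistent_positive_evidence_raises_high(self):
        agent = self._agent()
        for _ in range(5):  # 50 positive/top-bin summaries in all
            trait_step(agent, [2 * 3 + 2] * 10)
        post = agent.trait_posterior()
        assert post[TRAITS.index("high")] > post[TRAITS.index("low")]

    def test_wrong_block_length_rejected(self):
        with pytest.raises(ValueError):
            trait_step(self._agent(), [0] * 3)


class TestRunAgent:
    def test_zero_trials(self):
        agent = HierarchicalAgent.build()
        res = run_agent(agent, make_scenario("favorable"), 0, seed=0)
        assert res.records == [] and res.trait_steps == []
        assert agent.trial_count == 0  # input untouched

    def test_fixed_seed_is_bit_identical(self):
        agent = HierarchicalAgent.build()
        runs = [run_agent(agent, make_scenario("shifting"), 60, seed=9) for _ in range(2)]
        assert all(a.to_dict() == b.to_dict() for a, b in zip(*[r.records for r in runs]))
        assert runs[0].trait_steps == runs[1].trait_steps

    def test_preference_seeking(self):
        cfg = NicheConfig(approval_given_action=(0.9, 0.5, 0.1), kappa=1.0, base_rate=0.5)
        res = run_agent(HierarchicalAgent.build(), cfg, 300, seed=0)
        acts = res.actions()[100:]
        engage = np.mean(acts == ACTIONS.index("engage"))
        withdraw = np.mean(acts == ACTIONS.index("withdraw"))
        assert engage > withdraw

    def test_nesting_conservation(self):
        agent = HierarchicalAgent.build(trait_spec=TraitLevelSpec(slow_horizon=10))
        res = run_agent(agent, make_scenario("favorable"), 70, seed=1)
        assert res.agent.trial_count == 70
        assert len(res.trait_steps) == 70 // 10
        assert len(res.records) == 70 * agent.state_spec.horizon

    def test_alphabet_mismatch_rejected(self):
        agent = HierarchicalAgent.build(StateLevelSpec(n_feedback=2))
        with pytest.raises(ValueError):
            run_agent(agent, make_scenario("favorable"), 5, seed=0)  # 3-outcome niche

    def test_trait_hysteresis(self):
        # 300 trials at 90% approval then 50 trials at 50%: the slow trait
        # belief in "high" must stay above its time-zero prior of 1/3
        cfg = NicheConfig(
            approval_given_action=(0.9, 0.9, 0.9), kappa=1.0, base_rate=0.9,
            schedule=((300, dict(approval_given_action=(0.5, 0.5, 0.5), base_rate=0.5)),),
        )
        agent = HierarchicalAgent.build()
        start = agent.trait_posterior()[TRAITS.index("high")]
        res = run_agent(agent, cfg, 350, seed=4)
        end = res.agent.trait_posterior()[TRAITS.index("high")]
        assert start == pytest.approx(1 / 3, abs=1e-9)
        assert end > start


class TestBuildTraitLevel:
    def test_shapes_and_alphabet(self):
        m = build_trait_level(TraitLevelSpec(slow_horizon=10))
        assert m.n_states == 9 and m.n_obs == 9
        assert m.n_policies == 1 and m.horizon == 10
        # summariser output indices all fall inside the upper alphabet
        _, _, flat = summarize_trial([1.0], np.array([0.0, 0.0, 1.0]))
        assert 0 <= flat < m.n_obs
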