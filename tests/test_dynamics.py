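import numpy as np
import pytest

from actinet import (
    EXCITED,
    REFRACTORY,
    RESTING,
    AutomatonConfig,
    activity_profile,
    evolve,
    excitation_ratio,
    excitation_ratios,
    resting_state,
    step,
)

from conftest import hand_graph, make_graph


@pytest.fixture
def star_graph():
    # node 0: hard {1, 2}, soft {3, ..., 12}  -> |u| = 2, |w| = 10
    hard = [(0, 1), (0, 2)]
    soft = [(0, j) for j in range(3, 13)]
    return hand_graph(13, hard, soft)


class TestExcitationRatio:
    def test_no_excited_neighbours(self, star_graph):
        state = resting_state(13)
        assert excitation_ratio(0, state, star_graph, 0.9) == 0.0

    def test_weighted_mixed_counts(self, star_graph):
        state = resting_state(13)
        state[1] = EXCITED
        state[3] = EXCITED
        state[4] = EXCITED
        assert excitation_ratio(0, state, star_graph, 0.9) == pytest.approx(
            (1 + 0.9 * 2) / 12
        )

    def test_all_excited(self):
        g = hand_graph(11, [(0, 1), (0, 2)], [(0, j) for j in range(3, 11)])
        state = np.full(11, EXCITED, dtype=np.uint8)
        assert excitation_ratio(0, state, g, 0.9) == pytest.approx((2 + 7.2) / 10)

    def test_isolated_node_ratio_zero(self):
        g = make_graph([[0, 0, 0], [50, 0, 0]], rho=1.0)
        state = np.array([RESTING, EXCITED], dtype=np.uint8)
        assert excitation_ratio(0, state, g, 0.9) == 0.0

    def test_vectorised_matches_per_node(self, small_filament):
        _, g = small_filament
        rng = np.random.default_rng(2)
        state = rng.integers(0, 2, g.n_nodes).astype(np.uint8)
        gammas = excitation_ratios(state, g, 0.9)
        for node in rng.integers(0, g.n_nodes, 40):
            assert gammas[node] == pytest.approx(
                excitation_ratio(int(node), state, g, 0.9)
            )


class TestRuleG:
    def cfg(self):
        return AutomatonConfig.rule_g()

    def make(self, gamma_target):
        # node 0 has 8 soft neighbours; excite k to get gamma = 0.9 * k / 8
        g = hand_graph(9, [], [(0, j) for j in range(1, 9)])
        return g

    @pytest.mark.parametrize(
        "n_excited,expected",
        [
            (0, RESTING),  # gamma 0
            (3, EXCITED),  # gamma 0.3375 inside [0.25, 0.375]
            (4, RESTING),  # gamma 0.45 above the interval
        ],
    )
    def test_resting_birth_interval(self, n_excited, expected):
        g = self.make(None)
        state = resting_state(9)
        state[1 : 1 + n_excited] = EXCITED
        assert step(state, g, self.cfg())[0] == expected

    def test_boundary_inclusive(self):
        # node 0: hard {1}, soft {2, 3, 4}; one excited hard neighbour
        # -> gamma = 1/4 = 0.25 exactly (lower bound, must excite)
        g = hand_graph(5, [(0, 1)], [(0, 2), (0, 3), (0, 4)])
        state = resting_state(5)
        state[1] = EXCITED
        assert step(state, g, self.cfg())[0] == EXCITED

    def test_excited_survival_and_death(self):
        g = self.make(None)
        state = resting_state(9)
        state[0] = EXCITED
        state[1:4] = EXCITED  # gamma 0.3375 in survival interval
        assert step(state, g, self.cfg())[0] == EXCITED
        state[4] = EXCITED  # gamma 0.45 outside
        assert step(state, g, self.cfg())[0] == RESTING

    def test_refractory_state_rejected(self):
        g = self.make(None)
        state = resting_state(9)
        state[0] = REFRACTORY
        with pytest.raises(ValueError):
            step(state, g, self.cfg())


class TestRuleE:
    def cfg(self):
        return AutomatonConfig.rule_e()

    def test_excited_becomes_refractory_any_gamma(self):
        g = hand_graph(5, [], [(0, j) for j in range(1, 5)])
        for k in (0, 4):
            state = resting_state(5)
            state[0] = EXCITED
            state[1 : 1 + k] = EXCITED
            assert step(state, g, self.cfg())[0] == REFRACTORY

    def test_refractory_becomes_resting(self):
        g = hand_graph(3, [], [(0, 1), (0, 2)])
        state = np.array([REFRACTORY, EXCITED, EXCITED], dtype=np.uint8)
        assert step(state, g, self.cfg())[0] == RESTING

    def test_resting_excites_in_interval(self):
        # node 0 with 5 soft neighbours: 1 excited -> gamma = 0.18 in [0.15, 0.25]
        g = hand_graph(6, [], [(0, j) for j in range(1, 6)])
        state = resting_state(6)
        state[1] = EXCITED
        assert step(state, g, self.cfg())[0] == EXCITED

    def test_three_state_cycle(self):
        # single excited node below everyone's excitation threshold
        g = make_graph([[0, 0, 0], [50, 0, 0]], rho=1.0)
        state = np.array([EXCITED, RESTING], dtype=np.uint8)
        s1 = step(state, g, self.cfg())
        s2 = step(s1, g, self.cfg())
        assert s1[0] == REFRACTORY
        assert s2[0] == RESTING

    def test_refractory_conservation(self, small_filament):
        _, g = small_filament
        rng = np.random.default_rng(5)
        state = rng.integers(0, 3, g.n_nodes).astype(np.uint8)
        after = step(state, g, self.cfg())
        assert np.count_nonzero(after == REFRACTORY) == np.count_nonzero(
            state == EXCITED
        )
        assert np.all(state[after == EXCITED] == RESTING)


class TestEvolve:
    def test_zero_steps_identity(self, small_filament):
        _, g = small_filament
        rng = np.random.default_rng(0)
        state = rng.integers(0, 2, g.n_nodes).astype(np.uint8)
        np.testing.assert_array_equal(
            evolve(state, g, AutomatonConfig.rule_g(), 0), state
        )

    def test_edgeless_graph_dies_in_one_step(self):
        coords = [[40 * i, 0, 0] for i in range(6)]
        g = make_graph(coords, rho=1.0)
        state = np.ones(6, dtype=np.uint8)
        after = evolve(state, g, AutomatonConfig.rule_g(), 1)
        assert not after.any()

    def test_step_is_pure(self, small_filament):
        _, g = small_filament
        rng = np.random.default_rng(1)
        state = rng.integers(0, 2, g.n_nodes).astype(np.uint8)
        cfg = AutomatonConfig.rule_g()
        np.testing.assert_array_equal(step(state, g, cfg), step(state, g, cfg))

    def test_trajectory_recording(self, small_filament):
        _, g = small_filament
        state = resting_state(g.n_nodes)
        final, traj = evolve(state, g, AutomatonConfig.rule_e(), 3, record=True)
        assert len(traj) == 4
        np.testing.assert_array_equal(traj[-1], final)

    def test_negative_steps_rejected(self, small_filament):
        _, g = small_filament
        with pytest.raises(ValueError):
            evolve(resting_state(g.n_nodes), g, AutomatonConfig.rule_e(), -1)


class TestActivityProfile:
    def test_all_resting_zero_profile(self, small_filament):
        _, g = small_filament
        _, counts = activity_profile(resting_state(g.n_nodes), g, 10.0)
        assert counts.sum() == 0

    def test_single_excited_node_binned(self):
        g = make_graph([[0, 0, 0], [20.0, 0, 0]], rho=30.0)
        state = np.array([RESTING, EXCITED], dtype=np.uint8)
        edges, counts = activity_profile(state, g, 10.0)
        k = np.searchsorted(edges, 20.0, side="right") - 1
        assert counts[k] == 1
        assert edges[k] == pytest.approx(20.0)
        assert counts.sum() == 1

    def test_total_conserved(self, small_filament):
        _, g = small_filament
        rng = np.random.default_rng(9)
        state = rng.integers(0, 3, g.n_nodes).astype(np.uint8)
        _, counts = activity_profile(state, g, 7.0)
        assert counts.sum() == np.count_nonzero(state == EXCITED)


class TestConfigValidation:
    def test_bad_interval(self):
        with pytest.raises(ValueError):
            AutomatonConfig("E", 0.5, 0.2)

    def test_rule_g_requires_survival(self):
        with pytest.raises(ValueError):
            AutomatonConfig("G", 0.2, 0.3)

    def test_bad_mu(self):
        with pytest.raises(ValueError):
            AutomatonConfig.rule_e(mu=1.5)

    def test_bad_rule(self):
        with pytest.raises(ValueError):
            AutomatonConfig("X", 0.1, 0.2)
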