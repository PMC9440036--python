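"""The binary dwarf mongoose search operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bdmsao import ConfigError, DMOParams
from bdmsao.dmo import (
    Agent,
    alpha_move,
    alpha_probabilities,
    average_mound,
    babysitter_exchange,
    compute_cf,
    init_population,
    movement_vector,
    scout_move,
    sleeping_mound,
    tournament_select,
)
from bdmsao.fitness import FitnessValue


def fv(x):
    return FitnessValue(x, 1.0 - x, 0.0, d_s=1, selected_key=(0,))


class TestInitPopulation:
    def test_shape_and_bounds(self):
        p = DMOParams(d=30, n=10, var_min=0.4, var_max=0.6)
        pop = init_population(p, np.random.default_rng(0))
        positions = np.stack([a.position for a in pop])
        assert positions.shape == (10, 30)
        assert positions.min() >= 0.4 and positions.max() <= 0.6

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ConfigError):
            DMOParams(d=5, var_min=0.5, var_max=0.5)

    def test_seed_determinism(self):
        p = DMOParams(d=8, seed=42)
        a = init_population(p)
        b = init_population(p)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.position, y.position)


class TestAlphaProbabilities:
    def test_equal_fitness_uniform(self):
        np.testing.assert_allclose(alpha_probabilities([0.3] * 4), [0.25] * 4)

    def test_minimization_transform(self):
        # g = (max - fit + eps): [0.2+eps, eps] -> probabilities ~ [1, 0]
        probs = alpha_probabilities([0.1, 0.3])
        np.testing.assert_allclose(probs, [1.0, 0.0], atol=1e-10)
        assert probs[0] > probs[1]

    def test_lower_fitness_higher_probability(self):
        probs = alpha_probabilities([0.5, 0.2, 0.9, 0.4])
        assert np.argmax(probs) == 1 and np.argmin(probs) == 2

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20)
    )
    def test_normalization(self, fits):
        assert abs(alpha_probabilities(fits).sum() - 1.0) < 1e-12


class TestTournament:
    def test_best_of_two_chosen_three_quarters(self):
        agents = [Agent(np.zeros(2), fv(0.1)), Agent(np.zeros(2), fv(0.9))]
        rng = np.random.default_rng(0)
        picks = [tournament_select(agents, 2, rng) for _ in range(4000)]
        # enumeration of the 4 equally likely draws: best wins in 3 of 4
        assert np.mean(np.array(picks) == 0) == pytest.approx(0.75, abs=0.03)

    def test_size_one_is_uniform(self):
        agents = [Agent(np.zeros(2), fv(0.1)), Agent(np.zeros(2), fv(0.9))]
        rng = np.random.default_rng(1)
        picks = [tournament_select(agents, 1, rng) for _ in range(4000)]
        assert np.mean(np.array(picks) == 0) == pytest.approx(0.5, abs=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            tournament_select([], 2, np.random.default_rng(0))


class TestMoves:
    def test_alpha_move_zero_peep_is_identity(self):
        x = np.array([0.2, 0.8, 0.5])
        np.testing.assert_array_equal(
            alpha_move(x, 0.0, np.random.default_rng(0)), x
        )

    def test_alpha_move_bounded_by_peep(self):
        x = np.full(50, 0.5)
        cand = alpha_move(x, 0.3, np.random.default_rng(0))
        assert np.abs(cand - x).max() <= 0.3

    def test_alpha_move_clamped(self):
        p = DMOParams(d=3)
        cand = alpha_move(np.array([0.0, 1.0, 0.5]), 5.0,
                          np.random.default_rng(0), p)
        assert cand.min() >= 0.0 and cand.max() <= 1.0

    @pytest.mark.parametrize(
        "new, old, expected",
        [(0.5, 0.5, 0.0), (0.2, 0.1, 0.5), (0.1, 0.2, -0.5), (0.0, 0.0, 0.0)],
    )
    def test_sleeping_mound(self, new, old, expected):
        assert sleeping_mound(new, old) == pytest.approx(expected)

    def test_average_mound(self):
        assert average_mound([0.5, -0.5]) == 0.0
        assert average_mound([0.2]) == pytest.approx(0.2)
        with pytest.raises(ConfigError):
            average_mound([])

    def test_scout_move_identity_cases(self):
        x = np.array([0.3, 0.7])
        m = np.array([0.1, 0.1])
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(scout_move(x, 0.0, m, 1.0, 0.0, rng), x)
        np.testing.assert_array_equal(scout_move(x, 0.5, x, 1.0, 0.0, rng), x)


class TestCF:
    @pytest.mark.parametrize(
        "it, max_it, expected", [(0, 50, 1.0), (50, 50, 0.0), (25, 50, 0.5)]
    )
    def test_closed_form(self, it, max_it, expected):
        assert compute_cf(it, max_it) == pytest.approx(expected, abs=1e-15)

    def test_non_increasing_over_schedule(self):
        vals = [compute_cf(t, 100) for t in range(101)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            compute_cf(1, 0)
        with pytest.raises(ConfigError):
            compute_cf(-1, 10)


class TestMovementVector:
    def test_zero_sms_zero_vector(self):
        agents = [Agent(np.random.rand(4), fv(0.1), sm=0.0) for _ in range(3)]
        np.testing.assert_array_equal(movement_vector(agents), np.zeros(4))

    def test_broadcast_equals_symbolic_simplification(self):
        # the printed quotient sum_i (X_i * sm_i) / X_i cancels X elementwise
        rng = np.random.default_rng(5)
        agents = [
            Agent(rng.uniform(0.1, 1.0, 6), fv(0.1), sm=s)
            for s in (0.5, 0.25)
        ]
        printed = sum(
            (a.position * a.sm) / a.position for a in agents
        )
        np.testing.assert_allclose(movement_vector(agents), printed)
        np.testing.assert_allclose(movement_vector(agents), np.full(6, 0.75))

    def test_position_independence_of_default_form(self):
        rng = np.random.default_rng(6)
        sms = [0.3, -0.1, 0.2]
        a = [Agent(rng.uniform(0.1, 1, 5), fv(0.1), sm=s) for s in sms]
        b = [Agent(rng.uniform(0.1, 1, 5), fv(0.1), sm=s) for s in sms]
        np.testing.assert_allclose(movement_vector(a), movement_vector(b))

    def test_centroid_variant_depends_on_positions(self):
        agents = [
            Agent(np.array([1.0, 0.0]), fv(0.1), sm=0.5),
            Agent(np.array([0.0, 1.0]), fv(0.1), sm=0.25),
        ]
        np.testing.assert_allclose(
            movement_vector(agents, centroid=True), [0.25, 0.125]
        )


class TestBabysitterExchange:
    def make_pop(self, fits, d=4):
        return [Agent(np.full(d, 0.5), fv(f)) for f in fits]

    def test_no_babysitters_identity(self):
        p = DMOParams(d=4, n=3, n_babysitters=0, max_iter=10)
        agents = self.make_pop([0.1, 0.2, 0.3])
        assert babysitter_exchange(agents, 6, p, np.random.default_rng(0)) == []

    def test_off_schedule_identity(self):
        p = DMOParams(d=4, n=4, n_babysitters=2, max_iter=10)  # period 6
        agents = self.make_pop([0.1, 0.2, 0.3, 0.4])
        assert babysitter_exchange(agents, 5, p, np.random.default_rng(0)) == []

    def test_worst_replaced_best_kept(self):
        p = DMOParams(d=4, n=4, n_babysitters=3, max_iter=10)
        agents = self.make_pop([0.4, 0.1, 0.3, 0.2])
        replaced = babysitter_exchange(agents, 6, p, np.random.default_rng(0))
        assert sorted(replaced) == [0, 2, 3]  # everyone but the best (index 1)
        for i in replaced:
            assert agents[i].fitness is None
        assert agents[1].fitness is not None
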