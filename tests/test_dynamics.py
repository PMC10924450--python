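import numpy as np
import pytest

import misinfogame as mg
from misinfogame.dynamics import exact_fixation_oracle, fixation_frequency
from misinfogame.game import payoff_profile

A, B, C = mg.Strategy.A, mg.Strategy.B, mg.Strategy.C


def state_on(graph, strategies):
    strategies = np.asarray(strategies, dtype=np.int8)
    return mg.PopulationState(strategies, strategies == 2)


class TestImitationDraw:
    def test_neutral_draw_uniform_over_non_sanctioners(self):
        g = mg.Graph.from_edges(5, [(0, i) for i in range(1, 5)])
        state = state_on(g, [0, 0, 0, 1, 2])  # focal A; neighbors A, A, B, C
        prof = payoff_profile(state, g, mg.DEFAULT_PAYOFFS, beta=0.0)
        rng = np.random.default_rng(0)
        draws = [mg.imitation_draw(0, state, g, prof, rng) for _ in range(6000)]
        frac_b = np.mean([d == B for d in draws])
        assert abs(frac_b - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / 6000)

    def test_only_sanctioner_neighbors_freeze_strategy(self):
        g = mg.Graph.from_edges(3, [(0, 1), (0, 2)])
        state = state_on(g, [1, 2, 2])
        prof = payoff_profile(state, g, mg.DEFAULT_PAYOFFS, beta=0.5)
        rng = np.random.default_rng(1)
        assert all(mg.imitation_draw(0, state, g, prof, rng) == B for _ in range(50))

    def test_softmax_of_two_neighbors(self):
        # neighbor fitnesses e and 1 -> P(adopt B) = e / (1 + e)
        g = mg.Graph.from_edges(3, [(0, 1), (0, 2)])
        state = state_on(g, [0, 1, 0])
        prof = mg.PayoffProfile(pi=np.zeros(3), f=np.array([1.0, np.e, 1.0]))
        rng = np.random.default_rng(2)
        draws = [mg.imitation_draw(0, state, g, prof, rng) for _ in range(8000)]
        p = np.e / (1 + np.e)
        assert abs(np.mean([d == B for d in draws]) - p) < 3 * np.sqrt(p * (1 - p) / 8000)


class TestSynchronousStep:
    def test_unanimous_population_is_absorbing(self):
        g = mg.make_lattice(4, 4)
        state = state_on(g, [0] * 16)
        new = mg.step_synchronous(state, g, mg.DEFAULT_PAYOFFS, mg.DynamicsConfig(), np.random.default_rng(0))
        assert np.array_equal(new.strategies, state.strategies)
        assert new.t == 1

    def test_neutral_update_preserves_expected_abundance(self):
        # with beta = 0 and no sanctioners the A-count is a martingale
        g = mg.make_lattice(5, 5)
        rng = np.random.default_rng(3)
        strategies = np.zeros(25, dtype=np.int8)
        strategies[rng.choice(25, 10, replace=False)] = 1
        state = state_on(g, strategies)
        cfg = mg.DynamicsConfig(beta=0.0)
        reps = 10000
        counts = np.empty(reps)
        for r in range(reps):
            new = mg.step_synchronous(state, g, mg.DEFAULT_PAYOFFS, cfg, np.random.default_rng(r))
            counts[r] = (new.strategies == 0).sum()
        se = counts.std() / np.sqrt(reps)
        assert abs(counts.mean() - 15) < 3 * se

    def test_checkerboard_inverts_under_von_neumann(self):
        # every node's neighbors all hold the opposite strategy, so each
        # node copies it regardless of beta: the pattern inverts exactly
        g = mg.make_lattice(4, 4)
        board = np.fromfunction(lambda r, c: (r + c) % 2, (4, 4)).astype(np.int8).ravel()
        state = state_on(g, board)
        new = mg.step_synchronous(state, g, mg.DEFAULT_PAYOFFS,
                                  mg.DynamicsConfig(beta=4.0), np.random.default_rng(0))
        assert np.array_equal(new.strategies, 1 - board)

    def test_checkerboard_resolves_to_fake_news_under_moore(self):
        # with diagonal neighbors the B sublattice coordinates (payoff 2)
        # and outcompetes A at strong selection: one sweep turns all B
        g = mg.make_lattice(4, 4, neighborhood="moore")
        board = np.fromfunction(lambda r, c: (r + c) % 2, (4, 4)).astype(np.int8).ravel()
        state = state_on(g, board)
        new = mg.step_synchronous(state, g, mg.DEFAULT_PAYOFFS,
                                  mg.DynamicsConfig(beta=5.0), np.random.default_rng(0))
        assert (new.strategies == 1).all()


class TestAsynchronousStep:
    def test_sanctioner_draw_is_noop(self):
        g = mg.Graph.from_edges(2, [(0, 1)])
        state = state_on(g, [2, 0])
        cfg = mg.DynamicsConfig(update="asynchronous")
        for seed in range(20):
            new = mg.step_asynchronous(state, g, mg.DEFAULT_PAYOFFS, cfg, np.random.default_rng(seed))
            assert np.array_equal(new.strategies, state.strategies) or new.strategies[1] != 2
            assert new.sanctioner_mask[0] and not new.sanctioner_mask[1]

    def test_walled_in_nodes_frozen_forever(self):
        # a B walled in by sanctioners and an isolated A: no update can
        # ever change anyone, so the run times out with the state intact
        g = mg.Graph.from_edges(4, [(0, 1), (0, 2)])
        state = state_on(g, [1, 2, 2, 0])
        res = mg.run(state, g, mg.DEFAULT_PAYOFFS,
                     mg.DynamicsConfig(update="asynchronous", max_steps=300, seed=4))
        assert res.outcome == "timeout"
        assert np.array_equal(res.final_state.strategies, state.strategies)
        assert (res.activity == 0).all()


class TestRun:
    def test_no_contest_terminates_at_step_zero(self):
        g = mg.make_lattice(3, 3)
        res = mg.run(state_on(g, [0] * 9), g)
        assert res.outcome == "A_fixed" and res.steps_run == 0 and res.dominant == "A"

    def test_all_sanctioners_is_a_tie(self):
        g = mg.make_lattice(3, 3)
        res = mg.run(state_on(g, [2] * 9), g)
        assert res.dominant == "tie" and res.steps_run == 0 and res.outcome == "timeout"

    def test_replay_is_bit_identical(self, lattice30):
        init = mg.place_random(lattice30, mg.InitSpec(pC=0.2, seed=11))
        cfg = mg.DynamicsConfig(max_steps=120, seed=99)
        r1 = mg.run(init.copy(), lattice30, mg.DEFAULT_PAYOFFS, cfg)
        r2 = mg.run(init.copy(), lattice30, mg.DEFAULT_PAYOFFS, cfg)
        assert np.array_equal(r1.final_state.strategies, r2.final_state.strategies)
        assert np.array_equal(r1.activity, r2.activity)
        assert r1.to_record() == r2.to_record()

    def test_sanctioners_immutable_along_trajectory(self, lattice30):
        init = mg.place_random(lattice30, mg.InitSpec(pC=0.3, seed=21))
        res = mg.run(init, lattice30, mg.DEFAULT_PAYOFFS, mg.DynamicsConfig(max_steps=150, seed=5))
        assert np.array_equal(res.final_state.sanctioner_mask, init.sanctioner_mask)
        assert np.array_equal(res.final_state.strategies == 2, init.strategies == 2)
        assert res.final_state.counts()[2] == init.counts()[2]

    def test_activity_bounded_and_recorded_per_step(self, lattice30):
        init = mg.place_random(lattice30, mg.InitSpec(pC=0.2, seed=31))
        res = mg.run(init, lattice30, mg.DEFAULT_PAYOFFS, mg.DynamicsConfig(max_steps=80, seed=6))
        assert len(res.activity) == res.steps_run
        assert ((res.activity >= 0) & (res.activity <= 1)).all()

    def test_sync_and_async_dominance_agree_qualitatively(self):
        # matched parameters, async clock scaled by n: the two schedules
        # are the same process on different time scales
        g = mg.make_lattice(7, 7)
        reps = 20
        probs = {}
        for update, steps in (("synchronous", 600), ("asynchronous", 600 * 49)):
            wins = 0.0
            for r in range(reps):
                init = mg.place_random(g, mg.InitSpec(pC=0.25, seed=700 + r))
                res = mg.run(init, g, mg.DEFAULT_PAYOFFS,
                             mg.DynamicsConfig(update=update, max_steps=steps, seed=800 + r))
                wins += {"A": 1.0, "tie": 0.5, "B": 0.0}[res.dominant]
            probs[update] = wins / reps
        se = np.sqrt(2 * 0.25 / reps)
        assert abs(probs["synchronous"] - probs["asynchronous"]) < 3 * se + 0.05


class TestExactOracle:
    def test_two_viable_construction_is_a_coin_flip(self, two_viable):
        graph, state = two_viable
        cfg = mg.DynamicsConfig(update="asynchronous", beta=0.5)
        assert exact_fixation_oracle(graph, mg.DEFAULT_PAYOFFS, cfg, state) == pytest.approx(0.5)
        # payoff-independent: the lone non-sanctioner neighbor always wins
        weird = mg.PayoffMatrix(a=3, b=-1, alpha=2, c=7, d=0, gamma=-9)
        assert exact_fixation_oracle(graph, weird, cfg, state) == pytest.approx(0.5)

    def test_all_a_initial_is_absorbing(self):
        g = mg.make_lattice(3, 3, periodic=False)
        state = state_on(g, [0] * 9)
        cfg = mg.DynamicsConfig(update="asynchronous")
        assert exact_fixation_oracle(g, mg.DEFAULT_PAYOFFS, cfg, state) == pytest.approx(1.0)

    def test_neutral_fixation_is_initial_fraction(self):
        # beta = 0, no sanctioners, regular graph: voter-model identity m/N
        g = mg.make_lattice(4, 3)  # 12 nodes, 4-regular
        strategies = np.ones(12, dtype=np.int8)
        strategies[[0, 5, 7]] = 0
        state = state_on(g, strategies)
        cfg = mg.DynamicsConfig(update="asynchronous", beta=0.0)
        assert exact_fixation_oracle(g, mg.DEFAULT_PAYOFFS, cfg, state) == pytest.approx(3 / 12)

    def test_refuses_large_state_spaces(self):
        g = mg.make_lattice(4, 4)
        state = state_on(g, [0] * 16)
        with pytest.raises(ValueError, match="oracle limit"):
            exact_fixation_oracle(g, mg.DEFAULT_PAYOFFS, mg.DynamicsConfig(), state)


class TestSimulatorAgainstOracle:
    def test_corner_sanctioned_fixture(self, corner_sanctioned):
        graph, state = corner_sanctioned
        cfg = mg.DynamicsConfig(update="asynchronous", beta=0.5, payoff_mode="sum")
        exact = exact_fixation_oracle(graph, mg.DEFAULT_PAYOFFS, cfg, state)
        reps = 3000
        wins = sum(
            mg.run(state.copy(), graph, mg.DEFAULT_PAYOFFS,
                   mg.DynamicsConfig(update="asynchronous", beta=0.5, payoff_mode="sum",
                                     max_steps=100000, seed=r)).outcome == "A_fixed"
            for r in range(reps)
        )
        se = np.sqrt(exact * (1 - exact) / reps)
        assert abs(wins / reps - exact) < 3 * se


class TestBatchedFixationKernel:
    def test_neutral_identity_and_against_oracle(self):
        # beta = 0, pC = 0 on the 12-node lattice: fixation = m / N
        g = mg.make_lattice(4, 3)
        out = fixation_frequency(g, mg.DEFAULT_PAYOFFS, beta=0.0, n_sanctioners=0,
                                 n_a=3, reps=20000, seed=17)
        se = np.sqrt(0.25 * 0.75 / out["reps"])
        assert abs(out["fix_a"] - 3 / 12) < 3 * se
        assert out["stalled"] == 0.0
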