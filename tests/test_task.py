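"""Task environment: transition rules, fuel accounting, design generation."""

import numpy as np
import pandas as pd
import pytest

import satplan as sp
from satplan.config import ConfigError, MiniBlock, State, ring_neighbours
from satplan.task import (
    TaskError,
    blocks_from_frame,
    blocks_to_frame,
    is_discriminating,
    optimal_first_actions,
    transition_probabilities,
    validate_log,
)


def make_block(types=(0, 1, 2, 3, 4, 0), start=0, n_steps=3, noise="low", bid=0):
    return MiniBlock(id=bid, planet_types=tuple(types), start_position=start,
                     n_steps=n_steps, noise=noise)


class TestConfig:
    def test_defaults_valid_and_hash_stable(self, config):
        assert config.config_hash() == sp.TaskConfig().config_hash()

    def test_yaml_round_trip(self, config, tmp_path):
        path = tmp_path / "cfg.yaml"
        config.to_yaml(path)
        assert sp.TaskConfig.from_yaml(path) == config

    @pytest.mark.parametrize(
        "kw",
        [
            {"planet_type_rewards": (1.0, 2.0, 3.0)},       # not five types
            {"move_cost": -1.0},
            {"noise_success": {"low": 1.5, "high": 0.5}},
            {"jump_map": (1, 2, 3, 4, 5, 0)},               # neighbour targets
            {"jump_map": (0, 4, 5, 0, 1, 2)},               # self target
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            sp.TaskConfig(**kw)

    def test_jump_map_targets_non_neighbours(self, config):
        for p, t in enumerate(config.jump_map):
            assert t != p and t not in ring_neighbours(p)


class TestTransitions:
    def test_move_is_deterministic_clockwise(self, config):
        for pos in range(6):
            probs = transition_probabilities(config, pos, "move", 0.9)
            assert probs[(pos + 1) % 6] == 1.0 and probs.sum() == 1.0

    @pytest.mark.parametrize("p_succ", [0.9, 0.5, 0.0, 1.0, 0.37])
    def test_jump_splits_failure_mass_equally(self, config, p_succ):
        for pos in range(6):
            probs = transition_probabilities(config, pos, "jump", p_succ)
            target = config.jump_map[pos]
            left, right = ring_neighbours(target)
            assert probs[target] == pytest.approx(p_succ)
            assert probs[left] == probs[right] == pytest.approx((1 - p_succ) / 2)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert (probs > 0).sum() <= 3

    def test_invalid_inputs_raise(self, config):
        with pytest.raises(ConfigError):
            transition_probabilities(config, 6, "move", 0.9)
        with pytest.raises(ConfigError):
            transition_probabilities(config, 0, "jump", 1.2)
        with pytest.raises(ConfigError):
            transition_probabilities(config, 0, "teleport", 0.9)

    def test_empirical_jump_success_matches_configured(self, config):
        rng = np.random.default_rng(123)
        for noise, p_true in (("low", 0.9), ("high", 0.5)):
            block = make_block(noise=noise)
            hits = 0
            n = 10_000
            for _ in range(n):
                state = State(position=0, fuel=0.0, steps_remaining=3)
                _, outcome = sp.apply_action(config, block, state, "jump", rng)
                hits += outcome.jump_succeeded
            se = np.sqrt(p_true * (1 - p_true) / n)
            assert abs(hits / n - p_true) < 3 * se


class TestApplyAction:
    def test_costs_charged_regardless_of_outcome(self, config):
        rng = np.random.default_rng(0)
        block = make_block(noise="high")
        for action, cost in (("move", 2.0), ("jump", 5.0)):
            state = State(position=0, fuel=10.0, steps_remaining=3)
            new, outcome = sp.apply_action(config, block, state, action, rng)
            assert outcome.cost_paid == cost
            assert new.fuel == pytest.approx(10.0 - cost + outcome.reward_collected)
            assert new.steps_remaining == 2

    def test_full_block_fuel_conservation(self, config):
        rng = np.random.default_rng(5)
        block = make_block(n_steps=3)
        state = State(position=block.start_position, fuel=0.0, steps_remaining=3)
        total = 0.0
        for _ in range(3):
            state, outcome = sp.apply_action(config, block, state, "jump", rng)
            total += outcome.reward_collected - outcome.cost_paid
        assert state.fuel == pytest.approx(total)

    def test_acting_without_steps_raises(self, config):
        state = State(position=0, fuel=0.0, steps_remaining=0)
        with pytest.raises(TaskError):
            sp.apply_action(config, make_block(), state, "move", np.random.default_rng(0))


class TestDesignGeneration:
    def test_experiment_has_100_blocks_in_4_phases_of_25(self, config):
        blocks = sp.generate_experiment(config, seed=3)
        assert len(blocks) == 100
        per_phase = {}
        for b in blocks:
            per_phase.setdefault(b.phase, set()).add(b.condition)
        assert len(per_phase) == 4
        assert all(len(conds) == 1 for conds in per_phase.values())
        from collections import Counter

        counts = Counter(b.condition for b in blocks)
        assert all(c == 25 for c in counts.values()) and len(counts) == 4

    def test_training_has_20_blocks_5_per_condition(self, config):
        blocks = sp.generate_training(config, seed=3)
        assert len(blocks) == 20
        from collections import Counter

        counts = Counter(b.condition for b in blocks)
        assert all(c == 5 for c in counts.values()) and len(counts) == 4

    def test_same_seed_reproduces_sequence(self, config):
        a = sp.generate_experiment(config, seed=8)
        b = sp.generate_experiment(config, seed=8)
        assert a == b
        assert sp.generate_training(config, seed=8) == sp.generate_training(config, seed=8)

    def test_phase_order_counterbalanced_but_layouts_shared(self, config):
        base = sp.generate_experiment(config, seed=4, participant_index=0)
        rot = sp.generate_experiment(config, seed=4, participant_index=1)
        assert [b.condition for b in base] != [b.condition for b in rot]
        key = lambda blocks: sorted(
            (b.planet_types, b.start_position, b.condition) for b in blocks
        )
        assert key(base) == key(rot)

    def test_generated_blocks_are_discriminating(self, config):
        blocks = sp.generate_experiment(config, seed=6)
        assert all(is_discriminating(config, b) for b in blocks)

    def test_blocks_frame_round_trip(self, config):
        blocks = sp.generate_experiment(config, seed=2)
        assert blocks_from_frame(blocks_to_frame(blocks)) == blocks


class TestMaxExpectedScore:
    def brute_force(self, config, block):
        """Exhaustive expectation-maximization over the action/outcome tree."""
        p = config.noise_success[block.noise]
        rewards = block.rewards(config)

        def V(pos, d):
            if d == 0:
                return 0.0
            return max(Q(pos, a, d) for a in ("move", "jump"))

        def Q(pos, a, d):
            probs = transition_probabilities(config, pos, a, p)
            return -config.action_cost(a) + sum(
                probs[q] * (rewards[q] + V(q, d - 1)) for q in range(6) if probs[q] > 0
            )

        return V(block.start_position, block.n_steps)

    def test_matches_enumeration_on_random_blocks(self, config):
        rng = np.random.default_rng(17)
        for _ in range(50):
            block = make_block(
                types=tuple(rng.integers(0, 5, 6)),
                start=int(rng.integers(0, 6)),
                n_steps=int(rng.choice([2, 3])),
                noise=str(rng.choice(["low", "high"])),
            )
            assert sp.max_expected_score(config, block) == pytest.approx(
                self.brute_force(config, block), abs=1e-9
            )

    def test_forced_single_good_move(self, config):
        # only position 1 (reachable by move) rewards +20; every other planet
        # costs -20 on arrival.  Optimal play: move (+20 - 2), then the least
        # bad second action is another move (-20 - 2), totalling -4.
        types = [0, 4, 0, 0, 0, 0]
        block = make_block(types=types, start=0, n_steps=2, noise="low")
        assert sp.max_expected_score(config, block) == pytest.approx(-4.0)

    def test_deterministic_world_equals_best_sequence(self):
        cfg = sp.TaskConfig(noise_success={"low": 1.0, "high": 1.0})
        rng = np.random.default_rng(3)
        import itertools

        for _ in range(20):
            block = make_block(types=tuple(rng.integers(0, 5, 6)), start=0, n_steps=3)
            best = -np.inf
            for seq in itertools.product(["move", "jump"], repeat=3):
                pos, total = 0, 0.0
                for a in seq:
                    pos = (pos + 1) % 6 if a == "move" else cfg.jump_map[pos]
                    total += -cfg.action_cost(a) + block.rewards(cfg)[pos]
                best = max(best, total)
            assert sp.max_expected_score(cfg, block) == pytest.approx(best)

    def test_optimal_dominates_fixed_sequences(self, config):
        import itertools

        block = make_block(types=(3, 0, 4, 1, 2, 0), start=2, n_steps=3, noise="high")
        opt = sp.max_expected_score(config, block)
        p = config.noise_success[block.noise]
        for seq in itertools.product(["move", "jump"], repeat=3):
            # expected value of the fixed sequence by forward enumeration
            dist = {block.start_position: 1.0}
            value = 0.0
            for a in seq:
                new = {}
                for pos, w in dist.items():
                    probs = transition_probabilities(config, pos, a, p)
                    value -= w * config.action_cost(a)
                    for q in range(6):
                        if probs[q] > 0:
                            value += w * probs[q] * block.rewards(config)[q]
                            new[q] = new.get(q, 0.0) + w * probs[q]
                dist = new
            assert opt >= value - 1e-9


class TestLogValidation:
    def test_simulated_log_validates(self, small_config):
        blocks = sp.generate_experiment(small_config, seed=1)
        rng = np.random.default_rng(2)
        log, _ = sp.simulate_agent(
            small_config, blocks, sp.AgentParams(1.5, 0.0, 0.1), lambda b: 1, rng
        )
        validate_log(log, small_config)

    def test_corrupted_fuel_detected(self, small_config):
        blocks = sp.generate_experiment(small_config, seed=1)
        rng = np.random.default_rng(2)
        log, _ = sp.simulate_agent(
            small_config, blocks, sp.AgentParams(1.5, 0.0, 0.1), lambda b: 1, rng
        )
        bad = log.copy()
        bad.loc[bad.index[4], "fuel_after"] += 1.0
        with pytest.raises(TaskError):
            validate_log(bad, small_config)

    def test_illegal_transition_detected(self, small_config):
        blocks = sp.generate_experiment(small_config, seed=1)
        rng = np.random.default_rng(2)
        log, _ = sp.simulate_agent(
            small_config, blocks, sp.AgentParams(1.5, 0.0, 0.1), lambda b: 1, rng
        )
        bad = log.copy()
        first = bad.index[bad["action"] == "move"][0]
        bad.loc[first, "position_after"] = (int(bad.loc[first, "position_before"]) + 3) % 6
        with pytest.raises(TaskError):
            validate_log(bad, small_config)


class TestDiscriminability:
    def test_optimal_first_actions_has_one_entry_per_depth(self, config):
        block = make_block(n_steps=3)
        assert len(optimal_first_actions(config, block)) == 3
        assert len(optimal_first_actions(config, make_block(n_steps=2))) == 2
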