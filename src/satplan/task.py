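"""Simulator of the Space Adventure Task environment.

Implements the true task dynamics (used by the environment when rolling out
agents), experiment/training sequence generation with a depth-discriminability
filter and counterbalanced phase orders, and the optimal expected score of a
mini-block (the denominator of the performance percentage).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import (
    N_PLANETS,
    ConfigError,
    MiniBlock,
    Outcome,
    State,
    TaskConfig,
    ring_neighbours,
)


class TaskError(RuntimeError):
    """Raised on illegal environment operations (e.g. acting with no steps left)."""


#: Canonical column order of tidy behavior logs.
BEHAVIOR_COLUMNS = [
    "subject_id",
    "group",
    "phase",
    "miniblock_id",
    "trial_index",
    "noise",
    "n_steps",
    "planet_types",
    "start_position",
    "position_before",
    "action",
    "jump_succeeded",
    "position_after",
    "reward_collected",
    "cost_paid",
    "fuel_after",
    "rt_ms",
]

# Latin square over the four phase orders; participants cycle through rows.
_PHASE_ORDERS = ((0, 1, 2, 3), (1, 2, 3, 0), (2, 3, 0, 1), (3, 0, 1, 2))


def transition_probabilities(
    config: TaskConfig, position: int, action: str, success_prob: float
) -> np.ndarray:
    """Distribution over next positions for one action.

    Moving is deterministic (clockwise successor).  Jumping reaches the
    travel-pattern target with ``success_prob``; on failure the ship lands on
    one of the two ring neighbours of the target, each with probability
    ``(1 - success_prob) / 2``.
    """
    if not 0 <= position < config.n_planets:
        raise ConfigError(f"invalid position {position}")
    if not 0.0 <= success_prob <= 1.0:
        raise ConfigError(f"success probability {success_prob} not in [0, 1]")
    probs = np.zeros(config.n_planets)
    if action == "move":
        probs[(position + 1) % config.n_planets] = 1.0
    elif action == "jump":
        target = config.jump_map[position]
        left, right = ring_neighbours(target, config.n_planets)
        probs[target] += success_prob
        fail = (1.0 - success_prob) / 2.0
        probs[left] += fail
        probs[right] += fail
    else:
        raise ConfigError(f"unknown action {action!r}")
    return probs


def apply_action(
    config: TaskConfig,
    block: MiniBlock,
    state: State,
    action: str,
    rng: np.random.Generator,
) -> tuple[State, Outcome]:
    """Execute one action with the TRUE condition success probability.

    The action cost is charged regardless of outcome; the arrival reward is
    collected at the (sampled) next position.  Fuel has no floor.
    """
    if state.steps_remaining <= 0:
        raise TaskError("no steps remaining in this mini-block")
    success_prob = config.noise_success[block.noise]
    probs = transition_probabilities(config, state.position, action, success_prob)
    next_position = int(rng.choice(config.n_planets, p=probs))
    jump_succeeded = None
    if action == "jump":
        jump_succeeded = next_position == config.jump_map[state.position]
    cost = config.action_cost(action)
    reward = config.reward_at(block.planet_types, next_position)
    new_state = State(
        position=next_position,
        fuel=state.fuel - cost + reward,
        steps_remaining=state.steps_remaining - 1,
    )
    outcome = Outcome(
        action=action,
        next_position=next_position,
        jump_succeeded=jump_succeeded,
        reward_collected=reward,
        cost_paid=cost,
    )
    return new_state, outcome


def optimal_first_actions(config: TaskConfig, block: MiniBlock) -> list[str]:
    """Optimal first action of a fully informed agent at each depth 1..n_steps.

    Ties between equal-valued actions resolve to the deterministic move.
    """
    from .agents import Belief, q_values

    p = config.noise_success[block.noise]
    belief = Belief(rho_low=p, rho_high=p)
    actions = []
    for depth in range(1, block.n_steps + 1):
        q = q_values(config, block, block.start_position, block.n_steps, belief, depth)
        actions.append("jump" if q.q_jump > q.q_move else "move")
    return actions


def is_discriminating(config: TaskConfig, block: MiniBlock) -> bool:
    """Whether the optimal first action differs between planning depths."""
    return len(set(optimal_first_actions(config, block))) > 1


def _sample_block(
    config: TaskConfig,
    rng: np.random.Generator,
    n_steps: int,
    noise: str,
    apply_filter: bool,
) -> MiniBlock:
    keep_anyway = rng.random() < config.nondiscriminating_fraction
    for _ in range(config.max_resample_attempts):
        block = MiniBlock(
            id=-1,
            planet_types=tuple(int(t) for t in rng.integers(0, 5, size=N_PLANETS)),
            start_position=int(rng.integers(0, N_PLANETS)),
            n_steps=n_steps,
            noise=noise,
        )
        if not apply_filter or keep_anyway or is_discriminating(config, block):
            return block
    return block  # bounded attempts exhausted: accept the last candidate


def _replace(block: MiniBlock, **kw) -> MiniBlock:
    d = dict(
        id=block.id,
        planet_types=block.planet_types,
        start_position=block.start_position,
        n_steps=block.n_steps,
        noise=block.noise,
        phase=block.phase,
    )
    d.update(kw)
    return MiniBlock(**d)


def generate_experiment(
    config: TaskConfig, seed: int, participant_index: int = 0
) -> list[MiniBlock]:
    """Generate the 100-mini-block experiment sequence.

    The mini-block layouts are drawn from ``seed`` alone (every participant
    sees the same per-condition block pool); ``participant_index`` selects
    the counterbalanced phase order from a Latin square.
    """
    rng = np.random.default_rng(seed)
    pools = []
    for (n_steps, noise), n_blocks in config.phase_design:
        pools.append(
            [
                _sample_block(config, rng, n_steps, noise, config.discriminability_filter)
                for _ in range(n_blocks)
            ]
        )
    order = _PHASE_ORDERS[participant_index % len(_PHASE_ORDERS)]
    blocks: list[MiniBlock] = []
    for phase_idx, pool_idx in enumerate(order):
        for block in pools[pool_idx]:
            blocks.append(_replace(block, id=len(blocks), phase=phase_idx))
    return blocks


def generate_training(
    config: TaskConfig, seed: int, participant_index: int = 0
) -> list[MiniBlock]:
    """Generate the training session (5 mini-blocks per condition by default)."""
    rng = np.random.default_rng(seed)
    per_cond = config.training_blocks_per_condition
    pools = []
    for (n_steps, noise), _ in config.phase_design:
        pools.append(
            [
                _sample_block(config, rng, n_steps, noise, config.discriminability_filter)
                for _ in range(per_cond)
            ]
        )
    order = _PHASE_ORDERS[participant_index % len(_PHASE_ORDERS)]
    blocks: list[MiniBlock] = []
    for phase_idx, pool_idx in enumerate(order):
        for block in pools[pool_idx]:
            blocks.append(_replace(block, id=len(blocks), phase=phase_idx))
    return blocks


def max_expected_score(
    config: TaskConfig, block: MiniBlock, denominator: str = "expected"
) -> float:
    """Expected cumulative fuel change of the optimal policy for one mini-block.

    Computed by backward recursion over the full horizon (an exhaustive
    expectation over the at-most-3-branch outcome tree at every step) with
    the true success probability.  ``denominator="deterministic"`` instead
    scores the best plan assuming jumps always succeed (an optimistic upper
    bound, available for robustness analyses).
    """
    if denominator == "expected":
        p = config.noise_success[block.noise]
    elif denominator == "deterministic":
        p = 1.0
    else:
        raise ValueError(f"unknown denominator variant {denominator!r}")
    rewards = np.array(block.rewards(config))
    n = config.n_planets
    values = np.zeros(n)
    for _ in range(block.n_steps):
        q_move = np.empty(n)
        q_jump = np.empty(n)
        for pos in range(n):
            nxt = (pos + 1) % n
            q_move[pos] = -config.move_cost + rewards[nxt] + values[nxt]
            probs = transition_probabilities(config, pos, "jump", p)
            q_jump[pos] = -config.jump_cost + probs @ (rewards + values)
        values = np.maximum(q_move, q_jump)
    return float(values[block.start_position])


def validate_log(log: pd.DataFrame, config: TaskConfig, atol: float = 1e-9) -> None:
    """Consistency checks on a tidy behavior log.

    Verifies legal transitions, the fuel conservation identity, correct
    action costs, and per-block step counts.  Raises ``TaskError`` on the
    first violation.
    """
    required = set(BEHAVIOR_COLUMNS) - {"rt_ms", "group"}
    missing = required - set(log.columns)
    if missing:
        raise TaskError(f"behavior log missing columns: {sorted(missing)}")
    for (subject, block_id), rows in log.groupby(["subject_id", "miniblock_id"], sort=False):
        rows = rows.sort_values("trial_index")
        n_steps = int(rows["n_steps"].iloc[0])
        if len(rows) != n_steps:
            raise TaskError(
                f"subject {subject} block {block_id}: {len(rows)} trials, expected {n_steps}"
            )
        types = [int(t) for t in str(rows["planet_types"].iloc[0]).split(";")]
        prev_pos = int(rows["start_position"].iloc[0])
        for _, row in rows.iterrows():
            if int(row["position_before"]) != prev_pos:
                raise TaskError(f"subject {subject} block {block_id}: broken position chain")
            probs = transition_probabilities(
                config, prev_pos, row["action"], config.noise_success[row["noise"]]
            )
            if probs[int(row["position_after"])] <= 0:
                raise TaskError(
                    f"subject {subject} block {block_id}: illegal transition "
                    f"{prev_pos}->{row['position_after']} via {row['action']}"
                )
            expect_cost = config.action_cost(row["action"])
            if abs(row["cost_paid"] - expect_cost) > atol:
                raise TaskError(f"subject {subject} block {block_id}: wrong action cost")
            expect_reward = config.planet_type_rewards[types[int(row["position_after"])]]
            if abs(row["reward_collected"] - expect_reward) > atol:
                raise TaskError(f"subject {subject} block {block_id}: wrong arrival reward")
            prev_pos = int(row["position_after"])
    for subject, rows in log.groupby("subject_id", sort=False):
        rows = rows.sort_values(["miniblock_id", "trial_index"])
        fuel = rows["fuel_after"].to_numpy()
        delta = rows["reward_collected"].to_numpy() - rows["cost_paid"].to_numpy()
        if not np.allclose(np.diff(fuel), delta[1:], atol=atol):
            raise TaskError(f"subject {subject}: fuel conservation identity violated")


def blocks_to_frame(blocks: Iterable[MiniBlock]) -> pd.DataFrame:
    """Tabular view of a mini-block sequence."""
    return pd.DataFrame(
        {
            "miniblock_id": [b.id for b in blocks],
            "phase": [b.phase for b in blocks],
            "n_steps": [b.n_steps for b in blocks],
            "noise": [b.noise for b in blocks],
            "planet_types": [";".join(map(str, b.planet_types)) for b in blocks],
            "start_position": [b.start_position for b in blocks],
        }
    )


def blocks_from_frame(frame: pd.DataFrame) -> list[MiniBlock]:
    """Rebuild mini-blocks from the tabular view (or from a behavior log)."""
    cols = ["miniblock_id", "phase", "n_steps", "noise", "planet_types", "start_position"]
    frame = frame.drop_duplicates(subset="miniblock_id")[cols].sort_values("miniblock_id")
    return [
        MiniBlock(
            id=int(r.miniblock_id),
            planet_types=tuple(int(t) for t in str(r.planet_types).split(";")),
            start_position=int(r.start_position),
            n_steps=int(r.n_steps),
            noise=str(r.noise),
            phase=int(r.phase),
        )
        for r in frame.itertuples()
    ]
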