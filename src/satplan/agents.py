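"""Depth-limited planning agents for the Space Adventure Task.

An agent knows the task rules but plans only ``depth`` actions ahead, using
finite-horizon value iteration with its *believed* jump-success probability.
Actions are chosen through a sigmoid of the Q-value difference scaled by an
inverse temperature ``beta`` and shifted by a response bias ``theta``
(positive values favour jumping).  The believed success probability of each
noise condition is learned from experienced jump outcomes with a delta rule
with learning rate ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import ConfigError, MiniBlock, State, TaskConfig
from .task import BEHAVIOR_COLUMNS, TaskError, apply_action, transition_probabilities

MAX_DEPTH = 3
_NXT = np.array([(p + 1) % 6 for p in range(6)])


@dataclass(frozen=True)
class AgentParams:
    """Subject-level choice-model parameters.

    beta : inverse temperature, >= 0.  At 0 choices ignore values entirely.
    theta : response bias; negative values favour the deterministic move.
    alpha : learning rate of the jump-success belief, in [0, 1].
    """

    beta: float
    theta: float = 0.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ConfigError("beta must be nonnegative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError("alpha must be in [0, 1]")


@dataclass(frozen=True)
class Belief:
    """Believed jump-success probability per noise condition."""

    rho_low: float = 0.5
    rho_high: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_low <= 1.0 and 0.0 <= self.rho_high <= 1.0):
            raise ConfigError("beliefs must be probabilities")

    def for_noise(self, noise: str) -> float:
        return self.rho_low if noise == "low" else self.rho_high

    def updated(self, noise: str, outcome: int, alpha: float) -> "Belief":
        rho = update_belief(self.for_noise(noise), outcome, alpha)
        if noise == "low":
            return replace(self, rho_low=rho)
        return replace(self, rho_high=rho)


@dataclass(frozen=True)
class QPair:
    q_move: float
    q_jump: float
    depth: int

    @property
    def delta_q(self) -> float:
        return self.q_jump - self.q_move


def q_values(
    config: TaskConfig,
    block: MiniBlock,
    position: int,
    steps_remaining: int,
    belief: Belief,
    depth: int,
) -> QPair:
    """Q-values of move and jump under depth-limited value iteration.

    The recursion is Q_d(s, a) = -cost(a) + sum_s' p(s'|s,a) [r(s') + V_{d-1}(s')]
    with V_0 = 0 and V_k(s) = max_a Q_k(s, a), where the jump transition uses
    the believed success probability of the block's noise condition.  The
    horizon is truncated to the steps remaining in the mini-block.
    """
    if depth not in (1, 2, MAX_DEPTH):
        raise ConfigError(f"planning depth must be in 1..3, got {depth}")
    horizon = min(depth, steps_remaining)
    if horizon < 1:
        raise TaskError("cannot plan with no steps remaining")
    rho = belief.for_noise(block.noise)
    rewards = np.array(block.rewards(config))
    n = config.n_planets
    values = np.zeros(n)
    q_move = q_jump = None
    for _ in range(horizon):
        arrival = rewards + values
        q_move = -config.move_cost + arrival[_NXT]
        q_jump = np.empty(n)
        for pos in range(n):
            probs = transition_probabilities(config, pos, "jump", rho)
            q_jump[pos] = -config.jump_cost + probs @ arrival
        values = np.maximum(q_move, q_jump)
    return QPair(q_move=float(q_move[position]), q_jump=float(q_jump[position]), depth=depth)


def choice_probability(qpair: QPair, params: AgentParams) -> float:
    """Probability of choosing jump: sigmoid(beta * (Qjump - Qmove) + theta)."""
    return float(expit(params.beta * qpair.delta_q + params.theta))


def update_belief(rho: float, outcome: int, alpha: float) -> float:
    """Delta-rule update of the jump-success belief: rho + alpha * (o - rho)."""
    if not 0.0 <= rho <= 1.0:
        raise ConfigError("rho must be a probability")
    if outcome not in (0, 1, 0.0, 1.0):
        raise ConfigError("outcome must be 0 (failure) or 1 (success)")
    if not 0.0 <= alpha <= 1.0:
        raise ConfigError("alpha must be in [0, 1]")
    return float(rho + alpha * (outcome - rho))


def delta_q_batch(
    rewards: np.ndarray,
    start: np.ndarray,
    rho: np.ndarray,
    jump_map: Sequence[int],
    move_cost: float,
    jump_cost: float,
    max_depth: int = MAX_DEPTH,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ``delta Q`` per block and depth, with its derivative in rho.

    Parameters are arrays over B mini-blocks: ``rewards`` (B, 6) arrival
    rewards, ``start`` (B,) start positions, ``rho`` (B,) believed success
    probabilities.  Returns ``(dq, ddq_drho)``, each (B, max_depth), where
    ``dq[b, d-1]`` is Q(jump) - Q(move) at the start position under depth d.
    The derivative propagates through the value-iteration max via the argmax
    branch (a valid subgradient at ties).

    Used by the likelihood and inference layers, where the gradient of the
    log-likelihood in the learning rate flows through rho.
    """
    B = rewards.shape[0]
    tgt = np.asarray(jump_map)
    lft, rgt = (tgt - 1) % 6, (tgt + 1) % 6
    rho = rho[:, None]
    V = np.zeros((B, 6))
    dV = np.zeros((B, 6))
    rows = np.arange(B)
    dq = np.empty((B, max_depth))
    ddq = np.empty((B, max_depth))
    for k in range(max_depth):
        A = rewards + V
        dA = dV
        q_move = -move_cost + A[:, _NXT]
        dq_move = dA[:, _NXT]
        q_jump = -jump_cost + rho * A[:, tgt] + (1.0 - rho) / 2.0 * (A[:, lft] + A[:, rgt])
        dq_jump = (
            rho * dA[:, tgt]
            + (1.0 - rho) / 2.0 * (dA[:, lft] + dA[:, rgt])
            + (A[:, tgt] - (A[:, lft] + A[:, rgt]) / 2.0)
        )
        dq[:, k] = (q_jump - q_move)[rows, start]
        ddq[:, k] = (dq_jump - dq_move)[rows, start]
        take_jump = q_jump > q_move
        V = np.where(take_jump, q_jump, q_move)
        dV = np.where(take_jump, dq_jump, dq_move)
    return dq, ddq


def _resolve_depth(
    block: MiniBlock, depth_policy, rng: np.random.Generator
) -> int:
    if callable(depth_policy):
        spec = depth_policy(block)
    elif isinstance(depth_policy, dict):
        spec = depth_policy[block.id]
    else:
        spec = depth_policy[block.id]
    if np.ndim(spec) > 0:  # a simplex over depths to sample from
        weights = np.asarray(spec, dtype=float)
        if weights.size not in (2, MAX_DEPTH):
            raise ConfigError("depth weights must cover depths 1..2 or 1..3")
        depth = int(rng.choice(np.arange(1, weights.size + 1), p=weights / weights.sum()))
    else:
        depth = int(spec)
    if depth not in (1, 2, MAX_DEPTH):
        raise ConfigError(f"invalid planning depth {depth}")
    if depth > block.n_steps:
        raise ConfigError(
            f"depth {depth} requested in a {block.n_steps}-step mini-block"
        )
    return depth


def simulate_agent(
    config: TaskConfig,
    experiment: Sequence[MiniBlock],
    params: AgentParams,
    depth_policy: Callable[[MiniBlock], int] | Sequence | dict,
    rng: np.random.Generator,
    initial_belief: Belief = Belief(),
    subject_id: int | str = 0,
    group: str = "",
    initial_fuel: float = 0.0,
) -> tuple[pd.DataFrame, list[int]]:
    """Roll an agent through an experiment, producing a tidy behavior log.

    ``depth_policy`` supplies, per mini-block, either a depth in {1, 2, 3}
    or a simplex over depths to sample from; depth 3 in a 2-step block is
    rejected.  The environment steps with the TRUE success probabilities
    while the agent plans with its evolving belief, which is updated after
    every executed jump.  Fuel carries across mini-blocks.

    Returns the log and the list of realized depths (one per mini-block).
    """
    belief = initial_belief
    fuel = initial_fuel
    records = []
    depths: list[int] = []
    for block in experiment:
        depth = _resolve_depth(block, depth_policy, rng)
        depths.append(depth)
        state = State(position=block.start_position, fuel=fuel, steps_remaining=block.n_steps)
        for trial in range(block.n_steps):
            horizon_depth = depth
            q = q_values(config, block, state.position, state.steps_remaining, belief, horizon_depth)
            p_jump = choice_probability(q, params)
            action = "jump" if rng.random() < p_jump else "move"
            position_before = state.position
            state, outcome = apply_action(config, block, state, action, rng)
            if outcome.jump_succeeded is not None:
                belief = belief.updated(block.noise, int(outcome.jump_succeeded), params.alpha)
            records.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "phase": block.phase,
                    "miniblock_id": block.id,
                    "trial_index": trial,
                    "noise": block.noise,
                    "n_steps": block.n_steps,
                    "planet_types": ";".join(map(str, block.planet_types)),
                    "start_position": block.start_position,
                    "position_before": position_before,
                    "action": action,
                    "jump_succeeded": outcome.jump_succeeded,
                    "position_after": outcome.next_position,
                    "reward_collected": outcome.reward_collected,
                    "cost_paid": outcome.cost_paid,
                    "fuel_after": state.fuel,
                    "rt_ms": np.nan,
                }
            )
        fuel = state.fuel
    log = pd.DataFrame.from_records(records, columns=BEHAVIOR_COLUMNS)
    return log, depths
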