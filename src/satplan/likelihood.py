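"""Observation model: per-mini-block mixture over planning depths.

Only the *first* choice of each mini-block enters the likelihood (planning
is assumed to happen before the first action).  The likelihood of that
choice is a convex combination of the depth-conditional choice
probabilities, weighted by the latent depth distribution of the block:

    p(a_b | s_b) = sum_d p(d_b = d) p(a_b | s_b, d_b = d),

with the depth-3 weight fixed to zero in 2-step mini-blocks.  The belief
about jump success evolves across blocks by replaying the jump outcomes
observed in the log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .agents import AgentParams, Belief, choice_probability, delta_q_batch, q_values
from .config import ConfigError, MiniBlock, TaskConfig


class DataError(ValueError):
    """Raised when a behavior log is inconsistent with the experiment."""


@dataclass(frozen=True)
class DepthWeights:
    """Simplex over planning depths {1, 2, 3} for one mini-block."""

    w1: float
    w2: float
    w3: float = 0.0

    def __post_init__(self) -> None:
        w = np.array([self.w1, self.w2, self.w3])
        if (w < -1e-12).any():
            raise ConfigError("depth weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("depth weights must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3])

    def validated_for(self, n_steps: int, renormalize: bool = False) -> np.ndarray:
        """Weights restricted to the feasible depths of an ``n_steps`` block."""
        w = self.as_array()
        if n_steps == 2:
            if self.w3 > 1e-12:
                if not renormalize:
                    raise ConfigError(
                        "depth-3 weight must be zero in a 2-step mini-block"
                    )
                w = w.copy()
                w[2] = 0.0
                w = w / w.sum()
        return w


def first_action_likelihood(
    config: TaskConfig,
    block: MiniBlock,
    belief: Belief,
    params: AgentParams,
    depth: int,
    action: str,
) -> float:
    """Probability of the observed first action under a fixed planning depth."""
    if depth > block.n_steps:
        raise ConfigError(f"depth {depth} infeasible in a {block.n_steps}-step block")
    q = q_values(config, block, block.start_position, block.n_steps, belief, depth)
    p_jump = choice_probability(q, params)
    if action == "jump":
        return p_jump
    if action == "move":
        return 1.0 - p_jump
    raise ConfigError(f"unknown action {action!r}")


def mixture_likelihood(
    config: TaskConfig,
    block: MiniBlock,
    belief: Belief,
    params: AgentParams,
    weights: DepthWeights,
    action: str,
    renormalize: bool = False,
) -> float:
    """Mixture likelihood of the first action (Eq. over feasible depths)."""
    w = weights.validated_for(block.n_steps, renormalize=renormalize)
    total = 0.0
    for depth in range(1, block.n_steps + 1):
        if w[depth - 1] == 0.0:
            continue
        total += w[depth - 1] * first_action_likelihood(
            config, block, belief, params, depth, action
        )
    return float(total)


def first_actions(log: pd.DataFrame) -> pd.DataFrame:
    """First-trial rows of every mini-block, in block order."""
    first = log[log["trial_index"] == 0]
    return first.sort_values("miniblock_id")


def sequence_log_likelihood(
    config: TaskConfig,
    experiment: Sequence[MiniBlock],
    log: pd.DataFrame,
    params: AgentParams,
    weights_per_block: Sequence[DepthWeights],
    initial_belief: Belief = Belief(),
    renormalize: bool = False,
) -> float:
    """Log-likelihood of all first actions, with belief replayed from the log.

    The belief trajectory is deterministic given the log: every observed
    jump outcome (on any trial, not only the first) updates the belief of
    the block's noise condition before subsequent blocks are evaluated.
    """
    if len(log) == 0:
        return 0.0
    blocks = {b.id: b for b in experiment}
    log_ids = set(log["miniblock_id"].unique())
    if not log_ids <= set(blocks):
        raise DataError("behavior log contains mini-block ids not in the experiment")
    belief = initial_belief
    total = 0.0
    by_block = dict(tuple(log.groupby("miniblock_id", sort=True)))
    for block_id in sorted(by_block):
        block = blocks[block_id]
        rows = by_block[block_id].sort_values("trial_index")
        action = str(rows["action"].iloc[0])
        weights = weights_per_block[block_id] if not isinstance(weights_per_block, dict) \
            else weights_per_block[block_id]
        lik = mixture_likelihood(
            config, block, belief, params, weights, action, renormalize=renormalize
        )
        total += np.log(lik)
        for row in rows.itertuples():
            if row.action == "jump":
                belief = belief.updated(block.noise, int(row.jump_succeeded), params.alpha)
    return float(total)


# ---------------------------------------------------------------------------
# Vectorized per-subject data for inference
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """Precomputed arrays for one subject's likelihood evaluation.

    Attributes are arrays over the subject's B mini-blocks in presentation
    order: arrival rewards per position, start position, step count, the
    condition index into ``conditions``, whether the first action was a
    jump, and the ordered jump outcomes per block (for belief replay).
    """

    subject_id: object
    rewards: np.ndarray        # (B, 6)
    start: np.ndarray          # (B,)
    n_steps: np.ndarray        # (B,)
    cond_index: np.ndarray     # (B,) index into conditions
    noise_high: np.ndarray     # (B,) bool
    first_jump: np.ndarray     # (B,) bool
    jump_events: list          # per block: list of (noise_high: int, outcome: int)
    block_ids: np.ndarray      # (B,)
    conditions: list           # [(n_steps, noise), ...]

    @property
    def n_blocks(self) -> int:
        return len(self.block_ids)

    @classmethod
    def from_log(cls, log: pd.DataFrame, config: TaskConfig) -> "SubjectData":
        subjects = log["subject_id"].unique()
        if len(subjects) != 1:
            raise DataError("SubjectData.from_log expects a single subject's log")
        conditions = config.conditions
        cond_lookup = {c: i for i, c in enumerate(conditions)}
        rewards, start, n_steps, cond_index, noise_high = [], [], [], [], []
        first_jump, jump_events, block_ids = [], [], []
        rew = np.asarray(config.planet_type_rewards)
        for block_id, rows in log.sort_values(["miniblock_id", "trial_index"]).groupby(
            "miniblock_id", sort=True
        ):
            r0 = rows.iloc[0]
            types = [int(t) for t in str(r0["planet_types"]).split(";")]
            rewards.append(rew[types])
            start.append(int(r0["start_position"]))
            n_steps.append(int(r0["n_steps"]))
            cond = (int(r0["n_steps"]), str(r0["noise"]))
            if cond not in cond_lookup:
                raise DataError(f"condition {cond} not in the task design")
            cond_index.append(cond_lookup[cond])
            noise_high.append(str(r0["noise"]) == "high")
            first_jump.append(str(r0["action"]) == "jump")
            events = [
                (int(str(r0["noise"]) == "high"), int(row.jump_succeeded))
                for row in rows.itertuples()
                if row.action == "jump"
            ]
            jump_events.append(events)
            block_ids.append(int(block_id))
        return cls(
            subject_id=subjects[0],
            rewards=np.array(rewards),
            start=np.array(start, dtype=int),
            n_steps=np.array(n_steps, dtype=int),
            cond_index=np.array(cond_index, dtype=int),
            noise_high=np.array(noise_high, dtype=bool),
            first_jump=np.array(first_jump, dtype=bool),
            jump_events=jump_events,
            block_ids=np.array(block_ids, dtype=int),
            conditions=conditions,
        )


def replay_beliefs(
    data: SubjectData, alpha: float, initial: tuple[float, float] = (0.5, 0.5)
) -> tuple[np.ndarray, np.ndarray]:
    """Belief (and its alpha-derivative) at each block's first trial.

    Returns ``(rho, drho_dalpha)``, each (B,): the believed success
    probability of the block's own noise condition just before its first
    action, replaying every observed jump outcome in presentation order.
    """
    rho = [float(initial[0]), float(initial[1])]  # [low, high]
    drho = [0.0, 0.0]
    out_rho = np.empty(data.n_blocks)
    out_drho = np.empty(data.n_blocks)
    for b in range(data.n_blocks):
        c = 1 if data.noise_high[b] else 0
        out_rho[b] = rho[c]
        out_drho[b] = drho[c]
        for cond_high, outcome in data.jump_events[b]:
            drho[cond_high] = (1.0 - alpha) * drho[cond_high] + (outcome - rho[cond_high])
            rho[cond_high] += alpha * (outcome - rho[cond_high])
    return out_rho, out_drho


def subject_delta_q(
    data: SubjectData, config: TaskConfig, alpha: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-block, per-depth ``delta Q`` with derivatives for one subject.

    Returns ``(dq, ddq_dalpha, rho)`` with ``dq`` and ``ddq_dalpha`` of shape
    (B, 3).  Depth columns beyond a block's step count are present but unused
    by the mixture (their weights are structurally zero).
    """
    rho, drho = replay_beliefs(data, alpha)
    dq, ddq_drho = delta_q_batch(
        data.rewards,
        data.start,
        rho,
        config.jump_map,
        config.move_cost,
        config.jump_cost,
    )
    return dq, ddq_drho * drho[:, None], rho
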