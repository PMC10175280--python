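"""Task configuration and core data records for the Space Adventure Task (SAT).

The SAT is a sequential decision task on a ring of six planets.  On every
step the player either *moves* clockwise to the next planet (deterministic,
cheap) or *jumps* along a fixed travel pattern to a non-neighbouring planet
(expensive, and successful only with a condition-dependent probability).
Arriving at a planet pays the reward of its planet type; the running fuel
total is carried across mini-blocks.

Everything that defines the rules of the environment lives in
:class:`TaskConfig` so that the analysis machinery is agnostic to the exact
reward magnitudes and jump pattern, which are configurable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

N_PLANETS = 6
N_PLANET_TYPES = 5

#: Stand-in reward values for the five planet types (type id -> fuel units).
#: The analysis is agnostic to the exact magnitudes; these span losses to
#: gains symmetrically and are overridable in any TaskConfig.
DEFAULT_REWARDS = (-20.0, -10.0, 0.0, 10.0, 20.0)

#: Default jump travel pattern: the diametrically opposite planet, which is
#: never the current planet nor one of its ring neighbours.
DEFAULT_JUMP_MAP = tuple((p + 3) % N_PLANETS for p in range(N_PLANETS))

#: 2x2 factorial design: (n_steps, noise), 25 mini-blocks per phase.
DEFAULT_PHASE_DESIGN = (
    ((2, "low"), 25),
    ((2, "high"), 25),
    ((3, "low"), 25),
    ((3, "high"), 25),
)


class ConfigError(ValueError):
    """Raised when a task configuration violates the task rules."""


def ring_neighbours(p: int, n: int = N_PLANETS) -> tuple[int, int]:
    """The two ring neighbours of position ``p`` on an ``n``-cycle."""
    return ((p - 1) % n, (p + 1) % n)


@dataclass(frozen=True)
class TaskConfig:
    """Full rules of the SAT environment.

    Parameters
    ----------
    planet_type_rewards
        Fuel units gained (or lost) on *arrival* at a planet of each of the
        five types.
    move_cost, jump_cost
        Fuel charged for executing each action, regardless of outcome.
    jump_map
        Travel pattern of the jump action: target position for each of the
        six positions.  Targets must be non-neighbouring.
    noise_success
        Jump success probability per noise condition.
    phase_design
        ``(((n_steps, noise), n_blocks), ...)`` for the four experiment
        phases (order before counterbalancing).
    training_blocks_per_condition
        Mini-blocks per condition in the training session.
    discriminability_filter
        If True, generated mini-blocks are resampled until the optimal first
        action differs between planning depths (depth identifiability).
    nondiscriminating_fraction
        Fraction of blocks exempted from the discriminability filter.
    """

    n_planets: int = N_PLANETS
    planet_type_rewards: tuple[float, ...] = DEFAULT_REWARDS
    move_cost: float = 2.0
    jump_cost: float = 5.0
    jump_map: tuple[int, ...] = DEFAULT_JUMP_MAP
    noise_success: dict = field(default_factory=lambda: {"low": 0.9, "high": 0.5})
    phase_design: tuple = DEFAULT_PHASE_DESIGN
    training_blocks_per_condition: int = 5
    discriminability_filter: bool = True
    nondiscriminating_fraction: float = 0.0
    max_resample_attempts: int = 200

    def __post_init__(self) -> None:
        n = self.n_planets
        if n != N_PLANETS:
            raise ConfigError("the task is defined on a ring of six planets")
        if len(self.planet_type_rewards) != N_PLANET_TYPES:
            raise ConfigError("exactly five planet types are required")
        if self.move_cost < 0 or self.jump_cost < 0:
            raise ConfigError("action costs must be nonnegative")
        for cond, p in self.noise_success.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"success probability for {cond!r} not in [0, 1]")
        if len(self.jump_map) != n or not all(0 <= t < n for t in self.jump_map):
            raise ConfigError("jump_map must map each of the 6 positions to a position")
        for p, t in enumerate(self.jump_map):
            if t == p or t in ring_neighbours(p, n):
                raise ConfigError(
                    f"jump target {t} for position {p} must be a non-neighbouring planet"
                )
        if not 0.0 <= self.nondiscriminating_fraction <= 1.0:
            raise ConfigError("nondiscriminating_fraction must be in [0, 1]")
        for (steps, noise), n_blocks in self.phase_design:
            if steps not in (2, 3):
                raise ConfigError("mini-blocks have 2 or 3 steps")
            if noise not in self.noise_success:
                raise ConfigError(f"unknown noise condition {noise!r}")
            if n_blocks <= 0:
                raise ConfigError("phases must contain at least one mini-block")

    # -- condition helpers -------------------------------------------------
    @property
    def conditions(self) -> list[tuple[int, str]]:
        """The (n_steps, noise) conditions in canonical phase order."""
        return [cond for cond, _ in self.phase_design]

    def reward_at(self, planet_types: Sequence[int], position: int) -> float:
        return self.planet_type_rewards[planet_types[position]]

    def action_cost(self, action: str) -> float:
        if action == "move":
            return self.move_cost
        if action == "jump":
            return self.jump_cost
        raise ConfigError(f"unknown action {action!r}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["phase_design"] = [[list(cond), nb] for cond, nb in self.phase_design]
        d["jump_map"] = list(self.jump_map)
        d["planet_type_rewards"] = list(self.planet_type_rewards)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        if "phase_design" in d:
            d["phase_design"] = tuple(
                ((int(s), str(nz)), int(nb)) for (s, nz), nb in d["phase_design"]
            )
        for key in ("jump_map", "planet_type_rewards"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "TaskConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable hash of the full rule set, logged with every output."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class MiniBlock:
    """One self-contained planning problem."""

    id: int
    planet_types: tuple[int, ...]
    start_position: int
    n_steps: int
    noise: str
    phase: int = 0

    def __post_init__(self) -> None:
        if self.n_steps not in (2, 3):
            raise ConfigError("n_steps must be 2 or 3")
        if not 0 <= self.start_position < N_PLANETS:
            raise ConfigError("start_position must be a planet index")
        if len(self.planet_types) != N_PLANETS:
            raise ConfigError("planet_types must list a type for each of 6 planets")
        if not all(0 <= t < N_PLANET_TYPES for t in self.planet_types):
            raise ConfigError("planet type ids must be in 0..4")

    @property
    def condition(self) -> tuple[int, str]:
        return (self.n_steps, self.noise)

    def rewards(self, config: TaskConfig):
        """Arrival reward at each of the six positions."""
        return [config.planet_type_rewards[t] for t in self.planet_types]


@dataclass
class State:
    """Evolving position / fuel / remaining-step state within a mini-block."""

    position: int
    fuel: float
    steps_remaining: int


@dataclass(frozen=True)
class Outcome:
    """Result of one executed action."""

    action: str
    next_position: int
    jump_succeeded: bool | None
    reward_collected: float
    cost_paid: float
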