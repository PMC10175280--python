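"""Synthetic cohorts with the statistical structure the analysis assumes.

Subjects are drawn from group-level distributions of (beta, theta, alpha) in
transformed space; each mini-block's planning depth is drawn from
condition-level Dirichlet weights (or fixed at the maximum feasible depth);
choices are rolled out with the planning agents against the true task
dynamics; reaction times are lognormal with optional coupling to the
assigned depth.  The generating truth is serialized next to the logs so
recovery can be validated end to end.

The default group regimes emulate a younger and an older cohort: the older
group has a lower inverse temperature, a positive (jump-leaning) response
bias, a learning rate closer to zero, and flatter depth weights, giving the
downstream statistics realistic group effects to detect.  They are
stand-ins, not a reproduction of any real sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .agents import AgentParams, Belief, simulate_agent
from .config import MiniBlock, TaskConfig
from .task import generate_experiment


@dataclass(frozen=True)
class RTSpec:
    """Lognormal reaction-time model: log RT ~ Normal(loc + coupling*(d-2), scale)."""

    loc_log_ms: float = np.log(6000.0)
    scale: float = 0.5
    depth_coupling: float = 0.15


@dataclass
class GroupSpec:
    """Generating distributions for one group of synthetic subjects.

    Locations/scales are in transformed space: ``beta`` lognormal,
    ``theta`` normal, ``alpha`` logit-normal.  ``depth_conc`` maps each
    (n_steps, noise) condition to a Dirichlet concentration vector over the
    feasible depths; per-block weights are drawn from it and the block's
    depth from those weights.  ``depth_policy="max"`` instead fixes every
    block's depth at the maximum feasible depth (an idealised deep planner,
    used for depth-recovery runs); ``"min"`` fixes it at depth 1.
    """

    label: str
    n_subjects: int
    beta_loc: float
    beta_scale: float
    theta_loc: float
    theta_scale: float
    alpha_loc: float
    alpha_scale: float
    depth_conc: dict = field(default_factory=dict)
    depth_policy: str = "weights"
    rt: RTSpec = field(default_factory=RTSpec)
    covariates: dict = field(default_factory=dict)  # name -> (loc, scale)
    fixed_params: dict = field(default_factory=dict)  # param -> value (overrides draw)

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for s in (self.beta_scale, self.theta_scale, self.alpha_scale):
            if s < 0:
                raise ValueError("scales must be nonnegative")
        if self.depth_policy not in ("weights", "max", "min"):
            raise ValueError("depth_policy must be 'weights', 'max' or 'min'")


def younger_spec(n_subjects: int = 25) -> GroupSpec:
    """Default younger-adult regime (higher beta, move bias, deeper planning)."""
    return GroupSpec(
        label="younger",
        n_subjects=n_subjects,
        beta_loc=0.498, beta_scale=0.425,    # lognormal ~ mean 1.8, sd 0.8
        theta_loc=-0.2, theta_scale=0.3,
        alpha_loc=-3.0, alpha_scale=1.0,     # alpha close to zero
        depth_conc={
            (2, "low"): (1.0, 3.0),
            (2, "high"): (1.0, 3.0),
            (3, "low"): (1.0, 3.5, 5.5),
            (3, "high"): (1.0, 3.5, 5.5),
        },
        rt=RTSpec(loc_log_ms=np.log(6200.0), scale=0.5, depth_coupling=0.15),
        covariates={"idp_pct": (65.7, 9.3), "swm_pct": (91.2, 7.3)},
    )


def older_spec(n_subjects: int = 27) -> GroupSpec:
    """Default older-adult regime (lower beta, jump-leaning bias, shallower)."""
    return GroupSpec(
        label="older",
        n_subjects=n_subjects,
        beta_loc=0.033, beta_scale=0.352,    # lognormal ~ mean 1.1, sd 0.4
        theta_loc=0.2, theta_scale=0.6,
        alpha_loc=-3.5, alpha_scale=0.75,
        depth_conc={
            (2, "low"): (4.5, 5.5),
            (2, "high"): (4.5, 5.5),
            (3, "low"): (2.5, 4.5, 3.0),
            (3, "high"): (2.5, 4.5, 3.0),
        },
        rt=RTSpec(loc_log_ms=np.log(4600.0), scale=0.5, depth_coupling=0.15),
        covariates={"idp_pct": (45.8, 9.5), "swm_pct": (74.6, 22.1)},
    )


@dataclass
class CohortTruth:
    """Generating ground truth serialized alongside the behavior logs."""

    params: pd.DataFrame   # subject_id, group, beta, theta, alpha
    depths: pd.DataFrame   # subject_id, miniblock_id, depth
    seed: int
    config_hash: str

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.params.to_csv(outdir / "truth_params.csv", index=False)
        self.depths.to_csv(outdir / "truth_depths.csv", index=False)
        with open(outdir / "truth_meta.yaml", "w") as fh:
            yaml.safe_dump({"seed": self.seed, "config_hash": self.config_hash}, fh)

    @classmethod
    def load(cls, outdir) -> "CohortTruth":
        outdir = Path(outdir)
        with open(outdir / "truth_meta.yaml") as fh:
            meta = yaml.safe_load(fh)
        return cls(
            params=pd.read_csv(outdir / "truth_params.csv"),
            depths=pd.read_csv(outdir / "truth_depths.csv"),
            seed=int(meta["seed"]),
            config_hash=str(meta["config_hash"]),
        )


def _draw_depth_policy(
    spec: GroupSpec, experiment: Sequence[MiniBlock], rng: np.random.Generator
) -> dict[int, int]:
    policy: dict[int, int] = {}
    for block in experiment:
        if spec.depth_policy == "max":
            policy[block.id] = min(block.n_steps, 3)
            continue
        if spec.depth_policy == "min":
            policy[block.id] = 1
            continue
        conc = np.asarray(spec.depth_conc[block.condition], dtype=float)
        if conc.size != min(block.n_steps, 3):
            raise ValueError(
                f"concentration for condition {block.condition} must have "
                f"{min(block.n_steps, 3)} entries"
            )
        w = rng.dirichlet(conc)
        policy[block.id] = int(rng.choice(np.arange(1, conc.size + 1), p=w))
    return policy


def sample_cohort(
    config: TaskConfig,
    group_specs: Sequence[GroupSpec],
    seed: int,
    initial_belief: Belief = Belief(),
    contamination_fraction: float = 0.0,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Simulate a full cohort; returns (behavior log, generating truth).

    Every subject sees the same per-condition mini-block pool (layouts drawn
    from ``seed``), with phase order counterbalanced by participant index.
    The behavior log is byte-identical under the same seed and specs.
    """
    rng = np.random.default_rng(seed)
    logs = []
    param_rows = []
    depth_rows = []
    participant_index = 0
    for spec in group_specs:
        for i in range(spec.n_subjects):
            subject_id = f"{spec.label}_{i:02d}"
            lb = spec.beta_loc + spec.beta_scale * rng.standard_normal()
            th = spec.theta_loc + spec.theta_scale * rng.standard_normal()
            la = spec.alpha_loc + spec.alpha_scale * rng.standard_normal()
            beta = float(spec.fixed_params.get("beta", np.exp(lb)))
            theta = float(spec.fixed_params.get("theta", th))
            alpha = float(spec.fixed_params.get("alpha", expit(la)))
            params = AgentParams(beta=beta, theta=theta, alpha=alpha)
            experiment = generate_experiment(config, seed, participant_index)
            policy = _draw_depth_policy(spec, experiment, rng)
            log, depths = simulate_agent(
                config,
                experiment,
                params,
                policy,
                rng,
                initial_belief=initial_belief,
                subject_id=subject_id,
                group=spec.label,
            )
            log = inject_rt(
                log,
                spec.rt,
                rng=rng,
                contamination_fraction=contamination_fraction,
                block_depths=policy,
            )
            for name, (loc, scale) in spec.covariates.items():
                log[name] = loc + scale * rng.standard_normal()
            logs.append(log)
            param_rows.append(
                {
                    "subject_id": subject_id,
                    "group": spec.label,
                    "beta": beta,
                    "theta": theta,
                    "alpha": alpha,
                }
            )
            depth_rows.extend(
                {"subject_id": subject_id, "miniblock_id": bid, "depth": d}
                for bid, d in sorted(policy.items())
            )
            participant_index += 1
    behavior = pd.concat(logs, ignore_index=True)
    truth = CohortTruth(
        params=pd.DataFrame(param_rows),
        depths=pd.DataFrame(depth_rows),
        seed=seed,
        config_hash=config.config_hash(),
    )
    return behavior, truth


def inject_rt(
    log: pd.DataFrame,
    rt_spec: RTSpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    contamination_fraction: float = 0.0,
    block_depths: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Fill the rt_ms column with lognormal reaction times.

    ``block_depths`` (block id -> assigned depth) enables the positive
    depth-RT coupling; ``contamination_fraction`` of trials get fast-guess
    RTs drawn uniformly below 150 ms, to exercise the outlier filter.
    """
    if not 0.0 <= contamination_fraction <= 1.0:
        raise ValueError("contamination fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    log = log.copy()
    depth_term = np.zeros(len(log))
    if block_depths is not None and rt_spec.depth_coupling != 0.0:
        depths = log["miniblock_id"].map(block_depths).to_numpy(dtype=float)
        depth_term = rt_spec.depth_coupling * (depths - 2.0)
    rt = np.exp(
        rt_spec.loc_log_ms + depth_term + rt_spec.scale * rng.standard_normal(len(log))
    )
    fast = rng.random(len(log)) < contamination_fraction
    rt[fast] = rng.uniform(0.0, 149.0, size=int(fast.sum()))
    log["rt_ms"] = rt
    return log


def _plain(obj):
    """Recursively cast numpy scalars so YAML serialization stays plain."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def spec_to_dict(spec: GroupSpec) -> dict:
    d = asdict(spec)
    d["depth_conc"] = {f"{k[0]}_{k[1]}": list(v) for k, v in spec.depth_conc.items()}
    return _plain(d)


def specs_to_yaml(specs: Sequence[GroupSpec], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([spec_to_dict(s) for s in specs], fh)


def specs_from_yaml(path) -> list[GroupSpec]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for d in raw:
        conc = {}
        for key, v in d.get("depth_conc", {}).items():
            steps, noise = key.split("_")
            conc[(int(steps), noise)] = tuple(float(x) for x in v)
        d["depth_conc"] = conc
        d["rt"] = RTSpec(**d["rt"]) if "rt" in d else RTSpec()
        d["covariates"] = {k: tuple(v) for k, v in d.get("covariates", {}).items()}
        specs.append(GroupSpec(**d))
    return specs
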