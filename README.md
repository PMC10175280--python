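# satplan

Simulation and hierarchical Bayesian inference of **planning depth** in the
Space Adventure Task (SAT), a sequential decision task used to study
model-based forward planning — for example, how far ahead younger versus
older adults plan.

The SAT places a spaceship on a ring of six planets.  On each of 2 or 3
steps per mini-block the player *moves* clockwise (cost 2 fuel units,
deterministic) or *jumps* to a fixed non-neighbouring planet (cost 5 units;
succeeds with probability 0.9 under low noise, 0.5 under high noise, else
lands on a neighbour of the target).  Arriving at a planet pays its type's
reward; fuel carries across the 100 mini-blocks of an experiment.

Behaviour is modelled as a mixture of depth-limited value-iteration agents.
An agent of depth *d* computes

    Q_d(s, a) = -cost(a) + Σ_s' p_ρ(s'|s, a) [ r(s') + V_{d-1}(s') ],
    V_0 = 0,   V_k(s) = max_a Q_k(s, a),

with ρ its learned belief about jump success (delta rule with learning rate
α), and chooses `p(jump) = σ(β ΔQ + θ)` with inverse temperature β and
response bias θ.  Planning depth is latent per mini-block: the first choice
of block *b* has likelihood `p(a_b|s_b) = Σ_d p(d_b = d) p(a_b|s_b, d)`,
with depth 3 excluded in 2-step blocks.  Depth weights follow a Dirichlet
hierarchy per steps-by-noise condition; (β, θ, α) follow Normal group
hierarchies in transformed space.  Inference is stochastic variational
inference with analytic gradients; per-block depth posteriors and
subject-parameter credible intervals come from exact conditional
(Rao-Blackwellized) computations given the posterior draws — see
`docs/methods.md` for the model, priors, and numerical choices.

The package contains everything needed to exercise the full analysis
without any external data: the task simulator (`satplan.task`), the
planning agents (`satplan.agents`), the mixture likelihood
(`satplan.likelihood`), the hierarchical model with an exact small-instance
oracle (`satplan.model`), a synthetic-cohort generator (`satplan.cohort`),
and the downstream statistics (`satplan.stats`).

## Worked example

Simulate a small two-group cohort at known parameters, fit the hierarchical
model, and compare groups:

```python
from satplan import TaskConfig, PlanningDepthModel
from satplan.cohort import younger_spec, older_spec, sample_cohort
from satplan.model import FitSettings
from satplan.stats import group_compare, performance_percentage

config = TaskConfig()
behavior, truth = sample_cohort(config, [younger_spec(5), older_spec(5)], seed=42)

model = PlanningDepthModel(behavior, config)
results = model.fit(FitSettings(steps=2000, learning_rate=0.05, seed=0))

summaries = results.mean_depth().merge(
    performance_percentage(behavior, config)[["subject_id", "group", "performance_pct"]]
)
print(results.summary())
print(summaries.groupby("group")[["mean_depth", "performance_pct"]].mean().round(2))
test = group_compare(summaries, "mean_depth")
print(f"mean depth, younger vs older: t = {test.t_statistic:.2f}, p = {test.t_p_value:.4f}")
```

This prints (abridged):

```
Planning-depth mixture model (variational fit)
====================================================
subjects: 10   mini-blocks: 1000
SVI steps: 2000   seed: 0   final ELBO: -563.1

Subject posterior means:
param       beta  theta  alpha  mean_depth
subject_id
older_00   2.369 -0.473  0.054       1.797
...
younger_04 3.182 -0.238  0.213       1.958

         mean_depth  performance_pct
group
older          1.83           -29.19
younger        2.02             4.87

mean depth, younger vs older: t = -8.03, p = 0.0000
```

The generated younger group plans deeper (mean depth 2.02 vs 1.83, a
planted effect the fit recovers, here significant at t = −8.0) and scores
a higher percentage of the maximum possible fuel.  Absolute percentages
depend on the configured planet rewards — the defaults are documented
stand-ins, and low-β (noisy) agents can lose fuel overall, hence negative
values for the older group.  `results.depth_posterior()` gives per-block
depth distributions, `results.subject_params()` posterior means with 95%
credible intervals, and `results.recovery_report(truth.params,
truth.depths)` the recovery diagnostics when the generating truth is known.

The same workflow is scriptable from a shell:

```sh
satplan simulate-cohort --seed 1 --out cohort/
satplan infer --behavior cohort/behavior.csv --out posterior/ --seed 0
satplan analyze --posterior posterior/ --behavior cohort/behavior.csv --out report/
```

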