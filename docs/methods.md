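# Methods

## The task

The Space Adventure Task (SAT) is a finite-horizon sequential decision task
on a ring of six planets, each of one of five types with a fixed arrival
reward.  On each of 2 or 3 steps of a mini-block the player either *moves*
clockwise (cost 2 fuel units, deterministic) or *jumps* along a fixed travel
pattern to a non-neighbouring planet (cost 5 units).  A jump succeeds with
probability 0.9 in the low-noise condition and 0.5 in the high-noise
condition; on failure the ship lands on one of the two ring neighbours of
the target, each with probability 1/2.  Fuel is the running score and is
carried across mini-blocks.  An experiment is 100 mini-blocks in four
25-block phases crossing steps {2, 3} with noise {low, high}; phase order is
counterbalanced across participants by a Latin square; a training session
has 5 mini-blocks per condition.

Two pieces of the original design are not recoverable from the printed
description and are therefore configuration, not constants:

* **Reward magnitudes of the five planet types.** The default
  `(-20, -10, 0, +10, +20)` is a stand-in spanning losses to gains; every
  analysis is agnostic to the set, and tests parameterize on the config.
* **Jump travel pattern.**  The only stated constraint is that targets are
  non-neighbouring; the default is the diametric map `p -> (p+3) mod 6`.

A consequence of the symmetric stand-in rewards: on very small block pools
the summed optimal expected score can be non-positive, in which case the
performance percentage is flagged (`denominator_valid=False`) rather than
silently NaN.  On the default 100-block design the denominator is
comfortably positive.

Mini-block layouts are sampled uniformly and passed through a
*discriminability filter*: a layout is accepted only if a fully informed
agent's optimal first action differs between planning depths 1..n_steps
(resampling up to 200 attempts; a configurable fraction of
non-discriminating blocks can be retained).  This mirrors the design goal
that the problems require forward planning, and it is what makes the latent
depth identifiable from first choices.

## The agent model

An agent with planning depth d computes finite-horizon Q-values by value
iteration,

    Q_d(s, a) = -cost(a) + sum_s' p_rho(s' | s, a) [ r(s') + V_{d-1}(s') ],
    V_0 = 0,  V_k(s) = max_a Q_k(s, a),

where the jump transition uses the agent's *believed* success probability
rho of the current noise condition (the environment itself always uses the
true probability).  The horizon is truncated to the steps remaining in the
mini-block.  Choices follow a sigmoid of the Q-value difference,

    p(jump) = sigma(beta * (Q(jump) - Q(move)) + theta),

with inverse temperature beta >= 0 and response bias theta (negative values
favour the deterministic move).  After every executed jump the belief of
the block's noise condition is updated by the delta rule
`rho <- rho + alpha * (o - rho)` with learning rate alpha in [0, 1] and
outcome o in {0, 1}; beliefs start at 0.5 for both conditions, and one
alpha is shared across conditions.  Beliefs are updated on every executed
jump of every trial, although only first actions enter the likelihood:
experience accrues on all trials.

## Observation model

Planning depth is latent at the mini-block level.  Only the first choice of
each block is modelled (planning is assumed to happen before the first
action):

    p(a_b | s_b) = sum_d p(d_b = d) p(a_b | s_b, d_b = d),

with the depth-3 weight structurally zero in 2-step blocks (a hard error by
default; a renormalize flag exists for robustness runs).  Between blocks
the belief trajectory is replayed deterministically from the observed jump
outcomes in the log.

## Hierarchical model and inference

Subject parameters live in transformed space x = (log beta, theta,
logit alpha).  Per cohort group (e.g. younger/older — the hierarchy exists
precisely to capture within-group similarity):

* group locations mu ~ Normal(0, 1) and scales sigma ~ half-Normal(1);
* subject parameters x_i ~ Normal(mu, sigma);
* group-level log-concentration means g_c ~ Normal(0, 2) per
  steps-by-noise condition (centred on the uniform Dirichlet), and
  per-subject log-concentrations h_ic ~ Normal(g_c, 0.5);
* per-block depth weights w_b ~ Dirichlet(exp(h_ic)) restricted to feasible
  depths, and the first action from the mixture above.

Because the mixture likelihood is linear in w_b, the block weights
marginalize in closed form: the likelihood depends on the concentrations
only through the mean weights m_c = softmax(h_ic), and the depth posterior
of a block conditional on the continuous latents is exactly
`p(d | a_b) ∝ m_d p(a_b | d)`.  This collapse makes the per-block latent
space disappear from the optimization without approximation.

The remaining continuous posterior is approximated by stochastic
variational inference with reparameterized gradients and an Adam optimizer
(defaults: 2000 steps, learning rate 0.05, 1 Monte-Carlo sample; all
config-exposed).  The gradient of the log-joint is computed analytically,
including the learning-rate path: d(rho)/d(alpha) through the belief replay
and d(DeltaQ)/d(rho) through the value-iteration recursion (subgradient at
the max).  The guide is Gaussian with a full 3x3 covariance block per
subject's (log beta, theta, logit alpha) — these are strongly correlated in
the posterior — and independent factors elsewhere.  The entire fit is
deterministic given the seed.

Reported subject-parameter marginals are **Rao-Blackwellized**: for a
subset of posterior draws of the depth weights and group hyperparameters,
the exact 3-D conditional posterior of the subject block (hierarchical
prior times likelihood) is evaluated on a transformed-space grid
(41 x 41 x 21 over log beta in [-4, 4], theta in [-4, 4], logit alpha in
[-9, 5]; 16 draws) and averaged; means, sds and central 95% credible
intervals come from the resulting marginals.  This matters for
near-deterministic subjects, whose likelihood in beta is one-sided and
flat to the right: a Gaussian factor truncates that tail (we measured a
~30% marginal-sd shortfall against the exact grid oracle), while the
conditional marginals retain it.  The Gaussian-guide summaries remain
available (`subject_params(method="gaussian")`).

An exact brute-force oracle (`exact_posterior`) computes the grid posterior
of a single subject's three parameters under fixed uniform depth weights
and a fixed prior, by direct summation; it is restricted to at most 20
mini-blocks and is used to validate the variational depth posteriors
(total variation at most 0.15 per block on such instances) and the
marginal widths.

### Identifiability

* Depth is identifiable only through first actions on discriminating
  blocks, pooled within condition by the concentration hierarchy.  With
  beta = 0 (value-insensitive choices) depth recovery collapses to chance,
  and the fitted mixture tends to prefer the depth with the smallest
  |DeltaQ| — an expected property of mixtures fitted to uninformative
  choices, exercised in the tests.
* theta is weakly identified at realistic between-subject spreads (sd
  0.3–0.6): with ~100 binary first choices its posterior uncertainty is of
  the same order as its spread, and it partially trades off against beta
  and the depth weights.  In recovery studies the rank correlation between
  generating and recovered theta is low (~0.1–0.25) while beta and alpha
  recover well (Spearman ~0.7–0.95); credible-interval coverage is
  nevertheless calibrated for all three.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
subjects drawn from group regimes in transformed space, per-block depths
from condition-level Dirichlet-categorical draws (or fixed at the maximum
feasible depth for idealised deep planners, or at depth 1), rollouts
against the true dynamics with fuel carry-over, and lognormal reaction
times with an optional positive coupling to the assigned depth plus a
configurable fraction of sub-150-ms fast guesses (for the outlier filter).

Default regimes are anchored to published group summaries of younger and
older adults: beta lognormal with natural-scale mean/sd approximately
1.8/0.8 (younger) and 1.1/0.4 (older); theta Normal(-0.2, 0.3) vs
Normal(+0.2, 0.6); alpha logit-Normal(-3, 1) vs (-3.5, 0.75), i.e. close to
zero; and depth concentrations chosen so the expected mean planning depth
is about 2.1 (younger) vs 1.8 (older) with a positive steps effect in both
groups.  These are generating conditions for validation, not a reproduction
of any real sample; the generator does not emulate real participants'
block sequences, motor RT distributions, or any neuropsychological task —
covariate columns are plain Gaussian stand-ins for exercising the
regression interface.  Passing recovery tests therefore demonstrates that
the inference machinery works under the model's own assumptions, not that
the model is correct for real behaviour.

## Downstream statistics

Performance is the achieved percentage of the maximum possible fuel score;
the denominator is the sum over mini-blocks of the optimal policy's
*expected* score under the true success probabilities (computed by backward
recursion; an optimistic jumps-always-succeed variant is available behind a
flag, since the original definition is not printed).  Mini-blocks with
reaction times under 150 ms can be excluded (trial- or block-level).
Group comparisons use Student's t with Shapiro-Wilk-triggered
Mann-Whitney-U and Levene-triggered Welch fallbacks, always reporting the
plain t alongside.  Performance is regressed on (mean depth, alpha, beta,
theta) by OLS with standardized coefficients and a condition-number
collinearity flag.  An optional linear mixed model regresses
subject-by-condition mean depth on group, noise, steps and the
group-by-condition interactions with a random intercept and noise/steps
slopes per subject; singular or non-converged fits are reported, not fatal.

## Problem sizes and seeds

All randomness flows through explicit integer seeds; the simulator,
generator and fit are bit-reproducible.  The recovery studies run at a
reduced scale chosen as the smallest that exercises the full pipeline
meaningfully: ~20 subjects with full 100-block experiments, 2000–3000 SVI
steps and 100 posterior draws for the headline validations; 4–10 subjects,
12–48 blocks and a few hundred steps for unit-level checks; single
subjects with at most 20 blocks for the exact-oracle comparisons.

## Known limitations

* Mean-field/block variational approximations can still underestimate
  joint uncertainty across subjects and hyperparameters; only the
  within-subject block is Rao-Blackwellized exactly.
* The likelihood ignores non-first actions, discarding information that
  could sharpen beta and alpha.
* The exact supplementary prior specification of the original analysis is
  not public; all prior choices here are explicit and config-exposed, so
  numeric posterior values are not comparable to the original beyond the
  validation protocol itself.
* theta recovery is rank-unstable at realistic spreads (see
  Identifiability); group-level theta contrasts remain detectable.
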