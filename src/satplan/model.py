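"""Hierarchical Bayesian inference of planning depth and choice parameters.

The generative model, top down:

* group level: locations ``mu`` and scales ``sigma`` for the transformed
  subject parameters (log beta, theta, logit alpha), with Normal(0, 1)
  location priors and half-Normal(1) scale priors; group-level
  log-concentration means ``g`` (one vector per steps-by-noise condition,
  Normal(0, 1), i.e. centred on the uniform Dirichlet);
* subject level: transformed parameters ``x_i ~ Normal(mu, sigma)``;
  per-condition log-concentrations ``h_ic ~ Normal(g_c, tau)`` with a fixed
  between-subject scale ``tau``;
* mini-block level: depth weights ``w_b ~ Dirichlet(exp(h_ic))`` restricted
  to the feasible depths (no depth 3 in 2-step blocks), and the observed
  first action with the depth-mixture likelihood.

Because the mixture likelihood is *linear* in ``w_b``, the per-block weights
integrate out in closed form: the marginal likelihood only involves the
Dirichlet mean weights ``m_c = softmax(h_ic)``, and the depth posterior of a
block conditional on the continuous latents is exactly

    p(d_b = d | a_b, ...) = m_d p(a_b | d) / sum_d' m_d' p(a_b | d').

Inference over the remaining continuous latents uses stochastic variational
inference with a Gaussian guide in transformed space -- a full 3x3
covariance block per subject's (log beta, theta, logit alpha), which are
strongly correlated in the posterior, and independent factors elsewhere --
with reparameterized gradients; the gradient of the log-joint is computed
analytically (including the learning-rate path through the belief replay and
the value-iteration recursion).  Reported subject-parameter marginals are
Rao-Blackwellized: exact grid conditionals of the subject block averaged
over posterior draws of the other latents, which preserves the heavy or
one-sided tails that a Gaussian factor would truncate.  A brute-force grid
posterior over a single subject's parameters serves as an exact
small-instance oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import TaskConfig
from .likelihood import DataError, SubjectData, subject_delta_q

PARAM_NAMES = ("beta", "theta", "alpha")
_P_FLOOR = 1e-12


class FitError(RuntimeError):
    """Raised when the variational objective becomes non-finite."""


def _softmax(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max())
    return e / e.sum()


def to_natural(x: np.ndarray) -> np.ndarray:
    """Map (log beta, theta, logit alpha) to (beta, theta, alpha)."""
    x = np.asarray(x, dtype=float)
    out = x.copy()
    out[..., 0] = np.exp(x[..., 0])
    out[..., 2] = expit(x[..., 2])
    return out


class _Layout:
    """Index bookkeeping for the flattened latent vector.

    Group-level blocks (locations, log-scales, log-concentration means) are
    replicated per group so that each group gets its own hyperparameters;
    subject blocks hold the transformed parameters and, when depth weights
    are learned, the per-condition log-concentrations.
    """

    def __init__(self, n_subjects: int, k_list: Sequence[int],
                 hierarchical: bool, learn_weights: bool,
                 n_groups: int = 1) -> None:
        self.n_subjects = n_subjects
        self.k_list = list(k_list)
        self.K = sum(k_list)
        self.hierarchical = hierarchical
        self.learn_weights = learn_weights
        self.n_groups = n_groups
        self.group_block = (6 if hierarchical else 0) + (self.K if learn_weights else 0)
        self.subj0 = n_groups * self.group_block
        self.per_subject = 3 + (self.K if learn_weights else 0)
        self.dim = self.subj0 + n_subjects * self.per_subject
        self.cond_slices = []
        a = 0
        for k in k_list:
            self.cond_slices.append(slice(a, a + k))
            a += k

    def mu(self, j: int) -> slice:
        a = j * self.group_block
        return slice(a, a + 3)

    def s(self, j: int) -> slice:
        a = j * self.group_block + 3
        return slice(a, a + 3)

    def g(self, j: int) -> slice:
        a = j * self.group_block + (6 if self.hierarchical else 0)
        return slice(a, a + self.K)

    def x(self, i: int) -> slice:
        a = self.subj0 + i * self.per_subject
        return slice(a, a + 3)

    def h(self, i: int) -> slice:
        a = self.subj0 + i * self.per_subject + 3
        return slice(a, a + self.K)


class _Adam:
    def __init__(self, dim: int, lr: float) -> None:
        self.lr = lr
        self.m = np.zeros(dim)
        self.v = np.zeros(dim)
        self.t = 0

    def step(self, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = 0.9 * self.m + 0.1 * grad
        self.v = 0.999 * self.v + 0.001 * grad**2
        mhat = self.m / (1 - 0.9**self.t)
        vhat = self.v / (1 - 0.999**self.t)
        return params + self.lr * mhat / (np.sqrt(vhat) + 1e-8)


@dataclass
class FitSettings:
    """Knobs of the variational optimisation."""

    steps: int = 2000
    learning_rate: float = 0.05
    n_posterior_samples: int = 100
    seed: int = 0
    n_mc: int = 1

    def __post_init__(self) -> None:
        if min(self.steps, self.n_posterior_samples, self.n_mc) < 1:
            raise ValueError("fit settings must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


class PlanningDepthModel:
    """Hierarchical depth-mixture choice model, built from a behavior log.

    Parameters
    ----------
    data
        Tidy behavior log (one row per trial) covering one or more subjects.
    config
        The task rules the log was generated under.
    hierarchical
        Pool subjects through learned group-level locations/scales.  With
        ``False`` the subject-parameter prior is fixed at
        ``Normal(prior_loc, prior_scale)`` (used by the small-instance grid
        oracle mode).
    learn_weights
        Infer condition-level depth-weight concentrations.  With ``False``
        the depth weights are fixed uniform over feasible depths.
    prior_loc, prior_scale
        Location/scale of the (hyper)priors of (log beta, theta, logit alpha).
    conc_scale
        Fixed between-subject scale of the log-concentrations.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        config: TaskConfig,
        hierarchical: bool = True,
        learn_weights: bool = True,
        prior_loc: Sequence[float] = (0.0, 0.0, 0.0),
        prior_scale: Sequence[float] = (1.0, 1.0, 1.0),
        conc_scale: float = 0.5,
        conc_prior_scale: float = 2.0,
    ) -> None:
        if len(data) == 0:
            raise DataError("empty behavior log")
        self.config = config
        self.data = data
        self.subjects = []
        subject_groups = []
        for sid, g in data.groupby("subject_id", sort=True):
            self.subjects.append(SubjectData.from_log(g, config))
            label = str(g["group"].iloc[0]) if "group" in g.columns else ""
            subject_groups.append(label)
        self.subject_ids = [s.subject_id for s in self.subjects]
        # separate group-level hyperparameters per cohort group (within-group
        # similarity is the point of the hierarchy)
        self.group_labels = sorted(set(subject_groups))
        self.group_of_subject = [
            self.group_labels.index(lbl) for lbl in subject_groups
        ]
        self.conditions = config.conditions
        self.k_list = [min(steps, 3) for steps, _ in self.conditions]
        self.hierarchical = hierarchical
        self.learn_weights = learn_weights
        self.prior_loc = np.asarray(prior_loc, dtype=float)
        self.prior_scale = np.asarray(prior_scale, dtype=float)
        self.conc_scale = float(conc_scale)
        self.conc_prior_scale = float(conc_prior_scale)
        self._layout = _Layout(
            len(self.subjects), self.k_list, hierarchical, learn_weights,
            n_groups=len(self.group_labels),
        )

    @classmethod
    def from_csv(cls, path, config: TaskConfig, **kw) -> "PlanningDepthModel":
        return cls(pd.read_csv(path), config, **kw)

    # -- likelihood --------------------------------------------------------
    def _mixture_weights(self, h: np.ndarray | None) -> list[np.ndarray]:
        """Per-condition mean depth weights (padded to length 3)."""
        out = []
        for c, k in enumerate(self.k_list):
            m = np.zeros(3)
            if h is None:
                m[:k] = 1.0 / k
            else:
                m[:k] = _softmax(h[self._layout.cond_slices[c]])
            out.append(m)
        return out

    def _subject_loglik_grad(
        self, sdata: SubjectData, x: np.ndarray, m_list: list[np.ndarray]
    ):
        """Log-likelihood of one subject's first actions and its gradients.

        Returns ``(L, grad_x, grad_h)`` where ``grad_h`` is aligned with the
        concatenated per-condition log-concentration vector (None when
        weights are fixed).
        """
        lb, th, la = x
        beta = np.exp(lb)
        alpha = expit(la)
        dq, ddq_da, _ = subject_delta_q(sdata, self.config, alpha)
        y = beta * dq + th
        pj = expit(y)
        jump = sdata.first_jump[:, None]
        p = np.where(jump, pj, 1.0 - pj)
        p = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
        sign = np.where(jump, 1.0, -1.0)
        M = np.stack([m_list[c] for c in sdata.cond_index])  # (B, 3)
        P = (M * p).sum(axis=1)
        L = float(np.log(P).sum())
        dLdy = M * (p * (1.0 - p) * sign) / P[:, None]
        g_lb = float((dLdy * (beta * dq)).sum())
        g_th = float(dLdy.sum())
        g_la = float((dLdy * (beta * ddq_da)).sum() * alpha * (1.0 - alpha))
        grad_h = None
        if self.learn_weights:
            grad_h = np.zeros(self._layout.K)
            for c, cs in enumerate(self._layout.cond_slices):
                mask = sdata.cond_index == c
                if not mask.any():
                    continue
                k = self.k_list[c]
                mc = m_list[c][:k]
                contrib = mc * (p[mask, :k] - P[mask, None]) / P[mask, None]
                grad_h[cs] = contrib.sum(axis=0)
        return L, np.array([g_lb, g_th, g_la]), grad_h

    def log_joint_and_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        """Unnormalized log joint density and its gradient at latent ``z``."""
        lay = self._layout
        grad = np.zeros(lay.dim)
        lp = 0.0
        mus, sigs, gs = [], [], []
        for j in range(lay.n_groups):
            if self.hierarchical:
                mu = z[lay.mu(j)]
                s = z[lay.s(j)]
                sig = np.exp(s)
                r0 = (mu - self.prior_loc) / self.prior_scale
                lp += float(-0.5 * (r0**2).sum())
                grad[lay.mu(j)] += -r0 / self.prior_scale
                # half-Normal(1) prior on sigma, with log-Jacobian of sigma=exp(s)
                lp += float((-0.5 * np.exp(2 * s) + s).sum())
                grad[lay.s(j)] += -np.exp(2 * s) + 1.0
            else:
                mu = self.prior_loc
                sig = self.prior_scale
            g = None
            if self.learn_weights:
                g = z[lay.g(j)]
                cps = self.conc_prior_scale
                lp += float(-0.5 * ((g / cps) ** 2).sum())
                grad[lay.g(j)] += -g / cps**2
            mus.append(mu)
            sigs.append(sig)
            gs.append(g)
        for i, sdata in enumerate(self.subjects):
            j = self.group_of_subject[i]
            mu, sig, g = mus[j], sigs[j], gs[j]
            x = z[lay.x(i)]
            r = (x - mu) / sig
            lp += float(-0.5 * (r**2).sum() - np.log(sig).sum())
            grad[lay.x(i)] += -r / sig
            if self.hierarchical:
                grad[lay.mu(j)] += r / sig
                grad[lay.s(j)] += r**2 - 1.0
            h = None
            if self.learn_weights:
                h = z[lay.h(i)]
                d = (h - g) / self.conc_scale
                lp += float(-0.5 * (d**2).sum())
                grad[lay.h(i)] += -d / self.conc_scale
                grad[lay.g(j)] += d / self.conc_scale
            m_list = self._mixture_weights(h)
            L, gx, gh = self._subject_loglik_grad(sdata, x, m_list)
            lp += L
            grad[lay.x(i)] += gx
            if gh is not None:
                grad[lay.h(i)] += gh
        return lp, grad

    def _init_vmu(self) -> np.ndarray:
        lay = self._layout
        vmu = np.zeros(lay.dim)
        if self.hierarchical:
            for j in range(lay.n_groups):
                vmu[lay.mu(j)] = self.prior_loc
                vmu[lay.s(j)] = np.log(0.5)
        for i in range(len(self.subjects)):
            vmu[lay.x(i)] = self.prior_loc
        return vmu

    # -- fitting -----------------------------------------------------------
    def fit(self, settings: FitSettings | None = None, **kw) -> "PlanningDepthResults":
        """Run stochastic variational inference.

        Keyword arguments override :class:`FitSettings` fields.  The fit is
        deterministic given the settings and seed.
        """
        if settings is None:
            settings = FitSettings(**kw)
        elif kw:
            raise TypeError("pass either settings or keyword overrides, not both")
        lay = self._layout
        n_subj = len(self.subjects)
        rng = np.random.default_rng(settings.seed)
        # guide: Gaussian with a full 3x3 covariance block per subject's
        # (log beta, theta, logit alpha) -- these are strongly correlated in
        # the posterior and a diagonal guide underestimates their marginal
        # spread -- and diagonal factors everywhere else.  vls holds the log
        # Cholesky diagonal; voff the three below-diagonal entries per subject.
        vmu = self._init_vmu()
        vls = np.full(lay.dim, np.log(0.1))
        voff = np.zeros((n_subj, 3))  # order: (th,lb), (la,lb), (la,th)
        opt = _Adam(2 * lay.dim + voff.size, settings.learning_rate)
        elbo_trace = np.empty(settings.steps)
        ent_const = 0.5 * lay.dim * np.log(2 * np.pi * np.e)
        oi, oj = np.array([1, 2, 2]), np.array([0, 0, 1])  # lower-triangle index

        def sample_z(eps: np.ndarray) -> np.ndarray:
            z = vmu + np.exp(vls) * eps
            for i in range(n_subj):
                xs = lay.x(i)
                L = np.zeros((3, 3))
                L[np.arange(3), np.arange(3)] = np.exp(vls[xs])
                L[oi, oj] = voff[i]
                z[xs] = vmu[xs] + L @ eps[xs]
            return z

        for step in range(settings.steps):
            gmu = np.zeros(lay.dim)
            gls = np.zeros(lay.dim)
            goff = np.zeros_like(voff)
            lp_acc = 0.0
            for _ in range(settings.n_mc):
                eps = rng.standard_normal(lay.dim)
                z = sample_z(eps)
                lp, gz = self.log_joint_and_grad(z)
                if not np.isfinite(lp):
                    raise FitError(
                        f"non-finite objective at step {step}; "
                        f"trace so far: {elbo_trace[:step].tolist()[-5:]}"
                    )
                gmu += gz
                gls += gz * eps * np.exp(vls)
                for i in range(n_subj):
                    xs = lay.x(i)
                    G = np.outer(gz[xs], eps[xs])
                    # diagonal handled through vls (already accumulated above,
                    # and identical there since z_x diag term is exp(vls)*eps)
                    goff[i] += G[oi, oj]
                lp_acc += lp
            gmu /= settings.n_mc
            gls = gls / settings.n_mc + 1.0  # + d/dvls of the Gaussian entropy
            goff /= settings.n_mc
            packed = opt.step(
                np.concatenate([vmu, vls, voff.ravel()]),
                np.concatenate([gmu, gls, goff.ravel()]),
            )
            vmu = packed[: lay.dim]
            vls = packed[lay.dim: 2 * lay.dim]
            voff = packed[2 * lay.dim:].reshape(n_subj, 3)
            elbo_trace[step] = lp_acc / settings.n_mc + vls.sum() + ent_const
        draws = np.stack(
            [
                sample_z(rng.standard_normal(lay.dim))
                for _ in range(settings.n_posterior_samples)
            ]
        )
        return PlanningDepthResults(
            self, vmu, vls, draws, elbo_trace, settings, voff=voff
        )

    # -- exact small-instance oracle ----------------------------------------
    def exact_posterior(
        self,
        lb_grid: np.ndarray,
        th_grid: np.ndarray,
        la_grid: np.ndarray,
        max_points: int = 200_000,
    ) -> "GridPosterior":
        """Brute-force grid posterior over one subject's (beta, theta, alpha).

        Requires the non-hierarchical, fixed-uniform-weights model mode with
        a single subject and a handful of mini-blocks, where the depth
        weights are analytically uniform and only the three continuous
        parameters remain: the posterior is computed by direct summation
        over the grid, serving as an exact oracle for the variational fit.
        """
        if self.hierarchical or self.learn_weights:
            raise ValueError(
                "the grid oracle targets hierarchical=False, learn_weights=False"
            )
        if len(self.subjects) != 1:
            raise ValueError("the grid oracle targets a single subject")
        sdata = self.subjects[0]
        if sdata.n_blocks > 20:
            raise ValueError("grid oracle restricted to <= 20 mini-blocks")
        lb_grid, th_grid, la_grid = (
            np.asarray(a, dtype=float) for a in (lb_grid, th_grid, la_grid)
        )
        n_points = lb_grid.size * th_grid.size * la_grid.size
        if n_points > max_points:
            raise MemoryError(f"grid of {n_points} points exceeds {max_points}")
        m_list = self._mixture_weights(None)
        M = np.stack([m_list[c] for c in sdata.cond_index])  # (B, 3)
        jump = sdata.first_jump[:, None]
        loglik = np.empty((lb_grid.size, th_grid.size, la_grid.size))
        depth_num = np.zeros((sdata.n_blocks, 3))
        beta = np.exp(lb_grid)
        # accumulate depth posterior in a second pass after normalization
        q_store = np.empty(
            (la_grid.size, lb_grid.size, th_grid.size, sdata.n_blocks, 3)
        )
        for ia, la in enumerate(la_grid):
            alpha = float(expit(la))
            dq, _, _ = subject_delta_q(sdata, self.config, alpha)  # (B, 3)
            y = (
                beta[:, None, None, None] * dq[None, None, :, :]
                + th_grid[None, :, None, None]
            )
            pj = expit(y)
            p = np.where(jump[None, None], pj, 1.0 - pj)
            p = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
            Pb = (M[None, None] * p).sum(axis=3)  # (nb, nt, B)
            loglik[:, :, ia] = np.log(Pb).sum(axis=2)
            q_store[ia] = (M[None, None] * p) / Pb[..., None]
        prior = (
            -0.5 * (((lb_grid - self.prior_loc[0]) / self.prior_scale[0]) ** 2)[:, None, None]
            - 0.5 * (((th_grid - self.prior_loc[1]) / self.prior_scale[1]) ** 2)[None, :, None]
            - 0.5 * (((la_grid - self.prior_loc[2]) / self.prior_scale[2]) ** 2)[None, None, :]
        )
        logpost = loglik + prior
        logpost -= logpost.max()
        W = np.exp(logpost)
        W /= W.sum()
        for ia in range(la_grid.size):
            depth_num += np.einsum("nt,ntbd->bd", W[:, :, ia], q_store[ia])
        return GridPosterior(
            lb_grid=lb_grid,
            th_grid=th_grid,
            la_grid=la_grid,
            weights=W,
            depth_posterior=depth_num,
            block_ids=sdata.block_ids.copy(),
            n_steps=sdata.n_steps.copy(),
        )


@dataclass
class GridPosterior:
    """Exact grid posterior over one subject (small-instance oracle)."""

    lb_grid: np.ndarray
    th_grid: np.ndarray
    la_grid: np.ndarray
    weights: np.ndarray          # (n_lb, n_th, n_la), sums to 1
    depth_posterior: np.ndarray  # (B, 3)
    block_ids: np.ndarray
    n_steps: np.ndarray

    def marginal(self, param: str) -> tuple[np.ndarray, np.ndarray]:
        axis_map = {"beta": (0, (1, 2)), "theta": (1, (0, 2)), "alpha": (2, (0, 1))}
        ax, others = axis_map[param]
        grid = (self.lb_grid, self.th_grid, self.la_grid)[ax]
        return grid, self.weights.sum(axis=others)

    def mean_params(self) -> dict:
        """Posterior means on the natural scale."""
        lbm, lbw = self.marginal("beta")
        thm, thw = self.marginal("theta")
        lam, law = self.marginal("alpha")
        return {
            "beta": float(np.exp(lbm) @ lbw),
            "theta": float(thm @ thw),
            "alpha": float(expit(lam) @ law),
        }

    def mode_params(self) -> dict:
        idx = np.unravel_index(np.argmax(self.weights), self.weights.shape)
        return {
            "beta": float(np.exp(self.lb_grid[idx[0]])),
            "theta": float(self.th_grid[idx[1]]),
            "alpha": float(expit(self.la_grid[idx[2]])),
        }

    def depth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "miniblock_id": self.block_ids,
                "p1": self.depth_posterior[:, 0],
                "p2": self.depth_posterior[:, 1],
                "p3": self.depth_posterior[:, 2],
                "mean_depth": self.depth_posterior @ np.array([1.0, 2.0, 3.0]),
            }
        )


class PlanningDepthResults:
    """Posterior summaries of a fitted :class:`PlanningDepthModel`.

    Carries the variational parameters, posterior draws, the ELBO trace and
    derived quantities: subject-parameter estimates with credible intervals,
    per-mini-block depth posteriors, and recovery diagnostics.
    """

    def __init__(self, model, vmu, vls, draws, elbo_trace, settings,
                 voff=None) -> None:
        self.model = model
        self.vmu = vmu
        self.vls = vls
        self.voff = voff
        self.draws = draws
        self.elbo_trace = elbo_trace
        self.settings = settings
        self._depth_draws: dict | None = None
        self._params_cache: dict[str, pd.DataFrame] = {}

    def _marginal_sd(self, i: int) -> np.ndarray:
        """Marginal guide sd of subject i's transformed parameters.

        Row norms of the subject's Cholesky block: the guide marginals stay
        Gaussian, so interval endpoints remain exact quantile transforms.
        """
        xs = self.model._layout.x(i)
        d = np.exp(self.vls[xs])
        if self.voff is None:
            return d
        o = self.voff[i]
        return np.sqrt(
            np.array(
                [d[0] ** 2, o[0] ** 2 + d[1] ** 2, o[1] ** 2 + o[2] ** 2 + d[2] ** 2]
            )
        )

    # -- subject parameters -------------------------------------------------
    _LB_GRID = np.linspace(-4.0, 4.0, 41)    # log beta
    _TH_GRID = np.linspace(-4.0, 4.0, 41)    # theta
    _LA_GRID = np.linspace(-9.0, 5.0, 21)    # logit alpha
    _N_RB_DRAWS = 16

    def _conditional_marginals(self, i: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Rao-Blackwellized marginal posteriors of one subject's parameters.

        For each retained posterior draw of the depth weights and group
        hyperparameters, the 3-D conditional posterior of the subject's
        (log beta, theta, logit alpha) block -- hierarchical prior times
        exact likelihood -- is evaluated on a transformed-space grid and
        averaged over draws; the returned marginals integrate the strong
        within-subject correlations (e.g. the beta-theta ridge of a
        near-deterministic subject) exactly, unlike the Gaussian guide
        factors, and keep the tails of flat or one-sided likelihoods.
        """
        lay = self.model._layout
        model = self.model
        sdata = model.subjects[i]
        jg = model.group_of_subject[i]
        lb, th, la = self._LB_GRID, self._TH_GRID, self._LA_GRID
        jump = sdata.first_jump[:, None]
        n_draws = min(self._N_RB_DRAWS, self.draws.shape[0])
        stride = max(1, self.draws.shape[0] // n_draws)
        dens3 = np.zeros((lb.size, th.size, la.size))
        ll3: np.ndarray | None = None
        p_cache = []
        for s in range(0, stride * n_draws, stride):
            z = self.draws[s]
            if model.hierarchical:
                mu = z[lay.mu(jg)]
                sig = np.exp(z[lay.s(jg)])
            else:
                mu = model.prior_loc
                sig = model.prior_scale
            h = z[lay.h(i)] if model.learn_weights else None
            m_list = model._mixture_weights(h)
            M = np.stack([m_list[c] for c in sdata.cond_index])
            if not p_cache:
                # per-depth action likelihoods over the (lb, th, la) grid are
                # draw-independent; cache them on the first pass
                for ia in range(la.size):
                    dq, _, _ = subject_delta_q(sdata, model.config, float(expit(la[ia])))
                    y = np.exp(lb)[:, None, None, None] * dq[None, None] \
                        + th[None, :, None, None]
                    p = expit(y)
                    p = np.where(jump[None, None], p, 1.0 - p)
                    p_cache.append(np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR))
            ll3 = np.empty((lb.size, th.size, la.size))
            for ia in range(la.size):
                P = (M[None, None] * p_cache[ia]).sum(axis=3)
                ll3[:, :, ia] = np.log(P).sum(axis=2)
            logd = (
                ll3
                - 0.5 * (((lb - mu[0]) / sig[0]) ** 2)[:, None, None]
                - 0.5 * (((th - mu[1]) / sig[1]) ** 2)[None, :, None]
                - 0.5 * (((la - mu[2]) / sig[2]) ** 2)[None, None, :]
            )
            logd -= logd.max()
            w = np.exp(logd)
            dens3 += w / w.sum()
        out = {}
        for name, grid, axes in (
            ("beta", lb, (1, 2)), ("theta", th, (0, 2)), ("alpha", la, (0, 1))
        ):
            marg = dens3.sum(axis=axes)
            out[name] = (grid, marg / np.trapezoid(marg, grid))
        return out

    @staticmethod
    def _grid_summary(grid: np.ndarray, dens: np.ndarray, transform) -> dict:
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (dens[1:] + dens[:-1]) * np.diff(grid)
        )])
        cdf /= cdf[-1]
        lo = float(np.interp(0.025, cdf, grid))
        hi = float(np.interp(0.975, cdf, grid))
        nat = transform(grid)
        mean = float(np.trapezoid(nat * dens, grid) / np.trapezoid(dens, grid))
        sd = float(np.sqrt(max(
            np.trapezoid(nat**2 * dens, grid) / np.trapezoid(dens, grid) - mean**2, 0.0
        )))
        return {
            "post_mean": mean,
            "post_sd": sd,
            "ci_lower": float(transform(np.array([lo]))[0]),
            "ci_upper": float(transform(np.array([hi]))[0]),
        }

    def subject_params(self, method: str = "conditional") -> pd.DataFrame:
        """Posterior mean, sd and central 95% credible interval per parameter.

        ``method="conditional"`` (default) summarizes the Rao-Blackwellized
        conditional marginals (exact 1-D densities averaged over posterior
        draws of the other latents); ``method="gaussian"`` uses the guide's
        Gaussian factors pushed through the monotone transforms.
        """
        if method not in ("conditional", "gaussian"):
            raise ValueError("method must be 'conditional' or 'gaussian'")
        if method in self._params_cache:
            return self._params_cache[method].copy()
        lay = self.model._layout
        transforms = {
            "beta": np.exp,
            "theta": lambda v: v,
            "alpha": expit,
        }
        rows = []
        zcrit = 1.959963984540054
        for i, sid in enumerate(self.model.subject_ids):
            if method == "conditional":
                marginals = self._conditional_marginals(i)
                for name in PARAM_NAMES:
                    grid, dens = marginals[name]
                    summ = self._grid_summary(grid, dens, transforms[name])
                    rows.append({"subject_id": sid, "param": name, **summ})
            else:
                xs = self.draws[:, lay.x(i)]
                nat = to_natural(xs)
                mu = self.vmu[lay.x(i)]
                sd = self._marginal_sd(i)
                lo = to_natural(mu - zcrit * sd)
                hi = to_natural(mu + zcrit * sd)
                for j, name in enumerate(PARAM_NAMES):
                    rows.append(
                        {
                            "subject_id": sid,
                            "param": name,
                            "post_mean": float(nat[:, j].mean()),
                            "post_sd": float(nat[:, j].std(ddof=1)),
                            "ci_lower": float(lo[j]),
                            "ci_upper": float(hi[j]),
                        }
                    )
        frame = pd.DataFrame(rows)
        self._params_cache[method] = frame
        return frame.copy()

    def group_params(self) -> pd.DataFrame | None:
        """Posterior summary of the per-group locations and scales."""
        if not self.model.hierarchical:
            return None
        lay = self.model._layout
        rows = []
        for jg, label in enumerate(self.model.group_labels):
            for j, name in enumerate(PARAM_NAMES):
                mu_d = self.draws[:, lay.mu(jg)][:, j]
                s_d = np.exp(self.draws[:, lay.s(jg)][:, j])
                rows.append(
                    {
                        "group": label,
                        "param": name,
                        "loc_mean": float(mu_d.mean()),
                        "loc_sd": float(mu_d.std(ddof=1)),
                        "scale_mean": float(s_d.mean()),
                    }
                )
        return pd.DataFrame(rows)

    # -- depth posterior ----------------------------------------------------
    def _compute_depth_draws(self) -> dict:
        """Per-draw closed-form depth categoricals, per subject: (S, B, 3)."""
        if self._depth_draws is not None:
            return self._depth_draws
        lay = self.model._layout
        out = {}
        for i, sdata in enumerate(self.model.subjects):
            S = self.draws.shape[0]
            qs = np.empty((S, sdata.n_blocks, 3))
            for s in range(S):
                z = self.draws[s]
                x = z[lay.x(i)]
                h = z[lay.h(i)] if self.model.learn_weights else None
                m_list = self.model._mixture_weights(h)
                beta = np.exp(x[0])
                alpha = float(expit(x[2]))
                dq, _, _ = subject_delta_q(sdata, self.model.config, alpha)
                y = beta * dq + x[1]
                pj = expit(y)
                p = np.where(sdata.first_jump[:, None], pj, 1.0 - pj)
                p = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
                M = np.stack([m_list[c] for c in sdata.cond_index])
                num = M * p
                qs[s] = num / num.sum(axis=1, keepdims=True)
            out[sdata.subject_id] = qs
        self._depth_draws = out
        return out

    def depth_posterior(self) -> pd.DataFrame:
        """Posterior depth distribution and mean depth per mini-block."""
        dd = self._compute_depth_draws()
        frames = []
        for i, sdata in enumerate(self.model.subjects):
            q = dd[sdata.subject_id].mean(axis=0)  # (B, 3)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": sdata.subject_id,
                        "miniblock_id": sdata.block_ids,
                        "n_steps": sdata.n_steps,
                        "noise": np.where(sdata.noise_high, "high", "low"),
                        "p1": q[:, 0],
                        "p2": q[:, 1],
                        "p3": q[:, 2],
                        "mean_depth": q @ np.array([1.0, 2.0, 3.0]),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def mean_depth(self, by: str = "subject") -> pd.DataFrame:
        """Aggregate per-block mean depths per subject (and condition)."""
        dp = self.depth_posterior()
        if by == "subject":
            return dp.groupby("subject_id", as_index=False)["mean_depth"].mean()
        if by == "subject_condition":
            return dp.groupby(
                ["subject_id", "n_steps", "noise"], as_index=False
            )["mean_depth"].mean()
        raise ValueError("by must be 'subject' or 'subject_condition'")

    # -- recovery ------------------------------------------------------------
    def recovery_report(
        self, true_params: pd.DataFrame, true_depths: pd.DataFrame | None = None
    ) -> dict:
        """Validate the fit against known generating values.

        ``true_params`` needs columns subject_id, beta, theta, alpha;
        ``true_depths`` needs subject_id, miniblock_id, depth.  Reports each
        parameter's 95% credible interval with a containment indicator, the
        per-block fraction of posterior samples in which the generating depth
        has the strictly highest probability, and summary percentages.
        """
        sp = self.subject_params()
        tp = true_params.set_index("subject_id")
        recs = []
        for row in sp.itertuples():
            true_val = float(tp.loc[row.subject_id, row.param])
            recs.append(
                {
                    "subject_id": row.subject_id,
                    "param": row.param,
                    "true": true_val,
                    "post_mean": row.post_mean,
                    "ci_lower": row.ci_lower,
                    "ci_upper": row.ci_upper,
                    "covered": bool(row.ci_lower <= true_val <= row.ci_upper),
                }
            )
        params_df = pd.DataFrame(recs)
        report = {
            "param_table": params_df,
            "pct_params_in_ci": 100.0 * params_df["covered"].mean(),
        }
        if true_depths is not None:
            dd = self._compute_depth_draws()
            td = true_depths.set_index(["subject_id", "miniblock_id"])["depth"]
            rows = []
            for sdata in self.model.subjects:
                qs = dd[sdata.subject_id]  # (S, B, 3)
                argmax = qs.argmax(axis=2) + 1
                # strict argmax: ties count as failures
                sorted_q = np.sort(qs, axis=2)
                strict = sorted_q[:, :, -1] > sorted_q[:, :, -2]
                for b, block_id in enumerate(sdata.block_ids):
                    true_d = int(td.loc[(sdata.subject_id, int(block_id))])
                    frac = float(
                        np.mean((argmax[:, b] == true_d) & strict[:, b])
                    )
                    rows.append(
                        {
                            "subject_id": sdata.subject_id,
                            "miniblock_id": int(block_id),
                            "true_depth": true_d,
                            "top_fraction": frac,
                        }
                    )
            depth_df = pd.DataFrame(rows)
            report["depth_table"] = depth_df
            report["median_top_fraction_pct"] = 100.0 * float(
                depth_df["top_fraction"].median()
            )
            report["pct_blocks_top_ge_95"] = 100.0 * float(
                (depth_df["top_fraction"] >= 0.95).mean()
            )
        return report

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Planning-depth mixture model (variational fit)",
            "=" * 52,
            f"subjects: {len(self.model.subject_ids)}   "
            f"mini-blocks: {sum(s.n_blocks for s in self.model.subjects)}",
            f"SVI steps: {self.settings.steps}   seed: {self.settings.seed}   "
            f"final ELBO: {self.elbo_trace[-1]:.1f}",
            "",
        ]
        gp = self.group_params()
        if gp is not None:
            lines.append("Group-level transformed locations/scales:")
            lines.append(gp.to_string(index=False, float_format="%.3f"))
            lines.append("")
        sp = self.subject_params()
        pivot = sp.pivot(index="subject_id", columns="param", values="post_mean")
        md = self.mean_depth().set_index("subject_id")["mean_depth"]
        pivot["mean_depth"] = md
        lines.append("Subject posterior means:")
        lines.append(
            pivot[["beta", "theta", "alpha", "mean_depth"]].to_string(
                float_format="%.3f"
            )
        )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write subject_params.csv, depth_posterior.csv and diagnostics.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.subject_params().to_csv(outdir / "subject_params.csv", index=False)
        self.depth_posterior().to_csv(outdir / "depth_posterior.csv", index=False)
        diag = {
            "seed": int(self.settings.seed),
            "steps": int(self.settings.steps),
            "learning_rate": float(self.settings.learning_rate),
            "n_posterior_samples": int(self.settings.n_posterior_samples),
            "config_hash": self.model.config.config_hash(),
            "elbo_trace": [float(v) for v in self.elbo_trace],
        }
        with open(outdir / "diagnostics.json", "w") as fh:
            json.dump(diag, fh)
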