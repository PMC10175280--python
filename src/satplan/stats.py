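"""Downstream statistics on model outputs and behavior logs.

Covers the performance score (achieved percentage of the maximum possible
fuel score), the fast-guess reaction-time filter, two-group comparisons with
normality/variance-driven fallbacks, the regression of task performance on
the computational model parameters, and an optional mixed-effects model of
mean planning depth on the design factors.  All classical tests delegate to
scipy/statsmodels; the bespoke content here is the scoring, aggregation and
filtering logic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .config import TaskConfig
from .likelihood import DataError
from .task import blocks_from_frame, max_expected_score


def performance_percentage(
    log: pd.DataFrame, config: TaskConfig, denominator: str = "expected"
) -> pd.DataFrame:
    """Achieved percentage of the maximum possible fuel score, per subject.

    The numerator is the subject's total fuel change (rewards minus costs)
    over all trials; the denominator is the sum over mini-blocks of the
    optimal policy's expected score (``denominator="expected"``, default) or
    of the best plan under deterministic jumps (``"deterministic"``).  A
    non-positive denominator is flagged in the ``denominator_valid`` column
    rather than silently propagating NaN.
    """
    rows = []
    for subject, slog in log.groupby("subject_id", sort=True):
        blocks = blocks_from_frame(slog)
        max_score = sum(max_expected_score(config, b, denominator) for b in blocks)
        achieved = float(
            (slog["reward_collected"] - slog["cost_paid"]).sum()
        )
        valid = max_score > 0
        rows.append(
            {
                "subject_id": subject,
                "group": slog["group"].iloc[0] if "group" in slog else "",
                "achieved": achieved,
                "max_score": float(max_score),
                "performance_pct": 100.0 * achieved / max_score if valid else np.nan,
                "denominator_valid": bool(valid),
            }
        )
    return pd.DataFrame(rows)


def rt_filter(
    log: pd.DataFrame, threshold_ms: float = 150.0, level: str = "trial"
) -> tuple[pd.DataFrame, int]:
    """Exclude fast-guess responses (RT below ``threshold_ms``).

    ``level="trial"`` drops individual sub-threshold rows; ``level="miniblock"``
    drops every trial of any mini-block containing one.  Returns the filtered
    log and the number of excluded units (rows, or mini-blocks).
    """
    if "rt_ms" not in log.columns:
        raise DataError("behavior log has no rt_ms column")
    fast = log["rt_ms"] < threshold_ms
    if level == "trial":
        return log[~fast].copy(), int(fast.sum())
    if level == "miniblock":
        bad = log.loc[fast, ["subject_id", "miniblock_id"]].drop_duplicates()
        key = log.set_index(["subject_id", "miniblock_id"]).index
        bad_key = set(map(tuple, bad.to_numpy()))
        mask = np.array([k in bad_key for k in key])
        return log[~mask].copy(), len(bad_key)
    raise ValueError("level must be 'trial' or 'miniblock'")


@dataclass
class GroupTest:
    """Two-group comparison with assumption checks and fallbacks."""

    variable: str
    groups: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    statistic: float
    df: float | None
    p_value: float
    test: str                 # "t", "welch" or "mannwhitney"
    shapiro_p: tuple[float, float]
    levene_p: float
    t_statistic: float        # plain Student t, always reported alongside
    t_p_value: float

    def as_dict(self) -> dict:
        d = {
            "variable": self.variable,
            "group_a": self.groups[0],
            "group_b": self.groups[1],
            "n_a": self.n[0],
            "n_b": self.n[1],
            "mean_a": self.means[0],
            "mean_b": self.means[1],
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "shapiro_p_a": self.shapiro_p[0],
            "shapiro_p_b": self.shapiro_p[1],
            "levene_p": self.levene_p,
            "t_statistic": self.t_statistic,
            "t_p_value": self.t_p_value,
        }
        return d


def group_compare(
    summaries: pd.DataFrame,
    variable: str,
    group_col: str = "group",
    alpha: float = 0.05,
) -> GroupTest:
    """Two-sample comparison of ``variable`` between the two groups.

    The primary test is Student's t.  If either group fails Shapiro-Wilk
    normality at ``alpha``, the reported test falls back to Mann-Whitney-U;
    otherwise, if Levene's test indicates unequal variances, to Welch's t.
    The plain t statistic is always reported alongside for readability.
    """
    labels = list(pd.unique(summaries[group_col]))
    if len(labels) != 2:
        raise DataError(f"expected exactly two groups, found {labels}")
    a = summaries.loc[summaries[group_col] == labels[0], variable].dropna().to_numpy()
    b = summaries.loc[summaries[group_col] == labels[1], variable].dropna().to_numpy()
    if min(len(a), len(b)) < 2:
        raise DataError("each group needs at least two observations")
    sh_a = st.shapiro(a).pvalue if len(a) >= 3 else 1.0
    sh_b = st.shapiro(b).pvalue if len(b) >= 3 else 1.0
    lev_p = st.levene(a, b).pvalue
    t_res = st.ttest_ind(a, b, equal_var=True)
    t_df = len(a) + len(b) - 2
    if sh_a < alpha or sh_b < alpha:
        u = st.mannwhitneyu(a, b, alternative="two-sided")
        test, statistic, df, p = "mannwhitney", float(u.statistic), None, float(u.pvalue)
    elif lev_p < alpha:
        w = st.ttest_ind(a, b, equal_var=False)
        test, statistic, df, p = "welch", float(w.statistic), float(w.df), float(w.pvalue)
    else:
        test, statistic, df, p = "t", float(t_res.statistic), float(t_df), float(t_res.pvalue)
    return GroupTest(
        variable=variable,
        groups=(str(labels[0]), str(labels[1])),
        n=(len(a), len(b)),
        means=(float(a.mean()), float(b.mean())),
        statistic=statistic,
        df=df,
        p_value=p,
        test=test,
        shapiro_p=(float(sh_a), float(sh_b)),
        levene_p=float(lev_p),
        t_statistic=float(t_res.statistic),
        t_p_value=float(t_res.pvalue),
    )


def performance_regression(
    summaries: pd.DataFrame,
    outcome: str = "performance_pct",
    predictors: tuple[str, ...] = ("mean_depth", "alpha", "beta", "theta"),
) -> dict:
    """OLS regression of task performance on the computational model parameters.

    Returns coefficients, standardized coefficients, R-squared and a
    collinearity flag (from the design-matrix condition number).
    """
    cols = [outcome, *predictors]
    frame = summaries[cols].dropna()
    if len(frame) < 6:
        raise DataError("performance regression needs at least 6 subjects")
    y = frame[outcome].to_numpy(dtype=float)
    X = frame[list(predictors)].to_numpy(dtype=float)
    Xc = sm.add_constant(X)
    fit = sm.OLS(y, Xc).fit()
    sd_y = y.std(ddof=1)
    sd_x = X.std(axis=0, ddof=1)
    standardized = {
        name: float(fit.params[j + 1] * sd_x[j] / sd_y)
        for j, name in enumerate(predictors)
    }
    cond = np.linalg.cond(Xc)
    return {
        "n": len(frame),
        "r_squared": float(fit.rsquared),
        "adj_r_squared": float(fit.rsquared_adj),
        "coefficients": {
            "const": float(fit.params[0]),
            **{name: float(fit.params[j + 1]) for j, name in enumerate(predictors)},
        },
        "p_values": {
            "const": float(fit.pvalues[0]),
            **{name: float(fit.pvalues[j + 1]) for j, name in enumerate(predictors)},
        },
        "standardized_coefficients": standardized,
        "condition_number": float(cond),
        "collinear": bool(cond > 1e10),
    }


def depth_mixed_model(block_level_depths: pd.DataFrame) -> dict:
    """Mixed-effects model of mean planning depth on group, noise and steps.

    Expects one row per subject-condition with columns subject_id, group,
    noise, n_steps, mean_depth.  Fits fixed effects for group, noise, steps
    and the group-by-condition interactions, with a random intercept and
    random noise/steps slopes per subject.  A singular fit is reported, not
    fatal.
    """
    frame = block_level_depths.copy()
    groups = sorted(frame["group"].unique())
    frame["grp"] = (frame["group"] == groups[-1]).astype(float)
    frame["noise_high"] = (frame["noise"] == "high").astype(float)
    frame["steps3"] = (frame["n_steps"] == 3).astype(float)
    md = smf.mixedlm(
        "mean_depth ~ grp * noise_high + grp * steps3",
        frame,
        groups=frame["subject_id"],
        re_formula="~noise_high + steps3",
    )
    import warnings

    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = md.fit(reml=True, method="lbfgs")
        except Exception as exc:  # singular / non-converged fits are reported
            return {"converged": False, "singular": True, "error": str(exc)}
        singular = any("singular" in str(w.message).lower() for w in caught)
    return {
        "converged": bool(fit.converged),
        "singular": singular,
        "coefficients": {k: float(v) for k, v in fit.fe_params.items()},
        "p_values": {k: float(fit.pvalues[k]) for k in fit.fe_params.index},
        "reference_group": groups[0],
    }


def subject_summaries(
    results,
    log: pd.DataFrame,
    config: TaskConfig,
    covariate_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """One row per subject: mean depth, performance, RT, posterior means.

    ``results`` is a fitted :class:`~satplan.model.PlanningDepthResults`
    whose model was built from (a superset of) ``log``.
    """
    perf = performance_percentage(log, config).set_index("subject_id")
    depth = results.mean_depth().set_index("subject_id")["mean_depth"]
    by_cond = results.mean_depth(by="subject_condition")
    params = results.subject_params().pivot(
        index="subject_id", columns="param", values="post_mean"
    )
    rows = []
    for subject, slog in log.groupby("subject_id", sort=True):
        row = {
            "subject_id": subject,
            "group": slog["group"].iloc[0] if "group" in slog else "",
            "mean_depth": float(depth.loc[subject]),
            "performance_pct": float(perf.loc[subject, "performance_pct"]),
            "mean_rt_s": float(slog["rt_ms"].mean() / 1000.0)
            if slog["rt_ms"].notna().any()
            else np.nan,
            "beta": float(params.loc[subject, "beta"]),
            "theta": float(params.loc[subject, "theta"]),
            "alpha": float(params.loc[subject, "alpha"]),
        }
        sub_cond = by_cond[by_cond["subject_id"] == subject]
        for r in sub_cond.itertuples():
            row[f"mean_depth_{r.n_steps}_{r.noise}"] = float(r.mean_depth)
        for col in covariate_cols:
            row[col] = float(slog[col].iloc[0])
        rows.append(row)
    return pd.DataFrame(rows)
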