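"""Group statistics: covariate-adjusted comparisons, the Bonferroni testing
ladder, and covariate-adjusted partial correlations.

Cross-sectional comparisons fit an ordinary linear model of the metric on
cognitive group plus age, sex and education (one observation per subject a
random intercept would be unidentifiable for).  Longitudinal comparisons fit
a linear mixed model with a per-subject random intercept and a group x time
interaction.  Families of tests are Bonferroni-corrected along a gated
ladder: stage 1 tests {promiscuity, flexibility} (divisor 2); stage 2 tests
{cohesion, disjointedness} (divisor 2) only if flexibility was significant;
stage 3 descends to the seven subnetworks (divisor 7) only metrics with a
significant global effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .datatypes import DynreconfError

DEFAULT_COVARIATES = ("age", "sex", "education")


def bonferroni(p: float, divisor: int) -> float:
    """Family-wise adjusted p-value: ``min(1, p * divisor)``."""
    if divisor < 1:
        raise DynreconfError("Bonferroni divisor must be >= 1")
    return min(1.0, float(p) * divisor)


@dataclass
class GroupComparison:
    """Result of one covariate-adjusted group comparison."""

    outcome: str
    omnibus_stat: float
    omnibus_df: tuple[float, float]
    p_raw: float
    p_adjusted: float
    divisor: int
    contrasts: pd.DataFrame
    model_summary: str = ""


def _check_table(
    df: pd.DataFrame, outcome: str, covariates: Sequence[str], group_col: str
) -> pd.DataFrame:
    need = {outcome, group_col, *covariates}
    missing = need - set(df.columns)
    if missing:
        raise DynreconfError(f"missing columns: {sorted(missing)}")
    data = df.dropna(subset=list(need))
    counts = data[group_col].value_counts()
    small = counts[counts < 2]
    if len(small):
        raise DynreconfError(f"groups with < 2 subjects: {dict(small)}")
    return data


def compare_groups(
    df: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
    group_order: Sequence[str] = ("HC", "CP", "MCI", "CI"),
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    divisor: int = 1,
    extra_covariates: Sequence[str] = (),
) -> GroupComparison:
    """Omnibus group effect and all pairwise contrasts, covariate-adjusted.

    Fits ``outcome ~ C(group) + age + sex + education`` (plus any
    ``extra_covariates``, e.g. a surrogate-derived null level) by OLS on a
    one-row-per-subject table.  Returns the Wald F omnibus over the group
    dummies and every pairwise group contrast with 95% CI; raw p-values are
    Bonferroni-adjusted with ``divisor``.
    """
    covars = tuple(covariates) + tuple(extra_covariates)
    data = _check_table(df, outcome, covars, group_col).copy()
    present = [g for g in group_order if g in set(data[group_col])]
    if len(present) < 2:
        raise DynreconfError(f"need >= 2 groups to compare, found {present}")
    data[group_col] = pd.Categorical(data[group_col], categories=present)
    rhs = " + ".join([f"C({group_col})"] + list(covars))
    model = smf.ols(f"{outcome} ~ {rhs}", data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise DynreconfError(
            f"rank-deficient design; check collinearity among {list(covars)}"
        )
    res = model.fit()
    names = res.model.exog_names
    group_terms = [n for n in names if n.startswith(f"C({group_col})")]
    constraint = ", ".join(f"{t} = 0" for t in group_terms)
    ftest = res.f_test(constraint)
    p_raw = float(ftest.pvalue)

    def term(g: str) -> np.ndarray:
        v = np.zeros(len(names))
        t = f"C({group_col})[T.{g}]"
        if t in names:
            v[names.index(t)] = 1.0
        return v

    rows = []
    for i, a in enumerate(present):
        for b in present[i + 1 :]:
            vec = term(b) - term(a)
            tt = res.t_test(vec)
            lo, hi = np.atleast_2d(tt.conf_int())[0]
            rows.append(
                {
                    "contrast": f"{b} - {a}",
                    "estimate": float(np.atleast_1d(tt.effect)[0]),
                    "se": float(np.atleast_1d(tt.sd).ravel()[0]),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "p_raw": float(tt.pvalue),
                    "p_adjusted": bonferroni(float(tt.pvalue), divisor),
                }
            )
    return GroupComparison(
        outcome=outcome,
        omnibus_stat=float(ftest.fvalue),
        omnibus_df=(float(ftest.df_num), float(ftest.df_denom)),
        p_raw=p_raw,
        p_adjusted=bonferroni(p_raw, divisor),
        divisor=divisor,
        contrasts=pd.DataFrame(rows),
        model_summary=str(res.summary()),
    )


def longitudinal_change(
    df: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
    group_order: Sequence[str] = ("HC", "CP", "MCI", "CI"),
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    subject_col: str = "subject_id",
    time_col: str = "timepoint",
) -> pd.DataFrame:
    """Per-group time effects from a random-intercept mixed model.

    Fits ``outcome ~ C(group) * time + covariates`` with a per-subject random
    intercept (time coded 0/1 for baseline/follow-up).  Returns one row per
    group: the group's time effect (reference time slope plus its interaction),
    SE, 95% CI and p-value from the normal approximation to the fixed-effect
    estimates, plus the interaction contrast against the reference group.
    """
    tps = sorted(df[time_col].unique())
    if len(tps) != 2:
        raise DynreconfError(f"longitudinal model needs exactly 2 time-points, got {tps}")
    covars = tuple(covariates)
    data = _check_table(df, outcome, covars + (subject_col, time_col), group_col).copy()
    per_subj = data.groupby(subject_col)[time_col].nunique()
    keep = per_subj[per_subj == 2].index
    data = data[data[subject_col].isin(keep)]
    if data.empty:
        raise DynreconfError("no subject has both time-points")
    present = [g for g in group_order if g in set(data[group_col])]
    data[group_col] = pd.Categorical(data[group_col], categories=present)
    data["_time"] = (data[time_col] == tps[1]).astype(float)
    rhs = " + ".join([f"C({group_col}) * _time"] + list(covars))
    model = smf.mixedlm(
        f"{outcome} ~ {rhs}", data=data, groups=data[subject_col]
    )
    res = model.fit(reml=True, method="lbfgs")
    names = list(res.fe_params.index)
    params = res.fe_params.to_numpy()
    cov = res.cov_params().loc[names, names].to_numpy()

    rows = []
    for g in present:
        vec = np.zeros(len(names))
        vec[names.index("_time")] = 1.0
        inter = f"C({group_col})[T.{g}]:_time"
        if inter in names:
            vec[names.index(inter)] = 1.0
        est = float(vec @ params)
        se = float(np.sqrt(vec @ cov @ vec))
        z = est / se if se > 0 else np.nan
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        inter_est = inter_p = np.nan
        if inter in names:
            i = names.index(inter)
            inter_est = float(params[i])
            ise = float(np.sqrt(cov[i, i]))
            inter_p = 2.0 * scipy.stats.norm.sf(abs(inter_est / ise))
        rows.append(
            {
                "group": g,
                "time_effect": est,
                "se": se,
                "ci_low": est - 1.959963984540054 * se,
                "ci_high": est + 1.959963984540054 * se,
                "p": float(p),
                "interaction_vs_ref": inter_est,
                "interaction_p": float(inter_p) if np.isfinite(inter_p) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: pd.DataFrame | np.ndarray,
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates (with intercept) by
    least squares; r is the Pearson correlation of the residuals and p comes
    from the t distribution with ``n - k - 2`` degrees of freedom, k the
    number of covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    mask = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(c), axis=1)
    x, y, c = x[mask], y[mask], c[mask]
    n, k = len(x), c.shape[1]
    if n < k + 3:
        raise DynreconfError(f"need >= {k + 3} complete cases, got {n}")
    design = np.column_stack([np.ones(n), c])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    sx, sy = np.sqrt(rx @ rx), np.sqrt(ry @ ry)
    floor_x = 1e-10 * max(float(np.linalg.norm(x - x.mean())), np.finfo(float).tiny)
    floor_y = 1e-10 * max(float(np.linalg.norm(y - y.mean())), np.finfo(float).tiny)
    if sx <= floor_x or sy <= floor_y:
        raise DynreconfError("zero residual variance; partial correlation undefined")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    dof = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r * r))
    p = float(2.0 * scipy.stats.t.sf(abs(t), dof))
    return r, p


@dataclass
class LadderResult:
    """Tidy output of the gated Bonferroni ladder."""

    table: pd.DataFrame
    gates: dict[str, bool] = field(default_factory=dict)


def run_test_ladder(
    global_metrics: pd.DataFrame,
    cohort: pd.DataFrame,
    network_metrics: pd.DataFrame | None = None,
    alpha: float = 0.05,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    compare: Callable[..., GroupComparison] | None = None,
) -> LadderResult:
    """Run the three-stage gated comparison ladder on global metric z-scores.

    ``global_metrics``/``network_metrics`` are wide tables with one row per
    subject: columns named by metric (and ``<metric>@<network>`` for stage 3)
    merged with the cohort covariate columns.  Stage 2 runs only if the
    global flexibility effect survives its stage-1 correction; stage 3 runs,
    per metric, only if that metric's global effect was significant.  Rows
    for gated-off stages are simply absent from the output.
    """
    compare = compare or compare_groups
    rows: list[dict] = []
    gates: dict[str, bool] = {}

    def record(result: GroupComparison, family: str, stage: int) -> None:
        rows.append(
            {
                "stage": stage,
                "family": family,
                "outcome": result.outcome,
                "omnibus_F": result.omnibus_stat,
                "p_raw": result.p_raw,
                "p_adjusted": result.p_adjusted,
            }
        )

    stage1 = {}
    for metric in ("promiscuity", "flexibility"):
        res = compare(global_metrics, metric, covariates=covariates, divisor=2)
        stage1[metric] = res
        record(res, "stage1:promiscuity+flexibility", 1)
    gates["stage2"] = stage1["flexibility"].p_adjusted < alpha
    significant_globals = {
        m for m, r in stage1.items() if r.p_adjusted < alpha
    }
    if gates["stage2"]:
        for metric in ("cohesion", "disjointedness"):
            res = compare(global_metrics, metric, covariates=covariates, divisor=2)
            record(res, "stage2:cohesion+disjointedness", 2)
            if res.p_adjusted < alpha:
                significant_globals.add(metric)
        significant_globals.discard("flexibility")  # differentiated by stage 2
    for metric in sorted(significant_globals):
        gates[f"stage3:{metric}"] = True
        if network_metrics is None:
            continue
        nets = [
            c.split("@", 1)[1]
            for c in network_metrics.columns
            if c.startswith(f"{metric}@")
        ]
        for net in nets:
            col = f"{metric}@{net}"
            safe = f"{metric}_{net}"
            res = compare(
                network_metrics.rename(columns={col: safe}),
                safe,
                covariates=covariates,
                divisor=7,
            )
            record(res, f"stage3:{metric}", 3)
    return LadderResult(table=pd.DataFrame(rows), gates=gates)
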