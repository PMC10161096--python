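"""Inferential layer for dose-condition contrasts.

One-way ANOVAs across dose conditions with eta-squared, Tukey HSD post hocs
(vehicle contrasts highlighted) and Cohen's d versus vehicle; a linear
mixed-effects model on per-block median trials-to-criterion with
condition x session-third fixed effects and random intercepts for subject
and session-within-subject; and the Fisher r-to-z comparison of two
correlations.  Reporting mirrors the field's caption format
"F(df1, df2), p, eta^2, Tukey p, d".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "ConditionContrast",
    "MixedModelResult",
    "condition_anova",
    "mixed_model_ttc",
    "fisher_r_to_z",
    "effect_size_cohens_d",
]


@dataclass
class ConditionContrast:
    """A metric compared across dose conditions."""

    metric: str
    conditions: list[str]
    means: dict[str, float]
    sems: dict[str, float]
    ns: dict[str, int]
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    eta_squared: float
    tukey_p_vs_vehicle: dict[str, float]
    cohens_d_vs_vehicle: dict[str, float]
    tukey_all_pairs: pd.DataFrame
    degenerate: bool = False

    def summary(self) -> str:
        lines = [
            f"{self.metric}: F({self.df_between},{self.df_within}) = {self.f_stat:.2f}, "
            f"P = {self.p_value:.3g}; eta^2 = {self.eta_squared:.3f}"
        ]
        for cond in self.conditions:
            line = f"  {cond}: {self.means[cond]:.3f} (SE {self.sems[cond]:.3f}, n={self.ns[cond]})"
            if cond in self.tukey_p_vs_vehicle:
                line += (
                    f"; Tukey vs vehicle P = {self.tukey_p_vs_vehicle[cond]:.3g}, "
                    f"d = {self.cohens_d_vs_vehicle[cond]:.3f}"
                )
            lines.append(line)
        return "\n".join(lines)


@dataclass
class MixedModelResult:
    """Fixed and random effects of the trials-to-criterion mixed model."""

    fixed_effects: pd.DataFrame  # term, estimate, se, t, p
    df_resid: float
    random_variances: dict[str, float]
    cohens_d_by_third: pd.DataFrame  # third, condition, d
    singular: bool = False


def effect_size_cohens_d(group_a, group_b) -> float:
    """Cohen's d with pooled (n-1)-weighted SD; sign is mean(a) - mean(b).

    Returns NaN (with a warning) when the pooled SD is zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled_var = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        warnings.warn("zero pooled SD: Cohen's d undefined", RuntimeWarning)
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def condition_anova(
    table: pd.DataFrame,
    value: str,
    condition: str = "dose",
    vehicle: str = "vehicle",
    alpha: float = 0.05,
) -> ConditionContrast:
    """One-way ANOVA across conditions with Tukey HSD and vehicle effect sizes.

    ``eta_squared`` is SS_between / SS_total.  Cohen's d is condition minus
    vehicle (pooled SD), so improvements that reduce the metric are negative.
    A table with zero within-group variance everywhere is flagged degenerate
    (F undefined, Tukey p set to 1).
    """
    data = table[[condition, value]].dropna()
    groups = {str(c): g[value].to_numpy(dtype=float) for c, g in data.groupby(condition)}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >=2 conditions with >=2 observations each")
    conditions = sorted(groups, key=lambda c: (c != vehicle, c))
    grand = data[value].mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    ss_total = ss_between + ss_within
    df_b = len(groups) - 1
    df_w = len(data) - len(groups)
    degenerate = ss_within == 0
    if degenerate and ss_between == 0:
        f_stat, p_value = 0.0, 1.0
    elif degenerate:
        f_stat, p_value = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p_value = float(sps.f.sf(f_stat, df_b, df_w))
    eta_squared = float(ss_between / ss_total) if ss_total > 0 else 0.0

    if degenerate:
        tukey_df = pd.DataFrame(columns=["group1", "group2", "p_adj"])
        tukey_vs_vehicle = {c: 1.0 for c in conditions if c != vehicle}
    else:
        tk = pairwise_tukeyhsd(
            data[value].to_numpy(dtype=float),
            data[condition].astype(str).to_numpy(),
            alpha=alpha,
        )
        tukey_df = pd.DataFrame(
            tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
        ).rename(columns={"p-adj": "p_adj"})
        tukey_vs_vehicle = {}
        for _, row in tukey_df.iterrows():
            pair = {str(row["group1"]), str(row["group2"])}
            if vehicle in pair:
                other = (pair - {vehicle}).pop()
                tukey_vs_vehicle[other] = float(row["p_adj"])

    cohens = {}
    for cond in conditions:
        if cond == vehicle or vehicle not in groups:
            continue
        try:
            cohens[cond] = effect_size_cohens_d(groups[cond], groups[vehicle])
        except ValueError:
            cohens[cond] = float("nan")

    return ConditionContrast(
        metric=value,
        conditions=conditions,
        means={c: float(groups[c].mean()) for c in conditions},
        sems={c: float(sps.sem(groups[c])) if len(groups[c]) > 1 else float("nan")
              for c in conditions},
        ns={c: len(groups[c]) for c in conditions},
        f_stat=float(f_stat),
        df_between=df_b,
        df_within=df_w,
        p_value=float(p_value),
        eta_squared=eta_squared,
        tukey_p_vs_vehicle=tukey_vs_vehicle,
        cohens_d_vs_vehicle=cohens,
        tukey_all_pairs=tukey_df,
        degenerate=degenerate,
    )


def mixed_model_ttc(
    table: pd.DataFrame,
    value: str = "trials_to_criterion",
    vehicle: str = "vehicle",
    with_interaction: bool = True,
) -> MixedModelResult:
    """Linear mixed model on per-block (median) trials-to-criterion.

    Fixed effects: dose condition (vehicle reference) and, when
    ``with_interaction``, its interaction with the session third.  Random
    effects: subject intercept plus a session-within-subject variance
    component.  On a singular fit the session component is dropped and the
    model refit with the subject intercept alone.
    """
    data = table.dropna(subset=[value]).copy()
    if data["subject"].nunique() < 2:
        raise ValueError("need >=2 subjects for random intercepts")
    data["dose"] = data["dose"].astype(str)
    data["third"] = data["third"].astype(int)
    data["session"] = data["session"].astype(str)
    fixed = f"{value} ~ C(dose, Treatment('{vehicle}'))"
    if with_interaction:
        fixed += f" * C(third)"

    def _fit(vc: dict | None):
        model = smf.mixedlm(
            fixed, data, groups=data["subject"],
            vc_formula=vc, re_formula="1",
        )
        return model.fit(reml=True, method="lbfgs")

    singular = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = _fit({"session": "0 + C(session)"})
            if not np.all(np.isfinite(res.bse_fe)):
                raise np.linalg.LinAlgError("non-finite fixed-effect SEs")
        except (np.linalg.LinAlgError, ValueError):
            singular = True
            res = _fit(None)

    fe = pd.DataFrame(
        {
            "term": res.fe_params.index,
            "estimate": res.fe_params.to_numpy(),
            "se": res.bse_fe.to_numpy(),
            "t": (res.fe_params / res.bse_fe).to_numpy(),
        }
    )
    fe["p"] = 2 * sps.norm.sf(np.abs(fe["t"]))

    d_rows = []
    for third, grp in data.groupby("third"):
        veh = grp.loc[grp["dose"] == vehicle, value]
        for cond in sorted(grp["dose"].unique()):
            if cond == vehicle:
                continue
            vals = grp.loc[grp["dose"] == cond, value]
            if len(vals) >= 2 and len(veh) >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    d = effect_size_cohens_d(vals, veh)
            else:
                d = float("nan")
            d_rows.append({"third": third, "condition": cond, "d": d})

    random_variances = {"subject": float(res.cov_re.iloc[0, 0])}
    if not singular and res.vcomp.size:
        random_variances["session"] = float(res.vcomp[0])
    return MixedModelResult(
        fixed_effects=fe,
        df_resid=float(res.df_resid),
        random_variances=random_variances,
        cohens_d_by_third=pd.DataFrame(d_rows),
        singular=singular,
    )


def fisher_r_to_z(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided p from
    the standard normal.  Undefined at |r| = 1 or n < 4.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if n1 < 4 or n2 < 4:
        raise ValueError("each correlation needs n >= 4")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * float(sps.norm.sf(abs(z)))
    return float(z), p
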