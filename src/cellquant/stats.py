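"""Group summaries and nonparametric comparisons for per-cell measurements.

Figure-style reporting: per-condition box statistics (median, quartiles
by linear interpolation, min/max whiskers), a Kruskal–Wallis omnibus
test with Dunn's post-hoc z-tests against the control condition
(Bonferroni-adjusted, as in Dunn's original procedure), pairwise
two-tailed Mann–Whitney U, and a two-factor ANOVA with Bonferroni
post-tests for time x condition designs such as wound-healing series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_core import CellQuantError


class StatsError(CellQuantError):
    pass


@dataclass(frozen=True)
class GroupSummary:
    condition: str
    n: int
    median: float
    p25: float
    p75: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.p25 <= self.median <= self.p75 <= self.max):
            raise ValueError(f"order statistics out of order for {self.condition!r}")


@dataclass(frozen=True)
class ComparisonReport:
    design: str
    omnibus_stat: float
    omnibus_p: float
    table: pd.DataFrame  # columns: group_a, group_b, stat, p, p_adj


def summarize_groups(values_by_condition: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Box-plot order statistics per condition (quartiles by linear interpolation)."""
    out = []
    for cond, vals in values_by_condition.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise StatsError(f"group {cond!r} is empty")
        q25, q50, q75 = np.percentile(arr, [25, 50, 75], method="linear")
        out.append(
            GroupSummary(
                condition=str(cond),
                n=int(arr.size),
                median=float(q50),
                p25=float(q25),
                p75=float(q75),
                min=float(arr.min()),
                max=float(arr.max()),
            )
        )
    return out


def _dunn_vs_control(
    groups: dict[str, np.ndarray], control: str
) -> pd.DataFrame:
    """Dunn's rank-based z comparisons of each group against the control.

    Uses the pooled mid-ranks with tie correction; two-sided p-values
    from the normal distribution, Bonferroni-adjusted over the number of
    comparisons (Dunn's procedure).
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        k = groups[g].size
        mean_ranks[g] = ranks[start : start + k].mean()
        sizes[g] = k
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    others = [g for g in names if g != control]
    m = len(others)
    for g in others:
        se = np.sqrt(var_base * (1.0 / sizes[control] + 1.0 / sizes[g]))
        z = (mean_ranks[g] - mean_ranks[control]) / se
        p = 2 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": control,
                "group_b": g,
                "stat": float(z),
                "p": float(p),
                "p_adj": float(min(1.0, p * m)),
            }
        )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "stat", "p", "p_adj"])


def compare_groups(
    values_by_condition: Mapping[str, Sequence[float]],
    control: str | None = None,
    design: str = "kruskal-dunn",
) -> ComparisonReport:
    """Compare per-cell values across conditions.

    ``design='kruskal-dunn'``: Kruskal–Wallis omnibus + Dunn post-hoc
    against ``control`` (all pairs if no control is named).
    ``design='mannwhitney'``: two-tailed Mann–Whitney U pairwise vs
    control (or between exactly two groups).
    """
    groups = {
        str(k): np.asarray(v, dtype=float) for k, v in values_by_condition.items()
    }
    if len(groups) < 2:
        raise StatsError("need at least two groups")
    for name, arr in groups.items():
        if arr.size < 2:
            raise StatsError(f"group {name!r} has fewer than 2 values")
    if control is not None and control not in groups:
        raise StatsError(f"control group {control!r} not present")

    if design == "kruskal-dunn":
        stat, p = sps.kruskal(*groups.values())
        if control is None:
            # all-pairs Dunn: reuse the vs-control machinery per pair
            rows = []
            names = list(groups)
            m = len(names) * (len(names) - 1) // 2
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    sub = _dunn_vs_control({a: groups[a], b: groups[b]}, a)
                    row = sub.iloc[0].to_dict()
                    row["p_adj"] = min(1.0, row["p"] * m)
                    rows.append(row)
            table = pd.DataFrame(rows)
        else:
            table = _dunn_vs_control(groups, control)
        return ComparisonReport(
            design=design, omnibus_stat=float(stat), omnibus_p=float(p), table=table
        )

    if design == "mannwhitney":
        names = list(groups)
        if control is None:
            if len(names) != 2:
                raise StatsError("mannwhitney without control needs exactly 2 groups")
            pairs = [(names[0], names[1])]
        else:
            pairs = [(control, g) for g in names if g != control]
        rows = []
        for a, b in pairs:
            res = sps.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "stat": float(res.statistic),
                    "p": float(res.pvalue),
                    "p_adj": float(min(1.0, res.pvalue * len(pairs))),
                }
            )
        table = pd.DataFrame(rows, columns=["group_a", "group_b", "stat", "p", "p_adj"])
        omnibus = table["p"].min() if len(table) else float("nan")
        return ComparisonReport(
            design=design,
            omnibus_stat=float(table["stat"].iloc[0]),
            omnibus_p=float(omnibus),
            table=table,
        )

    raise StatsError(f"unknown design {design!r}")


def compare_two_factor(
    df: pd.DataFrame,
    value_col: str,
    factor_a: str,
    factor_b: str,
) -> ComparisonReport:
    """Two-way ANOVA (type II) with Bonferroni post-tests.

    Intended for wound-style data: ``factor_a`` = condition, ``factor_b``
    = timepoint.  Post-tests compare conditions pairwise within each
    level of ``factor_b`` by Welch t-tests, Bonferroni-adjusted over all
    comparisons.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df.rename(
        columns={value_col: "value", factor_a: "fa", factor_b: "fb"}
    )[["value", "fa", "fb"]]
    model = smf.ols("value ~ C(fa) * C(fb)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    rows = []
    levels_a = sorted(data["fa"].unique())
    levels_b = sorted(data["fb"].unique())
    comparisons = []
    for lb in levels_b:
        sub = data[data["fb"] == lb]
        for i, a1 in enumerate(levels_a):
            for a2 in levels_a[i + 1 :]:
                comparisons.append((lb, a1, a2, sub))
    m = len(comparisons)
    for lb, a1, a2, sub in comparisons:
        x = sub.loc[sub["fa"] == a1, "value"]
        y = sub.loc[sub["fa"] == a2, "value"]
        res = sps.ttest_ind(x, y, equal_var=False)
        rows.append(
            {
                "group_a": f"{a1}@{lb}",
                "group_b": f"{a2}@{lb}",
                "stat": float(res.statistic),
                "p": float(res.pvalue),
                "p_adj": float(min(1.0, res.pvalue * m)),
            }
        )
    return ComparisonReport(
        design="twoway-bonferroni",
        omnibus_stat=float(anova.loc["C(fa)", "F"]),
        omnibus_p=float(anova.loc["C(fa)", "PR(>F)"]),
        table=pd.DataFrame(rows, columns=["group_a", "group_b", "stat", "p", "p_adj"]),
    )
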