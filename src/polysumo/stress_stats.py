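"""Group-comparison statistics for puncta readouts.

Localization percentages are compared with an unpaired two-sided
Mann–Whitney U test (exact by enumeration for small tie-free samples,
otherwise a tie- and continuity-corrected normal approximation).  Puncta
number and intensity across condition x construct/compartment designs use
a two-way ANOVA with Šidák-adjusted pairwise comparisons; unbalanced
designs fall back to Type II sums of squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

EXACT_CUTOFF_DEFAULT = 16  # max n_a + n_b for the exact null distribution


@dataclass
class GroupComparisonResult:
    test_name: str
    group_labels: tuple[str, ...]
    n_per_group: tuple[int, ...]
    statistic: float  # U or F (or t for pairwise contrasts)
    p_value: float
    method: str  # "exact" | "normal_approx" | "f_test" | "t_test"
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value out of [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise ValueError("adjusted_p below p_value")


@lru_cache(maxsize=None)
def _u_counts(n_a: int, n_b: int) -> tuple[int, ...]:
    """Number of rank assignments giving each U value, for tie-free data.

    Classic recurrence: f(a, b, u) = f(a-1, b, u-b) + f(a, b-1, u),
    i.e. the largest rank goes to sample A (contributing b to U_A) or to
    sample B.  Returns counts for u = 0 .. n_a * n_b.
    """
    if n_a == 0 or n_b == 0:
        return (1,)
    upper = n_a * n_b
    left = _u_counts(n_a - 1, n_b)
    right = _u_counts(n_a, n_b - 1)
    out = [0] * (upper + 1)
    for u, cnt in enumerate(left):
        out[u + n_b] += cnt
    for u, cnt in enumerate(right):
        out[u] += cnt
    return tuple(out)


def mann_whitney_u(
    a, b, exact_cutoff: int = EXACT_CUTOFF_DEFAULT
) -> GroupComparisonResult:
    """Two-sided unpaired Mann–Whitney U test.

    The reported statistic is U for the first sample, computed from midrank
    sums.  When ``n_a + n_b <= exact_cutoff`` and there are no ties the
    two-sided p is exact: ``min(1, 2 * min(P(U <= u), P(U >= u)))`` under
    full enumeration of rank assignments.  Otherwise a normal approximation
    with tie correction and a 0.5 continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if not has_ties and n_a + n_b <= exact_cutoff:
        counts = _u_counts(n_a, n_b)
        total = sum(counts)
        u_int = int(round(u_a))
        p_le = sum(counts[: u_int + 1]) / total
        p_ge = sum(counts[u_int:]) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        n = n_a + n_b
        mu = n_a * n_b / 2.0
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = max(0.0, abs(u_a - mu) - 0.5) / math.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(z))
        method = "normal_approx"
    return GroupComparisonResult(
        test_name="mann_whitney_u",
        group_labels=("a", "b"),
        n_per_group=(n_a, n_b),
        statistic=u_a,
        p_value=p,
        method=method,
    )


def sidak_adjust(p: float, m: int) -> float:
    """Šidák family-wise adjustment, 1 - (1 - p)^m."""
    return min(1.0, 1.0 - (1.0 - p) ** m)


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment (available as an alternative)."""
    m = len(p_values)
    order = np.argsort(p_values)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


@dataclass
class AnovaResult:
    """Two-way ANOVA table plus adjusted pairwise comparisons of factor A."""

    table: pd.DataFrame  # rows: factor_a, factor_b, interaction, residual
    comparisons: list[GroupComparisonResult] = field(default_factory=list)
    factor_a: str = ""
    factor_b: str = ""


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    adjust: str = "sidak",
) -> AnovaResult:
    """Two-way ANOVA with interaction on tidy rows.

    Returns SS / df / MS / F / p for both factors, their interaction and
    the residual (Type II sums of squares, which coincide with the balanced
    decomposition on balanced designs), plus all pairwise comparisons of
    factor-A levels (t tests on the residual mean square) adjusted by
    Šidák or Holm.
    """
    for f in (factor_a, factor_b):
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    df = data[[response, factor_a, factor_b]].dropna().copy()
    df = df.rename(columns={response: "_y", factor_a: "_fa", factor_b: "_fb"})
    model = smf.ols("_y ~ C(_fa) * C(_fb)", data=df).fit()
    if model.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    aov = sm.stats.anova_lm(model, typ=2)

    rows = {
        "C(_fa)": factor_a,
        "C(_fb)": factor_b,
        "C(_fa):C(_fb)": f"{factor_a}:{factor_b}",
        "Residual": "residual",
    }
    table = aov.rename(index=rows).loc[list(rows.values())]
    table = table.rename(columns={"sum_sq": "SS", "PR(>F)": "p"})
    table["MS"] = table["SS"] / table["df"]
    table = table[["SS", "df", "MS", "F", "p"]]

    mse = table.loc["residual", "MS"]
    df_resid = table.loc["residual", "df"]
    levels = sorted(df["_fa"].unique())
    pairs = list(combinations(levels, 2))
    comparisons: list[GroupComparisonResult] = []
    raw_ps: list[float] = []
    stats_: list[tuple] = []
    for la, lb in pairs:
        ya = df.loc[df["_fa"] == la, "_y"].to_numpy()
        yb = df.loc[df["_fa"] == lb, "_y"].to_numpy()
        se = math.sqrt(mse * (1.0 / ya.size + 1.0 / yb.size))
        t = (ya.mean() - yb.mean()) / se if se > 0 else 0.0
        p = 2.0 * sps.t.sf(abs(t), df_resid)
        raw_ps.append(min(1.0, p))
        stats_.append((la, lb, ya.size, yb.size, t))
    if adjust == "holm":
        adj = holm_adjust(raw_ps)
    else:
        adj = [sidak_adjust(p, len(pairs)) for p in raw_ps]
    for (la, lb, na, nb, t), p, ap in zip(stats_, raw_ps, adj):
        comparisons.append(
            GroupComparisonResult(
                test_name="pairwise_t",
                group_labels=(str(la), str(lb)),
                n_per_group=(na, nb),
                statistic=float(t),
                p_value=float(p),
                method="t_test",
                adjusted_p=float(ap),
            )
        )
    return AnovaResult(
        table=table, comparisons=comparisons, factor_a=factor_a, factor_b=factor_b
    )
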