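"""Summary-statistic inference: pooled t tests, one-/two-way ANOVA with
Tukey HSD, and trajectory-slope comparison.

Every routine runs from either raw per-animal values or published
(mean, SEM, n) summaries.  The two paths agree to machine precision
whenever the raw data realize the summaries, because the statistics used
here (pooled t, F ratios, studentized range, OLS slopes on clustered ages)
are functions of the per-group means, sample SDs, and counts only.

Summary-mode inputs reconstruct the group SD as SEM·sqrt(n).  Where a
procedure needs an explicit data vector (the two-way Type III fit), a
deterministic realization with the exact sample mean and SD is used; the
resulting ANOVA is exact, not approximate.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import SummaryCell

__all__ = [
    "TestResult",
    "AnovaTerm",
    "AnovaTable",
    "TukeyComparison",
    "SlopeComparison",
    "realize_cell",
    "t_test_two_sample",
    "one_way_anova_tukey",
    "two_way_anova_tukey",
    "slope_compare",
    "p_stars",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    statistic_name: str  # "t", "F" or "q"
    df: float | tuple[float, float]
    p: float
    tails: str = "two"
    method: str = ""
    warning: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class AnovaTerm:
    name: str
    ss: float
    df: float
    ms: float
    F: float | None
    p: float | None
    pct_total_variance: float


@dataclass(frozen=True)
class AnovaTable:
    terms: tuple[AnovaTerm, ...]

    def term(self, name: str) -> AnovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def residual(self) -> AnovaTerm:
        return self.term("residual")

    @property
    def ss_total(self) -> float:
        return sum(t.ss for t in self.terms)


@dataclass(frozen=True)
class TukeyComparison:
    group_a: str
    group_b: str
    diff: float
    q: float
    p: float


@dataclass(frozen=True)
class SlopeComparison:
    slope_a: float
    se_a: float
    slope_b: float
    se_b: float
    t: float
    df: float
    p: float


# ---------------------------------------------------------------------------
# group handling

@dataclass(frozen=True)
class _Group:
    mean: float
    sd: float  # sample SD, n-1 denominator
    n: int

    @property
    def var(self) -> float:
        return self.sd**2


def _as_group(g) -> _Group:
    if isinstance(g, SummaryCell):
        return _Group(mean=g.mean, sd=g.sd, n=g.n)
    arr = np.asarray(g, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("raw group must be a non-empty 1-d array")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return _Group(mean=float(arr.mean()), sd=sd, n=int(arr.size))


def realize_cell(mean: float, sem: float, n: int) -> np.ndarray:
    """Deterministic n-vector with exact sample mean and SD = sem·sqrt(n).

    Built by standardizing a fixed ramp pattern; used wherever an explicit
    data vector is needed to stand in for a published summary.  For n = 1
    the single value is the mean (sem must then be 0).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return np.array([mean], dtype=float)
    base = np.arange(n, dtype=float)
    base -= base.mean()
    base /= np.std(base, ddof=1)
    return mean + sem * math.sqrt(n) * base


# ---------------------------------------------------------------------------
# two-sample t

def t_test_two_sample(a, b, equal_var: bool = True) -> TestResult:
    """Two-tailed two-sample t test from raw values or (mean, SEM, n).

    Default is the pooled-variance Student t with df = n_a + n_b − 2;
    ``equal_var=False`` selects the Welch–Satterthwaite variant.  Groups
    with identical means and zero pooled variance return t = 0, p = 1;
    unequal means with zero variance return p = 0 with a warning.
    """
    ga, gb = _as_group(a), _as_group(b)
    if ga.n + gb.n < 3:
        raise ValueError("need n_a + n_b >= 3 observations")
    if ga.n == 1 and gb.n == 1:
        raise ValueError("cannot test two single-observation groups")
    diff = ga.mean - gb.mean
    if equal_var:
        df = ga.n + gb.n - 2
        sp2 = ((ga.n - 1) * ga.var + (gb.n - 1) * gb.var) / df
        se = math.sqrt(sp2 * (1.0 / ga.n + 1.0 / gb.n))
        method = "student_t_pooled"
    else:
        va, vb = ga.var / ga.n, gb.var / gb.n
        se = math.sqrt(va + vb)
        df = (
            (va + vb) ** 2 / (va**2 / (ga.n - 1) + vb**2 / (gb.n - 1))
            if se > 0
            else ga.n + gb.n - 2
        )
        method = "welch_t"
    if se == 0.0:
        if diff == 0.0:
            return TestResult(0.0, "t", df, 1.0, method=method)
        return TestResult(
            math.copysign(math.inf, diff), "t", df, 0.0, method=method,
            warning="zero pooled variance with unequal means",
        )
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), "t", float(df), float(p), method=method)


# ---------------------------------------------------------------------------
# Tukey HSD from group summaries

def _tukey_pairwise(
    labels: Sequence[str],
    means: Sequence[float],
    ns: Sequence[int],
    ms_within: float,
    df_within: float,
) -> list[TukeyComparison]:
    """All-pairs Tukey HSD (Tukey–Kramer for unbalanced pairs).

    q = |mean_i − mean_j| / sqrt((MSW/2)(1/n_i + 1/n_j)); p from the
    studentized range distribution with k = number of groups.
    """
    k = len(means)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        se = math.sqrt((ms_within / 2.0) * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else math.inf
            p = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_within))
        out.append(TukeyComparison(labels[i], labels[j], float(diff), float(q), min(max(p, 0.0), 1.0)))
    return out


def one_way_anova_tukey(
    groups: Sequence,
    labels: Sequence[str] | None = None,
    compute_tukey: bool = True,
) -> tuple[AnovaTable, list[TukeyComparison]]:
    """One-way fixed-effects ANOVA with Tukey HSD post hoc comparisons.

    Between-group SS comes from the group means, within-group SS from the
    reconstructed (or computed) sample SDs: SSW = Σ (n_i − 1)·s_i².  In
    summary mode every group needs n ≥ 2, otherwise the within-group
    variance is undefined.  ``compute_tukey=False`` skips the post hoc
    pass (the studentized-range integration dominates the cost) and
    returns an empty comparison list.
    """
    gs = [_as_group(g) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.n == 1 for g in gs):
        raise ValueError("every group needs n >= 2 (within-group variance undefined)")
    if labels is None:
        labels = [f"group{i}" for i in range(len(gs))]
    N = sum(g.n for g in gs)
    k = len(gs)
    if N <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = sum(g.n * g.mean for g in gs) / N
    ss_between = sum(g.n * (g.mean - grand) ** 2 for g in gs)
    ss_within = sum((g.n - 1) * g.var for g in gs)
    df_b, df_w = k - 1, N - k
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0.0:
        F = 0.0 if ss_between == 0.0 else math.inf
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        F = ms_b / ms_w
        p = float(sps.f.sf(F, df_b, df_w))
    ss_tot = ss_between + ss_within
    table = AnovaTable(
        terms=(
            AnovaTerm("between", ss_between, df_b, ms_b, float(F), p,
                      100.0 * ss_between / ss_tot if ss_tot > 0 else 0.0),
            AnovaTerm("residual", ss_within, df_w, ms_w, None, None,
                      100.0 * ss_within / ss_tot if ss_tot > 0 else 0.0),
        )
    )
    tukey = (
        _tukey_pairwise(labels, [g.mean for g in gs], [g.n for g in gs], ms_w, df_w)
        if compute_tukey
        else []
    )
    return table, tukey


# ---------------------------------------------------------------------------
# two-way ANOVA

def two_way_anova_tukey(
    cells: Mapping[tuple[str, str], object],
    factor_names: tuple[str, str] = ("genotype", "age"),
) -> tuple[AnovaTable, list[TukeyComparison]]:
    """Two-way fixed-effects ANOVA on an a×b cell grid with Tukey HSD.

    ``cells`` maps (level_1, level_2) to a SummaryCell or a raw 1-d array;
    the grid must be complete with n ≥ 2 per cell.  Balanced designs give
    the classical cell-means decomposition; unbalanced designs use Type III
    sums of squares with sum-to-zero contrasts (the convention of the
    common commercial ANOVA packages), computed via a statsmodels OLS fit
    on an exact summary realization.  ``pct_total_variance`` for a term is
    100·SS_term/SS_total with SS_total the sum over terms plus residual.
    Post hoc Tukey comparisons run across all cell means using the
    residual mean square.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    levels_1 = sorted({k[0] for k in cells})
    levels_2 = sorted({k[1] for k in cells})
    for l1 in levels_1:
        for l2 in levels_2:
            if (l1, l2) not in cells:
                raise ValueError(f"missing cell {(l1, l2)!r}: the grid must be complete")

    rows = []
    groups: list[_Group] = []
    labels: list[str] = []
    for (l1, l2), cell in cells.items():
        if isinstance(cell, SummaryCell):
            if cell.n < 2:
                raise ValueError("every cell needs n >= 2")
            values = realize_cell(cell.mean, cell.sem, cell.n)
        else:
            values = np.asarray(cell, dtype=float)
            if values.size < 2:
                raise ValueError("every cell needs n >= 2")
        groups.append(_as_group(values))
        labels.append(f"{l1}:{l2}")
        for v in values:
            rows.append({"f1": str(l1), "f2": str(l2), "value": float(v)})
    frame = pd.DataFrame(rows)

    model = smf.ols("value ~ C(f1, Sum) * C(f2, Sum)", data=frame).fit()
    aov = anova_lm(model, typ=3)

    def _row(key_part: str) -> pd.Series:
        for idx in aov.index:
            if key_part in idx:
                return aov.loc[idx]
        raise KeyError(key_part)

    r1 = _row("C(f1, Sum):C(f2, Sum)")
    main1 = aov.loc["C(f1, Sum)"]
    main2 = aov.loc["C(f2, Sum)"]
    resid = aov.loc["Residual"]
    ss_total = float(main1.sum_sq + main2.sum_sq + r1.sum_sq + resid.sum_sq)

    def _term(name: str, row: pd.Series, is_resid: bool = False) -> AnovaTerm:
        ss, df = float(row.sum_sq), float(row.df)
        return AnovaTerm(
            name=name,
            ss=ss,
            df=df,
            ms=ss / df,
            F=None if is_resid else float(row.F),
            p=None if is_resid else float(row["PR(>F)"]),
            pct_total_variance=100.0 * ss / ss_total if ss_total > 0 else 0.0,
        )

    table = AnovaTable(
        terms=(
            _term(factor_names[0], main1),
            _term(factor_names[1], main2),
            _term(f"{factor_names[0]}:{factor_names[1]}", r1),
            _term("residual", resid, is_resid=True),
        )
    )
    ms_w = table.residual.ms
    df_w = table.residual.df
    tukey = _tukey_pairwise(
        labels, [g.mean for g in groups], [g.n for g in groups], ms_w, df_w
    )
    return table, tukey


# ---------------------------------------------------------------------------
# slope comparison

def _as_xy(group) -> tuple[np.ndarray, np.ndarray]:
    if (
        isinstance(group, Sequence)
        and len(group) > 0
        and isinstance(group[0], SummaryCell)
    ):
        xs, ys = [], []
        for cell in group:
            vals = realize_cell(cell.mean, cell.sem, cell.n)
            xs.extend([cell.age_months] * cell.n)
            ys.extend(vals.tolist())
        return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)
    pairs = np.asarray(group, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("raw slope group must be an iterable of (age, value) pairs")
    return pairs[:, 0], pairs[:, 1]


def slope_compare(group_a, group_b) -> SlopeComparison:
    """OLS trajectory slope per group and a two-tailed test of equality.

    Groups are (age, value) observations or lists of SummaryCell at
    distinct ages (realized exactly).  With two age clusters and balanced
    n the slope reduces to Δmean/Δage.  Equality is tested by
    t = (b₁ − b₂)/sqrt(SE₁² + SE₂²) on the summed residual df.
    """
    slopes, ses, dfs = [], [], []
    for group in (group_a, group_b):
        x, y = _as_xy(group)
        if np.unique(x).size < 2:
            raise ValueError("each group must span at least two distinct ages")
        res = sps.linregress(x, y)
        slopes.append(float(res.slope))
        ses.append(float(res.stderr))
        dfs.append(x.size - 2)
    se = math.sqrt(ses[0] ** 2 + ses[1] ** 2)
    df = dfs[0] + dfs[1]
    if se == 0.0:
        t = 0.0 if slopes[0] == slopes[1] else math.copysign(math.inf, slopes[0] - slopes[1])
        p = 1.0 if slopes[0] == slopes[1] else 0.0
    else:
        t = (slopes[0] - slopes[1]) / se
        p = 2.0 * float(sps.t.sf(abs(t), df))
    return SlopeComparison(slopes[0], ses[0], slopes[1], ses[1], float(t), float(df), min(p, 1.0))


def p_stars(p: float) -> str:
    """Figure-style significance bins: * ≤0.05, ** ≤0.01, *** ≤0.001, **** ≤0.0001."""
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"
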