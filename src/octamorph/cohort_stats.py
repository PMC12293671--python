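"""Cohort-level comparison of vascular metrics across the four study groups.

The analysis mirrors a standard clinical workflow: for each parameter,
per-group Shapiro–Wilk normality testing routes the comparison either to
one-way ANOVA (all groups normal) followed by Tukey's multiple
comparisons, or to the Kruskal–Wallis rank test followed by Dunn's test
with Bonferroni-capped multiplicity adjustment.  Spearman's rank
correlation is provided for metric-vs-function association (e.g. visual
acuity against wall-to-lumen ratio).

Omnibus results are reported the way clinical papers print them:
F(df1, df2) with df1 = k-1 and df2 = N-k for ANOVA, H(df) with
df = k-1 for Kruskal–Wallis.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSample",
    "OmnibusResult",
    "PosthocResult",
    "CorrelationResult",
    "normality_gate",
    "one_way_anova",
    "kruskal_wallis",
    "dunn_posthoc",
    "tukey_posthoc",
    "spearman_correlation",
    "run_full_comparison",
    "render_pairwise_table",
]


@dataclass(frozen=True)
class GroupSample:
    group: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class OmnibusResult:
    test: str                       # "anova" | "kruskal_wallis"
    statistic: float                # F or H
    df: tuple[int, ...]             # (df1, df2) for F, (df,) for H
    p_value: float


@dataclass(frozen=True)
class PosthocResult:
    pair: tuple[str, str]
    method: str                     # "tukey" | "dunn"
    adjusted_p: float


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p_value: float


def _check_groups(groups: Sequence[GroupSample], min_k: int = 2, min_n: int = 1) -> None:
    if len(groups) < min_k:
        raise ValueError(f"need at least {min_k} groups, got {len(groups)}")
    for g in groups:
        if g.n < min_n:
            raise ValueError(f"group {g.group!r} has n={g.n} < {min_n}")


def normality_gate(groups: Sequence[GroupSample], alpha: float = 0.05) -> str:
    """Choose the omnibus test: "anova" iff every group passes Shapiro–Wilk.

    A zero-variance group has no defined Shapiro–Wilk statistic; such
    degenerate input routes to the rank-based branch with a warning.
    """
    _check_groups(groups, min_k=2, min_n=3)
    for g in groups:
        vals = np.asarray(g.values)
        if np.ptp(vals) == 0:
            warnings.warn(
                f"group {g.group!r} has zero variance; routing to Kruskal–Wallis",
                stacklevel=2,
            )
            return "kruskal_wallis"
        if stats.shapiro(vals).pvalue < alpha:
            return "kruskal_wallis"
    return "anova"


def one_way_anova(groups: Sequence[GroupSample]) -> OmnibusResult:
    """Classical one-way ANOVA; df = (k-1, N-k)."""
    _check_groups(groups, min_k=2, min_n=2)
    arrays = [np.asarray(g.values) for g in groups]
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group; F undefined")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    res = stats.f_oneway(*arrays)
    return OmnibusResult(
        test="anova",
        statistic=float(res.statistic),
        df=(k - 1, n_total - k),
        p_value=float(res.pvalue),
    )


def kruskal_wallis(groups: Sequence[GroupSample]) -> OmnibusResult:
    """Kruskal–Wallis H with tie correction; df = k-1, chi-square p."""
    _check_groups(groups, min_k=2, min_n=1)
    arrays = [np.asarray(g.values) for g in groups]
    res = stats.kruskal(*arrays)
    return OmnibusResult(
        test="kruskal_wallis",
        statistic=float(res.statistic),
        df=(len(arrays) - 1,),
        p_value=float(res.pvalue),
    )


def dunn_posthoc(
    groups: Sequence[GroupSample], adjust: str = "bonferroni"
) -> list[PosthocResult]:
    """Dunn's pairwise mean-rank test after Kruskal–Wallis.

    For groups i, j with mean ranks Ri, Rj over the pooled sample of size
    N, the statistic is

        z = (Ri - Rj) / sqrt((N(N+1)/12 - T) (1/ni + 1/nj)),

    with tie correction T = sum(t^3 - t) / (12 (N - 1)) over tie groups.
    Two-sided normal p-values are adjusted over the m = k(k-1)/2 pairs:
    Bonferroni (min(1, m*p), default, matching common clinical software)
    or Holm step-down.
    """
    _check_groups(groups, min_k=2, min_n=1)
    if adjust not in ("bonferroni", "holm"):
        raise ValueError("adjust must be 'bonferroni' or 'holm'")
    pooled = np.concatenate([np.asarray(g.values) for g in groups])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # per-group mean ranks
    mean_rank: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for g in groups:
        mean_rank[g.group] = float(ranks[start:start + g.n].mean())
        sizes[g.group] = g.n
        start += g.n
    # tie correction over the pooled sample
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations([g.group for g in groups], 2))
    raw = []
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        raw.append(2.0 * stats.norm.sf(abs(z)))
    m = len(pairs)
    if adjust == "bonferroni":
        adj = [min(1.0, m * p) for p in raw]
    else:  # holm
        order = np.argsort(raw)
        adj = [0.0] * m
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (m - rank_i) * raw[idx])
            adj[idx] = min(1.0, running)
    return [
        PosthocResult(pair=pair, method="dunn", adjusted_p=float(p))
        for pair, p in zip(pairs, adj)
    ]


def tukey_posthoc(groups: Sequence[GroupSample]) -> list[PosthocResult]:
    """Tukey's multiple comparisons (Tukey–Kramer for unbalanced n)."""
    _check_groups(groups, min_k=2, min_n=2)
    arrays = [np.asarray(g.values) for g in groups]
    pooled_var = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if pooled_var == 0:
        raise ValueError("zero pooled within-group variance; Tukey undefined")
    res = stats.tukey_hsd(*arrays)
    out = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        out.append(
            PosthocResult(
                pair=(groups[i].group, groups[j].group),
                method="tukey",
                adjusted_p=float(res.pvalue[i, j]),
            )
        )
    return out


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's rank correlation with two-sided t-approximation p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), n=int(x.size),
                             p_value=float(res.pvalue))


def _groups_from_table(
    table: pd.DataFrame, parameter: str, group_col: str, group_order: Sequence[str]
) -> list[GroupSample]:
    if parameter not in table.columns:
        raise KeyError(f"parameter column {parameter!r} missing from table")
    out = []
    for g in group_order:
        vals = table.loc[table[group_col] == g, parameter].dropna()
        out.append(GroupSample(group=g, values=tuple(vals)))
    return out


def run_full_comparison(
    table: pd.DataFrame,
    parameters: Sequence[str],
    group_col: str = "group",
    alpha: float = 0.05,
    dunn_adjust: str = "bonferroni",
) -> dict[str, dict]:
    """Per-parameter normality-gated omnibus test plus matched post hoc.

    For each parameter: Shapiro–Wilk per group decides ANOVA vs
    Kruskal–Wallis; when the omnibus p is below ``alpha`` the matching
    post hoc (Tukey after ANOVA, Dunn after Kruskal–Wallis) produces one
    adjusted p per unordered group pair (6 pairs for 4 groups); otherwise
    ``posthoc`` is None.
    """
    if group_col not in table.columns:
        raise KeyError(f"group column {group_col!r} missing from table")
    group_order = [g for g in table[group_col].drop_duplicates()]
    if len(group_order) < 2:
        raise ValueError("need at least two groups")
    report: dict[str, dict] = {}
    for param in parameters:
        groups = _groups_from_table(table, param, group_col, group_order)
        branch = normality_gate(groups, alpha=alpha)
        omnibus = one_way_anova(groups) if branch == "anova" else kruskal_wallis(groups)
        posthoc = None
        if omnibus.p_value < alpha:
            posthoc = (
                tukey_posthoc(groups)
                if branch == "anova"
                else dunn_posthoc(groups, adjust=dunn_adjust)
            )
        report[param] = {"omnibus": omnibus, "posthoc": posthoc}
    return report


def render_pairwise_table(report: Mapping[str, dict]) -> pd.DataFrame:
    """Long-format table of the comparison report (one row per parameter
    x pair; omnibus columns repeated; NaN adjusted p when post hoc not run)."""
    rows = []
    for param, res in report.items():
        om: OmnibusResult = res["omnibus"]
        posthoc = res["posthoc"]
        if posthoc is None:
            rows.append({
                "parameter": param, "test": om.test, "statistic": om.statistic,
                "df": "/".join(str(d) for d in om.df), "p_value": om.p_value,
                "pair": None, "method": None, "adjusted_p": np.nan,
            })
        else:
            for ph in posthoc:
                rows.append({
                    "parameter": param, "test": om.test, "statistic": om.statistic,
                    "df": "/".join(str(d) for d in om.df), "p_value": om.p_value,
                    "pair": f"{ph.pair[0]} vs {ph.pair[1]}", "method": ph.method,
                    "adjusted_p": ph.adjusted_p,
                })
    return pd.DataFrame(rows)
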