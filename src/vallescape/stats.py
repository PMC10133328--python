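"""Group-comparison workflow and indicator correlogram.

The comparison of an indicator across the five management groups follows a
routed workflow: Shapiro-Wilk on the pooled within-group residuals and
Bartlett's homoscedasticity test decide between the parametric branch
(one-way ANOVA + Tukey HSD) and the nonparametric branch (Kruskal-Wallis H
on ranks + Dunn's post-hoc pairwise test).  Pairwise results are condensed
into per-group significance annotations (the letters drawn above group
plots: for each group, the set of other groups it differs from at the 95%
confidence level).

Trade-offs between indicator aggregates are screened with a Spearman
rank-correlation matrix over the six category aggregates (three CICES
categories x capacity/flow), with pairwise-complete exclusion of flagged
missing units.

The Dunn test is computed from the pooled ranking shared with the
Kruskal-Wallis statistic: for groups i, j with mean ranks R̄_i, R̄_j over N
pooled observations,

    z_ij = (R̄_i - R̄_j) / sqrt( (N(N+1)/12 - T) (1/n_i + 1/n_j) ),
    T = Σ_ties (t^3 - t) / (12 (N - 1)),

with a two-sided normal p-value and an optional multiplicity adjustment
(none by default; Holm, Bonferroni and Benjamini-Hochberg available).
"""

from __future__ import annotations

import itertools
import warnings
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

ADJUSTMENTS = {"none": None, "holm": "holm", "bonferroni": "bonferroni", "bh": "fdr_bh"}


def _as_groups(values_by_group: dict) -> dict[str, np.ndarray]:
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    groups = {k: v[~np.isnan(v)] for k, v in groups.items()}
    return {k: v for k, v in groups.items() if v.size > 0}


def route_test(values_by_group: dict, alpha: float = 0.05) -> str:
    """Decide between the parametric and nonparametric branch.

    Parametric iff Shapiro-Wilk on the pooled within-group residuals
    (observations minus their group mean — the quantity whose normality
    ANOVA actually assumes) passes at ``alpha`` AND Bartlett's test passes
    at ``alpha``; otherwise nonparametric.
    """
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {name!r} has {v.size} observations; need >= 3")
    residuals = np.concatenate([v - v.mean() for v in groups.values()])
    _, p_shapiro = sps.shapiro(residuals)
    with np.errstate(divide="ignore"), warnings.catch_warnings():
        # zero-variance groups (structurally absent flows) make Bartlett's
        # statistic infinite; that is a decisive nonparametric routing, not
        # an error
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p_bartlett = sps.bartlett(*groups.values())
    if np.isnan(p_bartlett):
        p_bartlett = 0.0
    return "parametric" if (p_shapiro > alpha and p_bartlett > alpha) else "nonparametric"


def kruskal_wallis(values_by_group: dict) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square (k-1 df) p-value."""
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(list(groups.values()))
    if np.unique(pooled).size == 1:
        raise ValueError("degenerate input: all values identical (H undefined under tie correction)")
    h, p = sps.kruskal(*groups.values())
    return float(h), float(p)


def dunn_posthoc(values_by_group: dict, adjustment: str = "none") -> pd.DataFrame:
    """Dunn's pairwise post-hoc test on the pooled ranks.

    Returns one row per unordered group pair with columns ``group1``,
    ``group2``, ``z``, ``p``, ``p_adjusted`` and the adjustment used.
    """
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"adjustment must be one of {sorted(ADJUSTMENTS)}")
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    if np.unique(pooled).size == 1:
        raise ValueError("degenerate input: all values identical")
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g in names:
        n = groups[g].size
        mean_ranks[g] = ranks[start : start + n].mean()
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    method = ADJUSTMENTS[adjustment]
    if method is None:
        table["p_adjusted"] = table["p"]
    else:
        table["p_adjusted"] = multipletests(table["p"].to_numpy(), method=method)[1]
    table["adjustment"] = adjustment
    return table


def anova_tukey(values_by_group: dict) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA with an exploratory Tukey HSD pairwise table.

    Returns ``(F, p, pairwise)`` where the pairwise frame has ``group1``,
    ``group2``, ``p_adjusted`` (the family-wise Tukey p) and mean
    difference columns.
    """
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(list(groups.values()))
    if np.unique(pooled).size == 1:
        raise ValueError("degenerate input: all values identical")
    f, p = sps.f_oneway(*groups.values())
    labels = np.concatenate([[g] * groups[g].size for g in groups])
    tukey = pairwise_tukeyhsd(pooled, labels)
    frame = pd.DataFrame(
        tukey.summary().data[1:],
        columns=[str(c) for c in tukey.summary().data[0]],
    )
    pairwise = pd.DataFrame(
        {
            "group1": frame["group1"],
            "group2": frame["group2"],
            "meandiff": frame["meandiff"].astype(float),
            "p": frame["p-adj"].astype(float),
            "p_adjusted": frame["p-adj"].astype(float),
        }
    )
    pairwise["adjustment"] = "tukey"
    return float(f), float(p), pairwise


def significance_letters(pairwise: pd.DataFrame, alpha: float = 0.05) -> dict[str, set[str]]:
    """Per-group significance annotations from a pairwise table.

    For each group, the set of other groups it differs from at ``alpha``
    (on the adjusted p-value) — the annotation drawn above group plots.
    """
    groups = sorted(set(pairwise["group1"]) | set(pairwise["group2"]))
    annot: dict[str, set[str]] = {g: set() for g in groups}
    for _, row in pairwise.iterrows():
        if row["p_adjusted"] < alpha:
            annot[row["group1"]].add(row["group2"])
            annot[row["group2"]].add(row["group1"])
    return annot


@dataclass
class GroupComparisonResult:
    """Routed comparison of one indicator across management groups."""

    indicator: str
    routing: str
    omnibus_statistic: float
    omnibus_p: float
    pairwise: pd.DataFrame = field(repr=False)
    annotations: dict[str, set[str]] = field(repr=False)


def compare_groups(
    indicator: str,
    values_by_group: dict,
    alpha: float = 0.05,
    adjustment: str = "none",
) -> GroupComparisonResult:
    """Full routed workflow for one indicator.

    Routes to Kruskal-Wallis + Dunn or ANOVA + Tukey, then derives the
    per-group significance annotations at ``alpha``.
    """
    routing = route_test(values_by_group, alpha=alpha)
    if routing == "parametric":
        stat, p, pairwise = anova_tukey(values_by_group)
    else:
        stat, p = kruskal_wallis(values_by_group)
        pairwise = dunn_posthoc(values_by_group, adjustment=adjustment)
    return GroupComparisonResult(
        indicator=indicator,
        routing=routing,
        omnibus_statistic=stat,
        omnibus_p=p,
        pairwise=pairwise,
        annotations=significance_letters(pairwise, alpha=alpha),
    )


def spearman_correlogram(aggregated: pd.DataFrame, columns=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank-correlation matrix over aggregate columns.

    Ranks use average ranks for ties; missing units are excluded pairwise.
    Returns ``(rho, p)`` frames; requires >= 4 pairwise-complete units for
    every pair.
    """
    cols = list(columns) if columns is not None else list(aggregated.columns)
    data = aggregated[cols]
    n = len(cols)
    rho = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((n, n)), index=cols, columns=cols)
    for i, j in itertools.combinations(range(n), 2):
        pair = data[[cols[i], cols[j]]].dropna()
        if len(pair) < 4:
            raise ValueError(
                f"<4 complete units for pair ({cols[i]}, {cols[j]}); correlation undefined"
            )
        r, p = sps.spearmanr(pair[cols[i]], pair[cols[j]])
        rho.iloc[i, j] = rho.iloc[j, i] = r
        pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return rho, pmat
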