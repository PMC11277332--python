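"""Nonparametric group comparison: Kruskal-Wallis, Dunn post hoc, chi-square.

The four differentiation-grade groups are compared per variable with the
tie-corrected Kruskal-Wallis rank test; variables that reach significance
are followed up with Dunn's pairwise z tests on the pooled midranks
(unadjusted by default, Bonferroni/Holm available).  Categorical manifest
variables are compared with the Pearson chi-square test.  Summaries mirror
the usual clinical-table layout: median [min; max] and mean (sd) per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GROUP_ORDER


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p_value: float


@dataclass(frozen=True)
class DunnPair:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupComparisonResult:
    variable: str
    kw: KWResult
    dunn: list[DunnPair] = field(default_factory=list)
    significant: bool = False


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t ** 3 - t).sum())


def _check_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need >= 2 groups")
    for i, a in enumerate(arrs):
        if a.size == 0:
            raise ValueError(f"group {i} is empty")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {i} contains non-finite values")
    if sum(a.size for a in arrs) < 3:
        raise ValueError("need at least 3 observations in total")
    return arrs


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Tie-corrected Kruskal-Wallis H test with midranks.

    H = [12/(N(N+1)) * sum R_g^2/n_g - 3(N+1)] / (1 - sum(t^3-t)/(N^3-N));
    p comes from the chi-square upper tail with df = (#groups - 1).
    All-identical data yield H = 0, p = 1.
    """
    arrs = _check_groups(groups)
    pooled = np.concatenate(arrs)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    correction = 1.0 - _tie_term(pooled) / (N ** 3 - N)
    df = len(arrs) - 1
    if correction == 0.0:  # every observation identical
        return KWResult(H=0.0, df=df, p_value=1.0)
    start = 0
    rank_sq = 0.0
    for a in arrs:
        R = ranks[start:start + a.size].sum()
        rank_sq += R * R / a.size
        start += a.size
    H = (12.0 / (N * (N + 1)) * rank_sq - 3.0 * (N + 1)) / correction
    H = max(H, 0.0)
    return KWResult(H=float(H), df=df, p_value=float(sps.chi2.sf(H, df)))


def _adjust(p_raw: list[float], method: str) -> list[float]:
    m = len(p_raw)
    if method == "none":
        return list(p_raw)
    if method == "bonferroni":
        return [min(1.0, m * p) for p in p_raw]
    if method == "holm":
        order = np.argsort(p_raw)
        adj = [0.0] * m
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw[idx])
            adj[idx] = min(1.0, running)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: str = "none",
) -> list[DunnPair]:
    """Dunn's pairwise z tests on pooled midranks with tie correction.

    z = (Rbar_a - Rbar_b) / sqrt([N(N+1)/12 - sum(t^3-t)/(12(N-1))]
                                 * (1/n_a + 1/n_b)),
    two-sided p from the standard normal.
    """
    arrs = _check_groups(groups)
    if labels is None:
        labels = [str(i) for i in range(len(arrs))]
    pooled = np.concatenate(arrs)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrs:
        mean_ranks.append(ranks[start:start + a.size].mean())
        start += a.size
    var_term = N * (N + 1) / 12.0 - _tie_term(pooled) / (12.0 * (N - 1))
    pairs = list(combinations(range(len(arrs)), 2))
    zs, ps = [], []
    for a, b in pairs:
        denom = math.sqrt(var_term * (1.0 / arrs[a].size + 1.0 / arrs[b].size))
        z = 0.0 if denom == 0 else (mean_ranks[a] - mean_ranks[b]) / denom
        zs.append(z)
        ps.append(float(2.0 * sps.norm.sf(abs(z))))
    p_adj = _adjust(ps, adjust)
    return [
        DunnPair(labels[a], labels[b], float(z), p, pa)
        for (a, b), z, p, pa in zip(pairs, zs, ps, p_adj)
    ]


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p_value: float
    low_expected: bool  # any expected count < 5
    dropped_rows: tuple[int, ...] = ()
    dropped_cols: tuple[int, ...] = ()


def chi_square_test(table: Sequence[Sequence[float]]) -> Chi2Result:
    """Pearson chi-square test of independence (no continuity correction).

    Zero-margin rows/columns are dropped with a record; a warning flag is set
    when any expected count falls below 5.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if (obs < 0).any():
        raise ValueError("negative counts")
    row_keep = obs.sum(axis=1) > 0
    col_keep = obs.sum(axis=0) > 0
    dropped_rows = tuple(np.nonzero(~row_keep)[0].tolist())
    dropped_cols = tuple(np.nonzero(~col_keep)[0].tolist())
    obs = obs[row_keep][:, col_keep]
    r, c = obs.shape
    if r < 2 or c < 2:
        raise ValueError("need >= 2 rows and >= 2 columns with positive margins")
    N = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / N
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    return Chi2Result(
        chi2=chi2,
        df=df,
        p_value=float(sps.chi2.sf(chi2, df)),
        low_expected=bool((expected < 5).any()),
        dropped_rows=dropped_rows,
        dropped_cols=dropped_cols,
    )


def summarize_groups(
    df: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "group",
    group_order: Sequence[str] = GROUP_ORDER,
) -> pd.DataFrame:
    """Per variable x group: n, median, min, max, mean, sd and formatted cells.

    sd uses the n-1 denominator; a single-observation group reports sd = 0
    with a flag.
    """
    rows = []
    for var in variables:
        for g in group_order:
            vals = df.loc[df[group_col] == g, var].to_numpy(dtype=float)
            if vals.size == 0:
                continue
            med = float(np.median(vals))
            lo, hi = float(vals.min()), float(vals.max())
            mean = float(vals.mean())
            sd_flag = vals.size == 1
            sd = 0.0 if sd_flag else float(vals.std(ddof=1))
            rows.append(
                {
                    "variable": var,
                    "group": g,
                    "n": int(vals.size),
                    "median": med,
                    "min": lo,
                    "max": hi,
                    "mean": mean,
                    "sd": sd,
                    "sd_flag": sd_flag,
                    "median_range": f"{med:.3g} [{lo:.3g};{hi:.3g}]",
                    "mean_sd": f"{mean:.3g} ({sd:.3g})",
                }
            )
    return pd.DataFrame(rows)


def compare_all_features(
    df: pd.DataFrame,
    variables: Sequence[str] | None = None,
    group_col: str = "group",
    alpha: float = 0.05,
    dunn_adjust: str = "none",
    gate_dunn: bool = True,
    group_order: Sequence[str] = GROUP_ORDER,
) -> list[GroupComparisonResult]:
    """Kruskal-Wallis per numeric variable, Dunn where significant.

    Variables default to every numeric column except the group column, in
    their table order ('age' first when present, then the reduced features).
    Dunn follow-up is gated on KW significance (classical protected
    procedure) unless ``gate_dunn`` is False.
    """
    present = [g for g in group_order if (df[group_col] == g).any()]
    if len(present) < 2:
        raise ValueError("need >= 2 groups")
    if variables is None:
        numeric = [
            c for c in df.columns
            if c != group_col and pd.api.types.is_numeric_dtype(df[c])
        ]
        variables = (["age"] if "age" in numeric else []) + [c for c in numeric if c != "age"]
    results = []
    for var in variables:
        groups = [df.loc[df[group_col] == g, var].to_numpy(dtype=float) for g in present]
        kw = kruskal_wallis(groups)
        res = GroupComparisonResult(variable=var, kw=kw, significant=kw.p_value < alpha)
        if res.significant or not gate_dunn:
            res.dunn = dunn_posthoc(groups, labels=present, adjust=dunn_adjust)
        results.append(res)
    return results


def comparison_to_frame(results: Sequence[GroupComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "H": r.kw.H,
                "df": r.kw.df,
                "p_value": r.kw.p_value,
                "significant": r.significant,
            }
            for r in results
        ]
    )
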