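"""Group-level inference: rank-sum tests, BH-FDR, Spearman correlations.

Both the rank-sum W (sum of the ranks of the first sample) and the
Mann-Whitney U = W - n1(n1+1)/2 are reported, so results are comparable
with software that prints either statistic.  P-values are exact (full
null enumeration) for combined samples up to 20 without ties, and use
the tie-corrected normal approximation otherwise — the study's n = 9/9
sits squarely in the exact regime.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_TAILS = {"greater": "greater", "less": "less", "two-sided": "two-sided"}

#: exact-enumeration limit for the rank-sum null (combined sample size)
EXACT_LIMIT = 20


@dataclass
class GroupResult:
    """One group comparison."""

    measure: str
    comparison: str
    tail: str
    w_statistic: float  # rank-sum of sample x
    u_statistic: float
    p_raw: float
    p_adjusted: Optional[float] = None
    n_x: int = 0
    n_y: int = 0
    mean_x: float = np.nan
    sd_x: float = np.nan
    mean_y: float = np.nan
    sd_y: float = np.nan
    method: str = ""


@dataclass
class CorrelationCell:
    measure_x: str
    measure_y: str
    rho: float
    p_two_sided: float
    n: int
    degenerate: bool = False


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    tail: str = "two-sided",
    measure: str = "",
    comparison: str = "",
) -> GroupResult:
    """Wilcoxon rank-sum / Mann-Whitney comparison of two samples.

    ``tail='greater'`` tests whether ``x`` tends to exceed ``y``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {tuple(_TAILS)}")
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0

    ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    exact = (n1 + n2 <= EXACT_LIMIT) and not ties
    res = sps.mannwhitneyu(
        x, y, alternative=tail, method="exact" if exact else "asymptotic"
    )
    return GroupResult(
        measure=measure,
        comparison=comparison,
        tail=tail,
        w_statistic=w,
        u_statistic=float(u),
        p_raw=float(res.pvalue),
        n_x=n1,
        n_y=n2,
        mean_x=float(x.mean()),
        sd_x=float(x.std(ddof=1)) if n1 > 1 else np.nan,
        mean_y=float(y.mean()),
        sd_y=float(y.std(ddof=1)) if n2 > 1 else np.nan,
        method="exact" if exact else "normal approximation (tie-corrected)",
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@lru_cache(maxsize=8)
def _exact_spearman_null(n: int) -> np.ndarray:
    """All n! Spearman rho values for tie-free data of size n."""
    base = np.arange(n)
    perms = np.array(list(permutations(base)))
    d2 = ((perms - base) ** 2).sum(axis=1)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def spearman(
    x: Sequence[float], y: Sequence[float], measure_x: str = "x", measure_y: str = "y"
) -> CorrelationCell:
    """Spearman rank correlation with a two-sided p-value.

    Tie-free samples of n <= 9 get an exact permutation p; larger or
    tied samples use the t-approximation.  Constant input yields an
    undefined (NaN) rho with the ``degenerate`` flag set.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationCell(measure_x, measure_y, np.nan, np.nan, n, degenerate=True)
    rho, p_t = sps.spearmanr(x, y)
    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    if tie_free and n <= 9:
        null = _exact_spearman_null(n)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        p = float(p_t)
    return CorrelationCell(measure_x, measure_y, float(rho), p, n)


def correlation_matrix(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Pairwise Spearman matrix over the given columns; returns a long
    table (measure_x, measure_y, rho, p_two_sided, n)."""
    rows = []
    for i, cx in enumerate(columns):
        for cy in columns[i:]:
            sub = df[[cx, cy]].dropna()
            if cx == cy:
                rows.append(CorrelationCell(cx, cy, 1.0, 0.0, len(sub)))
                continue
            rows.append(spearman(sub[cx], sub[cy], cx, cy))
    return pd.DataFrame([vars(c) for c in rows])


# ---------------------------------------------------------------------------
# hypothesis suite
# ---------------------------------------------------------------------------

#: time comparisons and tails of the behavioral (H2) family
_H2_PLAN = [
    ("pre-to-post", "less"),
    ("pre-to-during", "less"),
    ("during-to-post", "two-sided"),
]

#: commissions leave inference when the per-condition maximum is this small
COMMISSION_DISREGARD_MAX = 4


def _changes(change_df: pd.DataFrame, measure: str, comparison: str):
    sub = change_df[(change_df["measure"] == measure) & (change_df["comparison"] == comparison)]
    x = sub.loc[sub["group"] == "stim", "value"].to_numpy()
    y = sub.loc[sub["group"] == "sham", "value"].to_numpy()
    return x, y


def run_hypothesis_suite(
    outcomes: pd.DataFrame,
    commission_disregard_max: int = COMMISSION_DISREGARD_MAX,
) -> pd.DataFrame:
    """The study's inference plan on a long-format outcome table.

    * H1 — right-tailed rank-sum on relative P300-amplitude change
      pre-to-post (stim > sham), uncorrected.
    * H2 — per behavioral measure (RT-M, RT-V relative; omissions
      absolute): left-tailed pre-to-post and pre-to-during, two-sided
      during-to-post, BH-adjusted within the measure's three
      comparisons.  Commissions are reported descriptively only when
      their per-condition maximum is <= ``commission_disregard_max``.
    * ERSP window maximum — right-tailed on relative pre-to-post change,
      uncorrected.

    Measures absent from ``outcomes`` (all-NaN columns) are skipped.
    """
    from .outcomes import change_table

    groups = set(outcomes["group"])
    if not {"stim", "sham"}.issubset(groups):
        raise ValueError(f"both groups required, got {groups}")
    ch = change_table(outcomes)
    results: list[GroupResult] = []

    def have(measure: str, comparison: str) -> bool:
        x, y = _changes(ch, measure, comparison)
        return len(x) > 0 and len(y) > 0

    if have("p3_amp_uv", "pre-to-post"):
        x, y = _changes(ch, "p3_amp_uv", "pre-to-post")
        results.append(rank_sum_test(x, y, "greater", "p3_amp_uv", "pre-to-post"))

    h2_measures = ["rt_mean_ms", "rt_sd_ms", "omissions"]
    if "commissions" in outcomes.columns and outcomes["commissions"].notna().any():
        if outcomes["commissions"].max() > commission_disregard_max:
            h2_measures.append("commissions")
    for measure in h2_measures:
        fam = []
        for comparison, tail in _H2_PLAN:
            if have(measure, comparison):
                x, y = _changes(ch, measure, comparison)
                fam.append(rank_sum_test(x, y, tail, measure, comparison))
        if fam:
            adj = bh_adjust([r.p_raw for r in fam])
            for r, a in zip(fam, adj):
                r.p_adjusted = float(a)
            results.extend(fam)

    if have("ersp_max_db", "pre-to-post"):
        x, y = _changes(ch, "ersp_max_db", "pre-to-post")
        results.append(rank_sum_test(x, y, "greater", "ersp_max_db", "pre-to-post"))

    df = pd.DataFrame([vars(r) for r in results])
    return df.rename(
        columns={
            "w_statistic": "W",
            "u_statistic": "U",
            "mean_x": "mean_stim",
            "sd_x": "sd_stim",
            "mean_y": "mean_sham",
            "sd_y": "sd_sham",
        }
    )
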