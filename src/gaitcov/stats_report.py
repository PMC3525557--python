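"""Aggregation to participant x speed level and simple inferential statistics.

Dependent variables are transformed first (log COV, Fisher z') and then
averaged across heel-strike sides and the two trials within each speed, one
value per participant x speed cell.  Group-level inference uses one-sample
and Welch t-tests, Cohen's d, and Holm's step-down multiple-comparison
correction.  Repeated-measures ANOVA is deliberately not reimplemented: the
long-format participant table is directly consumable by standard routines
(statsmodels, R afex/ez).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

KEY_COLS = ["participant", "group", "speed", "variable"]
CELL_COLS = ["participant", "speed", "trial", "side", "variable"]


def aggregate(results: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Average transformed per-ensemble values to participant x speed cells.

    ``results`` is long-format with columns participant, group, speed, trial,
    side, variable and the (already transformed) value column.  Duplicate
    (participant, speed, trial, side, variable) keys are rejected; cells with
    fewer than the expected 4 contributing ensembles (2 trials x 2 sides) are
    kept but flagged via ``complete = False``.
    """
    required = set(CELL_COLS + ["group", value_col])
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    dup = results.duplicated(subset=CELL_COLS)
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicate (participant, speed, trial, side, "
            "variable) keys in results"
        )
    grouped = (
        results.groupby(KEY_COLS, sort=True, dropna=False)[value_col]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": value_col, "count": "n_items"})
    )
    grouped["complete"] = grouped["n_items"] >= 4
    return grouped


@dataclass
class GroupComparison:
    name: str
    t: float
    df: float
    p: float
    effect_size: float  # Cohen's d
    p_adjusted: float | None = None
    flagged: bool = False


def one_sample_t(values: np.ndarray, mu0: float = 0.0, name: str = "") -> GroupComparison:
    """One-sample t-test against mu0; d = (mean - mu0) / SD."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2 for a one-sample t-test")
    sd = x.std(ddof=1)
    if sd <= 0:
        return GroupComparison(name, np.nan, x.size - 1, np.nan, np.nan, flagged=True)
    res = stats.ttest_1samp(x, mu0)
    d = float((x.mean() - mu0) / sd)
    return GroupComparison(name, float(res.statistic), float(x.size - 1),
                           float(res.pvalue), d)


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need n >= 2 in both groups")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        return np.nan
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def welch_t(group_a: np.ndarray, group_b: np.ndarray, name: str = "") -> GroupComparison:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 in both groups")
    if a.var(ddof=1) <= 0 and b.var(ddof=1) <= 0:
        return GroupComparison(name, np.nan, np.nan, np.nan, np.nan, flagged=True)
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(name, float(res.statistic), float(res.df),
                           float(res.pvalue), cohens_d(a, b))


def holm(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down correction: (adjusted p-values, rejection flags).

    Step-down rule: sort p ascending and compare p(i) <= alpha / (m - i + 1),
    stopping at the first failure; adjusted p-values are the monotone
    cumulative maxima of (m - i + 1) * p(i).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject
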