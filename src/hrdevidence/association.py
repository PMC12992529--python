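"""Association between HR status and histopathology markers.

Chi-square independence tests (Pearson, no continuity correction by
default), Cramér's V effect sizes, and two-sided Wilcoxon rank-sum
comparisons of probability scores.  Rows with a missing marker value are
excluded per variable before any table is built; nothing is imputed.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

MARKERS = ("grade", "ER", "PR", "HER2", "TNBC")
MISSING_VALUES = {"missing", "", "NA", "nan", None}


class AssociationError(ValueError):
    pass


def _clean(table: np.ndarray) -> np.ndarray:
    """Drop zero-marginal rows/columns (they carry no information)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise AssociationError("contingency table must be two-dimensional")
    if (t < 0).any():
        raise AssociationError("contingency table has negative counts")
    keep_rows = t.sum(axis=1) > 0
    keep_cols = t.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        log.warning("dropping zero-marginal rows/columns before testing")
    t = t[keep_rows][:, keep_cols]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise AssociationError("need at least a 2x2 table with positive marginals")
    return t


def chi_square_independence(table, correction: bool = False):
    """Pearson chi-square test of independence.

    Returns (statistic, dof, p).  Yates continuity correction is off by
    default and only applies to 2x2 tables when requested.
    """
    t = _clean(np.asarray(table))
    stat, p, dof, _ = stats.chi2_contingency(t, correction=correction)
    return float(stat), int(dof), float(p)


def cramers_v(table, correction: bool = False) -> float:
    """Cramér's V = sqrt(chi2 / (n * (min(r, c) - 1))), in [0, 1]."""
    t = _clean(np.asarray(table))
    stat, _, _ = chi_square_independence(t, correction=correction)
    n = t.sum()
    k = min(t.shape) - 1
    return float(np.sqrt(stat / (n * k)))


def wilcoxon_rank_sum(values_a, values_b, exact_max_n: int = 8):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    Exact enumeration when both samples have at most exact_max_n
    observations and no ties; otherwise the normal approximation with tie
    and continuity corrections.  Returns the Mann-Whitney U statistic of
    the first sample and the p-value.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise AssociationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both samples; p = 1", stacklevel=2)
        return float(a.size * b.size / 2), 1.0
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size <= exact_max_n and b.size <= exact_max_n and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def marker_table(
    samples: pd.DataFrame, calls: pd.DataFrame, marker: str, tool: str
) -> pd.DataFrame:
    """HR status x marker contingency table for one tool, missing excluded."""
    if marker not in MARKERS:
        raise AssociationError(f"unknown marker {marker!r}; expected one of {MARKERS}")
    tool_calls = calls[calls["tool"] == tool][["patient_id", "status"]]
    merged = samples.merge(tool_calls, on="patient_id", how="inner")
    if marker == "TNBC":
        ok = ~merged[["ER", "PR", "HER2"]].isin(MISSING_VALUES).any(axis=1)
        ok &= merged[["ER", "PR", "HER2"]].notna().all(axis=1)
        merged = merged[ok]
        values = np.where(
            (merged["ER"] == "neg") & (merged["PR"] == "neg") & (merged["HER2"] == "neg"),
            "TNBC",
            "non-TNBC",
        )
    else:
        col = merged[marker]
        keep = col.notna() & ~col.astype(str).isin({str(m) for m in MISSING_VALUES if m is not None})
        merged = merged[keep]
        values = merged[marker].astype(str)
    return pd.crosstab(merged["status"], pd.Series(values, index=merged.index, name=marker))


def associate(
    samples: pd.DataFrame, calls: pd.DataFrame, marker: str, tool: str
) -> dict[str, float]:
    """One-stop association summary for a marker: chi2, dof, p, Cramér's V."""
    table = marker_table(samples, calls, marker, tool)
    stat, dof, p = chi_square_independence(table.values)
    v = cramers_v(table.values)
    return {
        "marker": marker,
        "tool": tool,
        "n": int(table.values.sum()),
        "chi2": stat,
        "dof": dof,
        "p": p,
        "cramers_v": v,
    }
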