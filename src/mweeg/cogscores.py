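"""Cognitive test scoring and group comparisons.

Covers the D2 attention test's derived scores — total effectiveness
TOT = TR - (O + C), concentration CON = TH - C, variation V = TR+ - TR- —
and the SCIP screening subtests. Group comparisons are two-sample t tests
for variables that pass a per-group Shapiro-Wilk normality screen and
Mood's median test (2x2 Pearson chi-squared on the pooled-median split)
for those that do not; p-values are Benjamini-Hochberg corrected within
the variable family being compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .stats import bh_adjust

__all__ = [
    "D2Raw", "D2Derived", "derive_d2", "normality_flags", "compare_groups",
    "SCIP_VARS", "D2_VARS",
]

SCIP_VARS = ("SCIP_VLi", "SCIP_VLd", "SCIP_VF", "SCIP_WM", "SCIP_PV")
D2_VARS = ("D2_TR", "D2_TH", "D2_O", "D2_C", "D2_TOT", "D2_CON", "D2_V")


@dataclass(frozen=True)
class D2Raw:
    """Raw D2 counts: responses, hits, omissions, commissions, line extremes."""

    TR: int
    TH: int
    O: int
    C: int
    TRplus: int
    TRminus: int

    def __post_init__(self) -> None:
        if min(self.TR, self.TH, self.O, self.C, self.TRplus, self.TRminus) < 0:
            raise ValueError("D2 counts must be non-negative")
        if self.TH > self.TR:
            raise ValueError("hits cannot exceed total responses (TH <= TR)")
        if self.TRminus > self.TRplus:
            raise ValueError("TR- cannot exceed TR+")


@dataclass(frozen=True)
class D2Derived:
    TOT: int
    CON: int
    V: int


def derive_d2(raw: D2Raw) -> D2Derived:
    """Exact integer arithmetic: TOT = TR - (O + C); CON = TH - C; V = TR+ - TR-."""
    return D2Derived(TOT=raw.TR - (raw.O + raw.C), CON=raw.TH - raw.C,
                     V=raw.TRplus - raw.TRminus)


def add_derived_d2(scores: pd.DataFrame) -> pd.DataFrame:
    """Append D2_TOT / D2_CON / D2_V columns computed from the raw counts."""
    out = scores.copy()
    out["D2_TOT"] = out["D2_TR"] - (out["D2_O"] + out["D2_C"])
    out["D2_CON"] = out["D2_TH"] - out["D2_C"]
    out["D2_V"] = out["D2_TRplus"] - out["D2_TRminus"]
    return out


def normality_flags(
    scores: pd.DataFrame, variables: list[str], alpha: float = 0.05
) -> dict[str, bool]:
    """True = non-normal: Shapiro-Wilk rejects at alpha in either group."""
    flags: dict[str, bool] = {}
    for var in variables:
        reject = False
        for _, g in scores.groupby("group"):
            x = g[var].dropna().to_numpy(dtype=float)
            if len(x) < 3:
                raise ValueError(f"need n >= 3 per group for {var}")
            if np.ptp(x) == 0:
                continue
            reject |= scipy.stats.shapiro(x).pvalue < alpha
        flags[var] = reject
    return flags


def mood_median_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mood's median test: Pearson chi-squared (1 df) on the pooled-median split."""
    stat, p, _, _ = scipy.stats.median_test(x, y, ties="ignore", correction=False)
    return float(stat), float(p)


def compare_groups(
    scores: pd.DataFrame,
    variables: list[str],
    equal_var: bool = True,
    flags: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Per-variable CTRL vs SZQ comparisons with BH correction.

    Normal variables get a two-sample t (Student pooled-variance by default);
    flagged non-normal variables get Mood's median test. Constant variables
    are skipped and flagged. The BH family is the supplied variable list.
    """
    groups = scores.groupby("group")
    if scores["group"].nunique() < 2:
        raise ValueError("both groups must be present")
    if flags is None:
        flags = normality_flags(scores, variables)
    rows = []
    for var in variables:
        a = scores.loc[scores["group"] == "CTRL", var].dropna().to_numpy(dtype=float)
        b = scores.loc[scores["group"] == "SZQ", var].dropna().to_numpy(dtype=float)
        row = {"variable": var, "mean_ctrl": a.mean(), "mean_szq": b.mean(),
               "test": "median" if flags[var] else "t", "skipped": False}
        if np.ptp(np.concatenate([a, b])) == 0:
            row.update(statistic=np.nan, p=np.nan, skipped=True)
        elif flags[var]:
            stat, p = mood_median_test(a, b)
            row.update(statistic=stat, p=p)
        else:
            t, p = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
            row.update(statistic=float(t), p=float(p))
        rows.append(row)
    out = pd.DataFrame(rows)
    ok = (~out["skipped"] & out["p"].notna()).to_numpy()
    adj = np.full(len(out), np.nan)
    adj[ok] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["p_adj"] = adj
    return out
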