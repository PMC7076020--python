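"""Cognitive-state frequency analysis.

Probe answers are tabulated per participant and synchrony condition into a
complete 4-way frequency table. The omnibus analysis is a generalized
linear model of the counts (Poisson, log link, log-exposure offset for the
varying number of probes) with Group x Cognitive State x Synchrony fixed
effects tested by type-III Wald chi-squared statistics — seven effects with
degrees of freedom (1, 3, 1, 3, 1, 3, 3). Post-hoc group contrasts on
relative frequencies (one two-sample t per synchrony x answer cell, 8 in
all) are corrected with the Benjamini-Hochberg false-discovery-rate
step-up procedure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import patsy
import scipy.stats
import statsmodels.api as sm

from .preprocess import ANSWERS
from .stats import bh_adjust

__all__ = ["tabulate", "omnibus_glm", "posthoc_contrasts", "SingularDesignError"]

SYNCS = ("Sync", "NoSync")


class SingularDesignError(ValueError):
    """Raised when empty design cells make the omnibus model inestimable."""


def tabulate(responses: pd.DataFrame) -> pd.DataFrame:
    """Complete per-participant frequency table with explicit zero cells.

    Input: one row per probe (participant_id, group, synchrony, answer).
    Output rows: (participant_id, group, synchrony, answer, count, n_probes,
    rel_freq), covering all 4 answers for every (participant, synchrony)
    present in the input.
    """
    cols = ["participant_id", "group", "synchrony", "answer", "count",
            "n_probes", "rel_freq"]
    if len(responses) == 0:
        return pd.DataFrame(columns=cols)
    bad = set(responses["answer"]) - set(ANSWERS)
    if bad:
        raise ValueError(f"unknown answers: {sorted(bad)}")
    counts = (responses.groupby(["participant_id", "group", "synchrony", "answer"])
              .size().rename("count"))
    # complete grid over observed (participant, group, synchrony) x all answers
    base = responses[["participant_id", "group", "synchrony"]].drop_duplicates()
    grid = base.merge(pd.DataFrame({"answer": ANSWERS}), how="cross")
    table = grid.merge(counts.reset_index(), how="left",
                       on=["participant_id", "group", "synchrony", "answer"])
    table["count"] = table["count"].fillna(0).astype(int)
    totals = (table.groupby(["participant_id", "synchrony"])["count"]
              .transform("sum"))
    table["n_probes"] = totals
    table["rel_freq"] = table["count"] / table["n_probes"]
    return table[cols].sort_values(["participant_id", "synchrony", "answer"],
                                   ignore_index=True)


def omnibus_glm(table: pd.DataFrame, family: str = "poisson") -> pd.DataFrame:
    """Type-III Wald chi-squared tests of the Group x State x Synchrony GLM.

    Counts are modeled with a log link and a log(n_probes) offset so the
    effects act on relative response rates. Returns one row per fixed effect
    — Group, Cognitive State, Synchrony and their interactions — with Wald
    chi2, df and p, in the conventional listing order.
    """
    if table.groupby("group")["participant_id"].nunique().min() < 2:
        raise ValueError("need at least 2 participants per group")
    zero_cells = (table.groupby(["group", "synchrony", "answer"])["count"].sum())
    if (zero_cells == 0).any():
        empty = zero_cells[zero_cells == 0].index.tolist()
        raise SingularDesignError(f"empty design cells: {empty}")

    fam = {"poisson": sm.families.Poisson()}.get(family)
    if fam is None:
        raise ValueError(f"unsupported family {family!r}")

    formula = ("count ~ C(group, Sum) * C(answer, Sum) * C(synchrony, Sum)")
    y, X = patsy.dmatrices(formula, table, return_type="dataframe")
    offset = np.log(table["n_probes"].to_numpy(dtype=float))
    res = sm.GLM(y, X, family=fam, offset=offset).fit()

    labels = {
        "C(group, Sum)": "Group",
        "C(answer, Sum)": "Cognitive State",
        "C(synchrony, Sum)": "Synchrony",
        "C(group, Sum):C(answer, Sum)": "Group x Cognitive State",
        "C(group, Sum):C(synchrony, Sum)": "Group x Synchrony",
        "C(answer, Sum):C(synchrony, Sum)": "Synchrony x Cognitive State",
        "C(group, Sum):C(answer, Sum):C(synchrony, Sum)":
            "Group x Synchrony x Cognitive State",
    }
    info = X.design_info
    rows = []
    for term, label in labels.items():
        sl = info.term_name_slices[term]
        L = np.zeros((sl.stop - sl.start, X.shape[1]))
        L[np.arange(L.shape[0]), np.arange(sl.start, sl.stop)] = 1.0
        wt = res.wald_test(L, scalar=True)
        rows.append({"effect": label, "wald_chi2": float(wt.statistic),
                     "df": L.shape[0], "p": float(wt.pvalue)})
    return pd.DataFrame(rows)


def posthoc_contrasts(table: pd.DataFrame, equal_var: bool = True) -> pd.DataFrame:
    """Group contrasts on relative frequencies per (synchrony, answer) cell.

    One two-sample t (Student by default, Welch with equal_var=False) per
    cell, 8 contrasts in all, BH-adjusted jointly. Zero-variance cells are
    skipped and flagged rather than tested.
    """
    rows = []
    for sync in SYNCS:
        for answer in ANSWERS:
            cell = table[(table["synchrony"] == sync) & (table["answer"] == answer)]
            a = cell.loc[cell["group"] == "CTRL", "rel_freq"].to_numpy()
            b = cell.loc[cell["group"] == "SZQ", "rel_freq"].to_numpy()
            if len(a) == 0 or len(b) == 0:
                raise ValueError("both groups must be present")
            row = {"synchrony": sync, "answer": answer,
                   "mean_ctrl": a.mean(), "mean_szq": b.mean()}
            if a.std() == 0 and b.std() == 0:
                row.update(t=np.nan, p=np.nan, skipped=True)
            else:
                t, p = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
                row.update(t=float(t), p=float(p), skipped=False)
            rows.append(row)
    out = pd.DataFrame(rows)
    mask = ~out["skipped"]
    adj = np.full(len(out), np.nan)
    adj[mask.to_numpy()] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out["p_adj"] = adj
    return out
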