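"""Cross-domain associations and medication subgroup tests.

Per group, Spearman rank correlations are computed pairwise-complete among
cognitive-state frequencies (MW / Full by synchrony), mean EEG complexity
(HFD averaged across all 10 areas), SCIP / D2 scores, and — within the
patient group — PANSS subscales, age and illness duration. Medication
effects in the patient group are screened with Mann-Whitney U tests per
outcome for antidepressant use, mood-stabilizer use, and antipsychotic dose
dichotomized at the median chlorpromazine equivalent, BH-corrected within
each factor's outcome family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
import scipy.stats

from .stats import bh_adjust

__all__ = ["CorrMatrix", "spearman", "correlation_matrix", "medication_tests",
           "participant_summary"]

MIN_PAIRS = 4


@dataclass
class CorrMatrix:
    """Symmetric Spearman correlation matrix with p-values and pair counts."""

    variables: list[str]
    rho: np.ndarray
    p: np.ndarray
    n: np.ndarray
    group: str

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.variables):
            for j, b in enumerate(self.variables):
                if j <= i:
                    continue
                rows.append({"group": self.group, "var_a": a, "var_b": b,
                             "rho": self.rho[i, j], "p": self.p[i, j],
                             "n": int(self.n[i, j])})
        return pd.DataFrame(rows)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.linalg.norm(rx_c) * np.linalg.norm(ry_c)
    obs = abs(rho)
    count = 0
    total = 0
    chunk: list = []
    for perm in permutations(ry_c):
        chunk.append(perm)
        if len(chunk) == 20000:
            r = np.asarray(chunk) @ rx_c / denom
            count += int((np.abs(r) >= obs - 1e-12).sum())
            total += len(chunk)
            chunk = []
    if chunk:
        r = np.asarray(chunk) @ rx_c / denom
        count += int((np.abs(r) >= obs - 1e-12).sum())
        total += len(chunk)
    return count / total


def spearman(x: np.ndarray, y: np.ndarray, exact_below: int = 10) -> tuple[float, float]:
    """Spearman rho with a t-approximation p (exact permutation for n < 10)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho, p = scipy.stats.spearmanr(x, y)
    if len(x) < exact_below:
        p = _spearman_exact_p(x, y, rho)
    return float(rho), float(p)


def correlation_matrix(
    data: pd.DataFrame, variables: list[str], group: str
) -> CorrMatrix:
    """Pairwise-complete Spearman matrix for one group's participant table.

    Cells with fewer than 4 complete pairs are set NA with the count
    recorded.
    """
    sub = data[data["group"] == group]
    k = len(variables)
    rho = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        n[i, i] = sub[variables[i]].notna().sum()
        for j in range(i + 1, k):
            pair = sub[[variables[i], variables[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < MIN_PAIRS:
                rho[i, j] = rho[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            r, pv = spearman(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy())
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    return CorrMatrix(variables=list(variables), rho=rho, p=p, n=n, group=group)


def medication_tests(
    data: pd.DataFrame,
    outcomes: list[str],
    factors: tuple[str, ...] = ("antidepressant", "mood_stabilizer", "cpz_dose_split"),
    min_subgroup: int = 3,
) -> pd.DataFrame:
    """Mann-Whitney U tests of medication factors on outcomes (SZQ only).

    ``cpz_dose_split`` dichotomizes at the median chlorpromazine equivalent.
    Subgroups smaller than ``min_subgroup`` are skipped with a flag; BH
    correction is applied within each factor's outcome family.
    """
    szq = data[data["group"] == "SZQ"].copy()
    if "cpz_dose_split" in factors:
        med = szq["chlorpromazine_equiv"].median()
        szq["cpz_dose_split"] = szq["chlorpromazine_equiv"] > med
    rows = []
    for factor in factors:
        lab = szq[factor].astype(bool)
        for outcome in outcomes:
            a = szq.loc[lab, outcome].dropna().to_numpy(dtype=float)
            b = szq.loc[~lab, outcome].dropna().to_numpy(dtype=float)
            row = {"factor": factor, "outcome": outcome,
                   "n_yes": len(a), "n_no": len(b)}
            if min(len(a), len(b)) < min_subgroup:
                row.update(U=np.nan, p=np.nan, skipped=True)
            else:
                u, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
                row.update(U=float(u), p=float(p), skipped=False)
            rows.append(row)
    out = pd.DataFrame(rows)
    adj = np.full(len(out), np.nan)
    for factor in factors:
        mask = ((out["factor"] == factor) & ~out["skipped"]).to_numpy()
        if mask.any():
            adj[mask] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out["p_adj"] = adj
    return out


def participant_summary(
    freq_table: pd.DataFrame,
    hfd_records: pd.DataFrame,
    profiles: pd.DataFrame,
) -> pd.DataFrame:
    """One row per participant: state frequencies, mean HFD, scores.

    Frequencies enter as Freq_<answer>_<synchrony>; HFD is averaged across
    all areas and conditions into a single HFD column, mirroring the
    correlation analysis.
    """
    freq = freq_table.pivot_table(index=["participant_id", "group"],
                                  columns=["answer", "synchrony"],
                                  values="rel_freq")
    freq.columns = [f"Freq_{a}_{s}" for a, s in freq.columns]
    freq = freq.reset_index()
    hfd = (hfd_records.groupby("participant_id")["hfd"].mean()
           .rename("HFD").reset_index())
    out = freq.merge(hfd, on="participant_id", how="left")
    return out.merge(profiles.drop(columns=["group"], errors="ignore"),
                     on="participant_id", how="left")
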