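"""Cross-domain associations and medication subgroup screens.

Builds the per-participant summary (MW/Full frequencies by synchrony, mean
HFD across areas, SCIP and D2 scores), computes per-group Spearman
correlation matrices, and — within the patient group — Mann-Whitney screens
of antidepressant use, mood stabilizers and median-split antipsychotic dose
on state frequencies and complexity.
"""

import pandas as pd

from common import outdir
from mweeg.assoc import correlation_matrix, medication_tests, participant_summary
from mweeg.cogscores import add_derived_d2


def main() -> None:
    out = outdir()
    table = pd.read_csv(out / "state_frequencies.csv")
    records = pd.read_csv(out / "hfd.csv")
    profiles = add_derived_d2(pd.read_csv(out / "profiles.csv"))
    summary = participant_summary(table, records, profiles)
    summary.to_csv(out / "participant_summary.csv", index=False)

    variables = ([c for c in summary.columns if c.startswith(("Freq_MW", "Freq_Full"))]
                 + ["HFD"]
                 + [c for c in summary.columns if c.startswith(("SCIP_", "D2_"))])
    mats = []
    for group in ("CTRL", "SZQ"):
        cm = correlation_matrix(summary, variables, group)
        long = cm.to_long()
        mats.append(long)
        strong = long[(long["p"] < 0.05) & (long["rho"].abs() > 0.5)]
        print(f"{group}: {len(strong)} correlations with p < .05 and |rho| > 0.5")
    pd.concat(mats, ignore_index=True).to_csv(out / "correlations.csv", index=False)

    outcomes = [c for c in variables if c.startswith("Freq_")] + ["HFD"]
    med = medication_tests(summary, outcomes)
    med.to_csv(out / "medication_tests.csv", index=False)
    print("\nmedication screens (SZQ, Mann-Whitney, BH within factor):")
    print(med.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
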