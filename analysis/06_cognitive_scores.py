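"""Group comparisons of SCIP subtests and D2 attention scores.

Derives the D2 composite scores (TOT, CON, V), screens every variable for
normality per group (Shapiro-Wilk), and compares CTRL vs SZQ with t tests
or Mood's median test accordingly, BH-corrected within the SCIP and D2
families.
"""

import pandas as pd

from common import outdir
from mweeg.cogscores import D2_VARS, SCIP_VARS, add_derived_d2, compare_groups, normality_flags


def main() -> None:
    out = outdir()
    profiles = add_derived_d2(pd.read_csv(out / "profiles.csv"))
    variables = list(SCIP_VARS) + list(D2_VARS)
    flags = normality_flags(profiles, variables)
    non_normal = [v for v, f in flags.items() if f]
    print(f"non-normal variables (routed to the median test): {non_normal}")

    scip = compare_groups(profiles, list(SCIP_VARS), flags=flags)
    d2 = compare_groups(profiles, list(D2_VARS), flags=flags)
    result = pd.concat([scip, d2], ignore_index=True)
    result.to_csv(out / "cogscores_tests.csv", index=False)
    print("\ngroup comparisons (BH-corrected within family):")
    print(result.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
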