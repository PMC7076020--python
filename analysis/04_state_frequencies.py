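"""Analyse probe-reported cognitive states: omnibus GLM and group contrasts.

Tabulates per-participant state frequencies, fits the Poisson log-link GLM
of counts on Group x Cognitive State x Synchrony (log-exposure offset) with
type-III Wald chi-squared tests, and runs the eight BH-corrected group
contrasts on relative frequencies.
"""

import pandas as pd

from common import outdir
from mweeg.statefreq import omnibus_glm, posthoc_contrasts, tabulate


def main() -> None:
    out = outdir()
    responses = pd.read_csv(out / "responses.csv")
    table = tabulate(responses)
    table.to_csv(out / "state_frequencies.csv", index=False)

    omnibus = omnibus_glm(table)
    omnibus.to_csv(out / "statefreq_omnibus.csv", index=False)
    print("omnibus Wald chi-squared tests:")
    print(omnibus.round(4).to_string(index=False))

    posthoc = posthoc_contrasts(table)
    posthoc.to_csv(out / "statefreq_posthoc.csv", index=False)
    print("\ngroup contrasts on relative frequencies (BH-corrected):")
    print(posthoc.round(4).to_string(index=False))

    sig = posthoc[posthoc["p_adj"] < 0.05]
    print(f"\nsignificant contrasts after BH: "
          f"{[f'{r.answer}/{r.synchrony}' for r in sig.itertuples()]}")


if __name__ == "__main__":
    main()
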