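"""Synthesize EEG segment by segment and estimate its fractal complexity.

For every probe response, the participant's 50-s, 31-channel pre-probe
segment is generated (fBm with the cell's Hurst exponent plus observation
noise), screened by the amplitude rejector, scored with the sliding-window
Higuchi estimator (2000 ms windows, 90% overlap, k_max = 10), and averaged
into the 10 scalp areas. Segments are discarded after scoring, so the run
needs little memory; with the full 45-participant study this is the slow
step (several minutes on one CPU).

The synthetic segments are generated clean and band-unlimited, so the 1-30
Hz recording filter is not applied here; see docs/methods.md.
"""

import time

import pandas as pd

from common import HFD_PARAMS, STUDY, outdir
from mweeg.hfd import sliding_hfd
from mweeg.montage import default_region_map, aggregate_by_region
from mweeg.preprocess import amplitude_flags
from mweeg.synth import make_participants, simulate_participant_eeg, simulate_responses


def main() -> None:
    rmap = default_region_map()
    participants = make_participants(STUDY)
    rows = []
    n_flagged = 0
    t0 = time.time()
    for i, p in enumerate(participants, 1):
        responses = simulate_responses(p, STUDY)
        segments = simulate_participant_eeg(p, STUDY, responses)
        flags = amplitude_flags(segments)
        n_flagged += int(flags.sum())
        for seg, flagged in zip(segments, flags):
            if flagged:
                continue
            dims = sliding_hfd(seg.data, seg.sfreq, HFD_PARAMS)
            for area, val in aggregate_by_region(
                    dict(zip(seg.channels, dims)), rmap).items():
                rows.append({"participant_id": p.id, "group": p.group,
                             "synchrony": seg.synchrony, "answer": seg.answer,
                             "area": area, "hfd": val})
        print(f"[{i:2d}/{len(participants)}] {p.id} ({p.group}): "
              f"{len(segments)} segments, {time.time() - t0:.0f}s elapsed")
    records = pd.DataFrame(rows)
    out = outdir() / "hfd.csv"
    records.to_csv(out, index=False)
    print(f"{len(records)} area-level HFD records "
          f"({n_flagged} segments rejected by the amplitude screen)")
    print("mean HFD by answer (MW vs Full), CTRL in the Sync condition:")
    ctrl = records[(records.group == "CTRL") & (records.synchrony == "Sync")
                   & records.answer.isin(["MW", "Full"])]
    print(ctrl.groupby("answer")["hfd"].mean().round(4))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
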