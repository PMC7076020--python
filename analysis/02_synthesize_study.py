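"""Generate the synthetic study: participants, probe responses, score tables.

Emulates the design conditions — 23 controls and 22 patients, four 5-minute
videos each (2 synchronized, 2 not), probes every 60 +/- 10 s — and writes
the probe-response log and the cognitive/clinical score table. EEG segments
are regenerated on demand by later scripts (they are deterministic in the
seed), so no bulky signal files are stored; one example segment is exported
as EDF+ under scratch/ to demonstrate the recording format.
"""

from pathlib import Path

from common import STUDY, outdir
from mweeg.edfio_min import write_edf
from mweeg.montage import MONTAGE_31
from mweeg.synth import simulate_participant_eeg, simulate_study


def main() -> None:
    participants, responses, profiles, _ = simulate_study(STUDY, with_eeg=False)
    out = outdir()
    responses.to_csv(out / "responses.csv", index=False)
    profiles.to_csv(out / "profiles.csv", index=False)
    n_per = responses.groupby("participant_id").size()
    print(f"{len(participants)} participants "
          f"({sum(p.group == 'CTRL' for p in participants)} CTRL / "
          f"{sum(p.group == 'SZQ' for p in participants)} SZQ)")
    print(f"{len(responses)} probe responses "
          f"({n_per.min()}-{n_per.max()} per participant)")
    print("answer frequencies by group and synchrony:")
    freq = (responses.groupby(["group", "synchrony", "answer"]).size()
            .unstack("answer").fillna(0).astype(int))
    print(freq)
    print(f"wrote {out / 'responses.csv'} and {out / 'profiles.csv'}")

    # one example 50-s segment as EDF+ (scratch: demonstration only)
    scratch = Path(__file__).resolve().parent.parent / "scratch"
    scratch.mkdir(exist_ok=True)
    p = participants[0]
    resp = [r for r in _responses_of(p)][:1]
    seg = simulate_participant_eeg(p, STUDY, resp)[0]
    edf = scratch / f"{p.id}_example.edf"
    write_edf(edf, seg.data, STUDY.sfreq, list(MONTAGE_31),
              annotations=[(0.0, STUDY.segment_length,
                            f"answer={seg.answer};synchrony={seg.synchrony}")])
    print(f"wrote example EDF {edf}")


def _responses_of(p):
    from mweeg.synth import simulate_responses
    return simulate_responses(p, STUDY)


if __name__ == "__main__":
    main()
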