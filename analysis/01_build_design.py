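"""Construct the factorial clip set and counterbalanced presentation versions.

Six source films are split into audio and image tracks and factorially
recombined into 36 clips (6 synchronized, 30 non-synchronized); a
backtracking search assigns them to 6 versions of 2+2 experimental clips
under the counterbalancing constraints, and an independent validator
re-checks every constraint before the design is written out.
"""

import json

from common import STUDY_SEED, outdir
from mweeg.design import build_clip_set, build_versions, validate_versions


def main() -> None:
    clips = build_clip_set(6)
    n_sync = sum(c.synchrony == "Sync" for c in clips)
    print(f"clip set: {len(clips)} clips ({n_sync} Sync, {len(clips) - n_sync} NoSync)")

    versions = build_versions(clips, 6, seed=STUDY_SEED)
    problems = validate_versions(versions, 6)
    print(f"versions: {len(versions)}; validator violations: {problems or 'none'}")

    doc = {
        "films": list(range(6)),
        "clips": [{"image": c.image_film, "audio": c.audio_film,
                   "synchrony": c.synchrony} for c in clips],
        "versions": [{"id": v.id,
                      "clips": [{"image": c.image_film, "audio": c.audio_film,
                                 "synchrony": c.synchrony} for c in v.clips]}
                     for v in versions],
        "valid": not problems,
    }
    path = outdir() / "design.json"
    path.write_text(json.dumps(doc, indent=2))
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
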