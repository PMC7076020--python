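"""Shared settings for the numbered analysis scripts.

One root seed drives the whole synthetic study; every script regenerates
what it needs deterministically from this configuration, so the scripts can
be run independently (in order) and always agree with each other.
"""

from pathlib import Path

from mweeg.hfd import HFDParams
from mweeg.synth import SynthConfig

STUDY_SEED = 42
RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"

STUDY = SynthConfig(seed=STUDY_SEED)
HFD_PARAMS = HFDParams()  # 2000 ms windows, 90% overlap, k_max 10


def outdir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
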