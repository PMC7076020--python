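"""10-20 electrode montage and scalp regions of interest.

The recording montage is the study's 31-electrode 10-20 cap. For analysis,
electrodes are grouped into 10 scalp areas — frontal midline (F), frontal
left/right (FL/FR), central left/right (CL/CR), temporal left/right (TL/TR),
occipito-parietal midline/left/right (OP/OPL/OPR) — and channel-level HFD is
averaged within each area. The default electrode-to-area assignment is an
anatomically conventional left/midline/right split and can be overridden
from a two-column CSV (electrode, region).
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "MONTAGE_31",
    "REGIONS",
    "RegionMap",
    "default_region_map",
    "aggregate_by_region",
]

#: The 31 active electrodes of the recording cap, in recorded order.
MONTAGE_31: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8", "FT9", "FC5", "FC1",
    "FC2", "FC6", "FT10", "T7", "C3", "C4", "T8", "TP9", "CP5", "CP1",
    "CP2", "CP6", "TP10", "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
)

#: The 10 scalp areas of interest.
REGIONS: tuple[str, ...] = ("CL", "CR", "F", "FL", "FR", "OP", "OPL", "OPR", "TL", "TR")


class MontageError(ValueError):
    """Raised for unknown channels or malformed region maps."""


class RegionMap:
    """Mapping electrode name -> region code, validated against the montage.

    Every montage electrode must map to exactly one of the 10 regions and
    every region must be non-empty.
    """

    def __init__(self, mapping: Mapping[str, str], montage: Iterable[str] = MONTAGE_31):
        montage = tuple(montage)
        unknown = sorted(set(mapping) - set(montage))
        if unknown:
            raise MontageError(f"electrodes not in montage: {unknown}")
        missing = sorted(set(montage) - set(mapping))
        if missing:
            raise MontageError(f"montage electrodes without a region: {missing}")
        bad = sorted({r for r in mapping.values() if r not in REGIONS})
        if bad:
            raise MontageError(f"unknown region codes: {bad}")
        empty = sorted(set(REGIONS) - set(mapping.values()))
        if empty:
            raise MontageError(f"regions with no electrodes: {empty}")
        self.mapping = dict(mapping)
        self.montage = montage

    def electrodes(self, region: str) -> list[str]:
        return [ch for ch, r in self.mapping.items() if r == region]

    @classmethod
    def from_csv(cls, path) -> "RegionMap":
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["electrode", "region"]:
            raise MontageError("region map CSV must have columns (electrode, region)")
        return cls(dict(zip(df["electrode"], df["region"])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"electrode": list(self.mapping), "region": list(self.mapping.values())}
        )


def default_region_map() -> RegionMap:
    """The packaged default electrode-to-region assignment."""
    with resources.files("mweeg.data").joinpath("region_map.csv").open() as fh:
        df = pd.read_csv(fh)
    return RegionMap(dict(zip(df["electrode"], df["region"])))


def aggregate_by_region(
    per_channel: Mapping[str, float], region_map: RegionMap | None = None
) -> dict[str, float]:
    """Arithmetic mean of channel-level values within each region.

    per_channel must cover every mapped electrode; unmapped channels present
    in the input raise a MontageError naming the offenders.
    """
    rmap = region_map if region_map is not None else default_region_map()
    offenders = sorted(set(per_channel) - set(rmap.mapping))
    if offenders:
        raise MontageError(f"channels without a region assignment: {offenders}")
    missing = sorted(set(rmap.mapping) - set(per_channel))
    if missing:
        raise MontageError(f"mapped electrodes missing from input: {missing}")
    out: dict[str, float] = {}
    for region in REGIONS:
        members = rmap.electrodes(region)
        out[region] = float(sum(per_channel[ch] for ch in members) / len(members))
    return out
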