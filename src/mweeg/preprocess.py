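"""EEG preprocessing: band-pass filtering, probe-locked segmentation, QC.

The analysis operates on labeled 50-s windows: continuous EEG is band-pass
filtered at 1-30 Hz (zero-phase Butterworth), and for every experience-
sampling probe the 50 s immediately preceding probe onset are cut out and
labeled with the reported cognitive state and the clip's synchrony
condition. Probes arriving earlier than 50 s into a video are skipped with a
warning. Artifact handling on synthetic data reduces to an optional
amplitude-threshold rejector (|z| > 6 on any channel flags the segment);
component-based cleaning of real recordings is out of scope.

Time convention: seconds, 0-based sample indexing, half-open intervals
[t0, t0 + length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .montage import MONTAGE_31, MontageError

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "EEGSegment",
    "ProbeResponse",
    "bandpass",
    "extract_segments",
    "amplitude_flags",
    "read_raw",
]

ANSWERS = ("Audio", "Image", "Full", "MW")


@dataclass(frozen=True)
class ProbeResponse:
    """One introspective report at a probe."""

    participant_id: str
    video_idx: int
    probe_time_s: float
    synchrony: str  # Sync | NoSync
    answer: str  # Audio | Image | Full | MW

    def __post_init__(self) -> None:
        if self.answer not in ANSWERS:
            raise ValueError(f"unknown answer {self.answer!r}")
        if self.synchrony not in ("Sync", "NoSync"):
            raise ValueError(f"unknown synchrony {self.synchrony!r}")


@dataclass
class Recording:
    """Continuous multichannel EEG for one video presentation."""

    participant_id: str
    channels: tuple[str, ...]
    sfreq: float
    data: np.ndarray  # (n_channels, n_samples)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.channels):
            raise ValueError("data rows must match channel count")
        unknown = sorted(set(self.channels) - set(MONTAGE_31))
        if unknown:
            raise MontageError(f"channels not in the 31-electrode montage: {unknown}")


@dataclass
class EEGSegment:
    """One labeled 50-s analysis window."""

    participant_id: str
    channels: tuple[str, ...]
    sfreq: float
    data: np.ndarray  # (n_channels, round(length*sfreq))
    answer: str
    synchrony: str
    t0: float  # seconds within video
    clean: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.isfinite(self.data).all():
            raise ValueError("segment contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def bandpass(
    data: np.ndarray, sfreq: float, lo: float = 1.0, hi: float = 30.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass; removes DC, preserves in-band amplitude.

    Applied forward-backward (sosfiltfilt) so filtering introduces no phase
    lag relative to the probe-locked labels.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    nyq = sfreq / 2.0
    if not 0 < lo < hi:
        raise ValueError("require 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"high cutoff {hi} Hz must be below Nyquist {nyq} Hz")
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=sfreq, output="sos")
    return scipy.signal.sosfiltfilt(sos, data, axis=-1)


def extract_segments(
    recording: Recording,
    responses: list[ProbeResponse],
    length_s: float = 50.0,
) -> list[EEGSegment]:
    """Cut the ``length_s`` window preceding each probe; label from the probe.

    A probe earlier than ``length_s`` into the video is skipped with a logged
    warning (no error). Windows are [probe - length, probe), half-open, and
    never read outside the recording.
    """
    n_samples = recording.data.shape[1]
    need = int(round(length_s * recording.sfreq))
    out: list[EEGSegment] = []
    for resp in responses:
        stop = int(round(resp.probe_time_s * recording.sfreq))
        start = stop - need
        if start < 0:
            logger.warning(
                "probe at %.1f s in video %d of %s precedes %g s; segment skipped",
                resp.probe_time_s, resp.video_idx, resp.participant_id, length_s,
            )
            continue
        if stop > n_samples:
            logger.warning(
                "probe at %.1f s beyond recording end (%d samples); segment skipped",
                resp.probe_time_s, n_samples,
            )
            continue
        out.append(
            EEGSegment(
                participant_id=resp.participant_id,
                channels=recording.channels,
                sfreq=recording.sfreq,
                data=recording.data[:, start:stop].copy(),
                answer=resp.answer,
                synchrony=resp.synchrony,
                t0=resp.probe_time_s - length_s,
            )
        )
    return out


def amplitude_flags(segments: list[EEGSegment], z_thresh: float = 6.0) -> np.ndarray:
    """Flag segments whose any-channel amplitude exceeds z_thresh channel SDs.

    Returns a boolean array (True = flagged as artifactual). Channel mean/SD
    are computed within the segment.
    """
    flags = np.zeros(len(segments), dtype=bool)
    for i, seg in enumerate(segments):
        mu = seg.data.mean(axis=1, keepdims=True)
        sd = seg.data.std(axis=1, keepdims=True)
        sd[sd == 0] = np.inf
        z = np.abs(seg.data - mu) / sd
        flags[i] = bool((z > z_thresh).any())
    return flags


def read_raw(path, participant_id: str | None = None) -> Recording:
    """Load continuous EEG from EDF or BrainVision (.vhdr) via MNE."""
    import mne

    p = str(path)
    if p.lower().endswith(".edf"):
        raw = mne.io.read_raw_edf(p, preload=True, verbose="error")
    elif p.lower().endswith(".vhdr"):
        raw = mne.io.read_raw_brainvision(p, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG file type: {p}")
    chans = tuple(ch for ch in raw.ch_names if ch in MONTAGE_31)
    data = raw.get_data(picks=list(chans))
    return Recording(
        participant_id=participant_id or "unknown",
        channels=chans,
        sfreq=float(raw.info["sfreq"]),
        data=data,
    )
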