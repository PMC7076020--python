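"""Minimal EDF+ writer for continuous multichannel recordings.

Writes EDF+C files: 16-bit sample encoding, one-second data records, and an
'EDF Annotations' channel carrying time-stamped annotation lists (TALs) so
that segment labels survive a round trip through standard readers
(mne.io.read_raw_edf is the round-trip oracle in the test suite). Reading is
delegated to MNE; only writing is implemented here.
"""

from __future__ import annotations

import datetime as _dt
import math

import numpy as np

__all__ = ["write_edf"]


def _field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _num(x: float, width: int = 8) -> str:
    """Shortest %g rendering of x that fits the EDF field width."""
    for prec in range(7, 0, -1):
        s = f"{x:.{prec}g}"
        if len(s) <= width:
            return s
    raise ValueError(f"cannot render {x} in {width} chars")


def _tal(onset: float, duration: float | None, text: str) -> bytes:
    out = f"+{onset:g}".encode("ascii")
    if duration is not None:
        out += b"\x15" + f"{duration:g}".encode("ascii")
    out += b"\x14" + text.encode("utf-8") + b"\x14\x00"
    return out


def write_edf(
    path,
    data: np.ndarray,
    sfreq: float,
    ch_names: list[str],
    annotations: list[tuple[float, float, str]] | None = None,
    patient_id: str = "X",
    phys_dim: str = "uV",
) -> None:
    """Write an (n_channels, n_samples) array as an EDF+C file.

    sfreq must be a positive integer number of samples per one-second record;
    the last record is zero-padded. Annotations are (onset_s, duration_s,
    text) triples.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be (n_channels, n_samples)")
    if len(ch_names) != data.shape[0]:
        raise ValueError("ch_names length must match data rows")
    spr = int(round(sfreq))
    if spr <= 0 or abs(spr - sfreq) > 1e-9:
        raise ValueError("sfreq must be a positive integer for 1-s records")
    n_ch, n_samp = data.shape
    n_rec = math.ceil(n_samp / spr)
    annotations = list(annotations or [])

    # per-channel physical range (symmetric, non-degenerate); scale with the
    # value as rendered in the header so readers rescale consistently
    pmax = np.array([float(_num(p)) for p in
                     np.maximum(np.abs(data).max(axis=1) * 1.001, 1e-6)])
    dig_max, dig_min = 32767, -32768
    scaled = np.round(data / pmax[:, None] * dig_max).astype("<i2")

    # annotation channel: each record holds its timestamp TAL plus any TALs
    # whose onset falls in that record
    rec_tals: list[bytes] = []
    for r in range(n_rec):
        chunk = _tal(float(r), None, "")
        for onset, dur, text in annotations:
            if r <= onset < r + 1:
                chunk += _tal(onset, dur if dur > 0 else None, text)
        rec_tals.append(chunk)
    ann_bytes = max(len(c) for c in rec_tals)
    ann_spr = math.ceil(ann_bytes / 2)

    n_sig = n_ch + 1
    header_bytes = 256 * (1 + n_sig)
    now = _dt.datetime(2000, 1, 1)

    hdr = b""
    hdr += _field("0", 8)
    hdr += _field(patient_id, 80)
    hdr += _field("Startdate 01-JAN-2000 X X X", 80)
    hdr += _field(now.strftime("%d.%m.%y"), 8)
    hdr += _field(now.strftime("%H.%M.%S"), 8)
    hdr += _field(header_bytes, 8)
    hdr += _field("EDF+C", 44)
    hdr += _field(n_rec, 8)
    hdr += _field(1, 8)  # record duration, seconds
    hdr += _field(n_sig, 4)

    labels = [n[:16] for n in ch_names] + ["EDF Annotations"]
    hdr += b"".join(_field(l, 16) for l in labels)
    hdr += b"".join(_field("", 80) for _ in range(n_sig))  # transducer
    hdr += b"".join(_field(phys_dim, 8) for _ in range(n_ch)) + _field("", 8)
    hdr += b"".join(_field(_num(-p), 8) for p in pmax) + _field(-1, 8)
    hdr += b"".join(_field(_num(p), 8) for p in pmax) + _field(1, 8)
    hdr += b"".join(_field(dig_min, 8) for _ in range(n_sig))
    hdr += b"".join(_field(dig_max, 8) for _ in range(n_sig))
    hdr += b"".join(_field("", 80) for _ in range(n_sig))  # prefiltering
    hdr += b"".join(_field(spr, 8) for _ in range(n_ch)) + _field(ann_spr, 8)
    hdr += b"".join(_field("", 32) for _ in range(n_sig))  # reserved
    assert len(hdr) == header_bytes

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            sl = slice(r * spr, (r + 1) * spr)
            for ch in range(n_ch):
                chunk = scaled[ch, sl]
                if chunk.shape[0] < spr:
                    chunk = np.pad(chunk, (0, spr - chunk.shape[0]))
                fh.write(chunk.tobytes())
            tal = rec_tals[r].ljust(ann_spr * 2, b"\x00")
            fh.write(tal)
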