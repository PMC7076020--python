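"""Higuchi fractal dimension (HFD) of EEG time series.

HFD scores the irregularity of a signal directly in the time domain. For a
series x(1..N) and a lag k, curve lengths are formed from k decimated
subsequences (offsets m = 1..k):

    L_m(k) = [ sum_{i=1..n_k} |x(m + i k) - x(m + (i-1) k)| ] * (N - 1) / (n_k * k) / k

with n_k = floor((N - m) / k). The mean L(k) over offsets scales as
k^(-D); D, the negative slope of an OLS fit of ln L(k) on ln k for
k = 1..k_max, is the fractal dimension. D ranges from 1 for smooth periodic
signals (e.g. a sinusoid) to 2 for signals that nearly fill the plane
(e.g. white noise).

Segment-level estimates follow a sliding-window procedure: HFD is computed
in windows of 2000 ms with 90% overlap and averaged over windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HFDParams", "curve_length", "higuchi_fd", "higuchi_fd_batch", "sliding_hfd"]


@dataclass(frozen=True)
class HFDParams:
    """Parameters of the sliding-window HFD estimator.

    window_ms and overlap_frac follow the study protocol (2000 ms, 90%);
    k_max is the largest lag in the log-log regression. The window must be
    long enough that the smallest decimated subsequence still has at least
    two points (window samples > 2 * k_max).
    """

    window_ms: float = 2000.0
    overlap_frac: float = 0.9
    k_max: int = 10
    fit: str = "ols"

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError("overlap_frac must lie in [0, 1)")
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")
        if self.fit != "ols":
            raise ValueError(f"unknown fit method {self.fit!r}")

    def window_samples(self, sfreq: float) -> int:
        n = int(round(self.window_ms / 1000.0 * sfreq))
        if n <= 2 * self.k_max:
            raise ValueError(
                f"window of {n} samples too short for k_max={self.k_max}"
            )
        return n

    def step_samples(self, sfreq: float) -> int:
        # round-half-to-even via python round(), per the documented convention
        return max(1, round(self.window_samples(sfreq) * (1.0 - self.overlap_frac)))


def curve_length(x: np.ndarray, k: int, m: int) -> float:
    """Normalized Higuchi curve length L_m(k); offset m is 1-based (1 <= m <= k)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if not 1 <= m <= k:
        raise ValueError(f"offset m={m} must satisfy 1 <= m <= k={k}")
    n_k = (n - m) // k
    if n_k < 1:
        raise ValueError(f"series of length {n} too short for (k={k}, m={m})")
    sub = x[m - 1 :: k][: n_k + 1]
    total = np.abs(np.diff(sub)).sum()
    return float(total * (n - 1) / (n_k * k) / k)


def _curve_lengths_batch(x: np.ndarray, k_max: int) -> np.ndarray:
    """Mean curve length L(k) for k = 1..k_max over the last axis.

    x may be 1-D or 2-D (batch of series); returns shape (..., k_max).
    """
    n = x.shape[-1]
    out = np.empty(x.shape[:-1] + (k_max,))
    for k in range(1, k_max + 1):
        acc = 0.0
        for m in range(1, k + 1):
            n_k = (n - m) // k
            sub = x[..., m - 1 :: k][..., : n_k + 1]
            total = np.abs(np.diff(sub, axis=-1)).sum(axis=-1)
            acc = acc + total * ((n - 1) / (n_k * k) / k)
        out[..., k - 1] = acc / k
    return out


def higuchi_fd_batch(x: np.ndarray, k_max: int = 10) -> np.ndarray:
    """Vectorized HFD over the last axis of a (batch of) series."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n <= 2 * k_max:
        raise ValueError(f"need more than {2 * k_max} samples, got {n}")
    lengths = _curve_lengths_batch(x, k_max)
    if np.any(lengths <= 0.0):
        raise ValueError("zero curve length: input has (locally) zero variance")
    ln_k = np.log(np.arange(1, k_max + 1, dtype=float))
    ln_l = np.log(lengths)
    # OLS slope of ln L on ln k, all k weights equal
    ln_k_c = ln_k - ln_k.mean()
    slope = (ln_l * ln_k_c).sum(axis=-1) / (ln_k_c**2).sum()
    return -slope


def higuchi_fd(x: np.ndarray, k_max: int = 10) -> float:
    """HFD of a single 1-D series; see module docstring for the estimator."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("higuchi_fd expects a 1-D series")
    return float(higuchi_fd_batch(x, k_max))


def sliding_hfd(data: np.ndarray, sfreq: float, params: HFDParams = HFDParams()) -> np.ndarray:
    """Sliding-window HFD averaged over windows, per channel.

    data: (n_channels, n_samples) or 1-D. Windows of params.window_ms slide
    with step window*(1-overlap); a trailing partial window is discarded.
    Returns one dimension per channel.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    win = params.window_samples(sfreq)
    step = params.step_samples(sfreq)
    n = data.shape[-1]
    if win > n:
        raise ValueError(f"window of {win} samples exceeds segment of {n} samples")
    n_win = (n - win) // step + 1
    # (channels, windows, win) strided view — no copy
    windows = np.lib.stride_tricks.sliding_window_view(data, win, axis=-1)[:, ::step][:, :n_win]
    dims = higuchi_fd_batch(windows, params.k_max)
    return dims.mean(axis=-1)


def n_windows(n_samples: int, sfreq: float, params: HFDParams = HFDParams()) -> int:
    """Number of full sliding windows in a segment of n_samples."""
    win = params.window_samples(sfreq)
    step = params.step_samples(sfreq)
    if win > n_samples:
        return 0
    return (n_samples - win) // step + 1
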