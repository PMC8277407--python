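"""Spectrogram computation and per-frame spectral peak extraction.

Levels are expressed in dB relative to a full-scale sine (a unit-amplitude
sinusoid peaks at ~0 dB regardless of window), with a floor at -120 dB for
zero-power bins. Only level differences are meaningful; the adaptive
threshold makes the peak set invariant to overall gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.signal import get_window

from .config import StftParams, ThresholdPolicy

DB_FLOOR = -120.0


@dataclass(frozen=True)
class SpectralPeak:
    """One above-threshold local maximum in one STFT frame."""

    frame_index: int
    bin_index: int
    freq_hz: float
    level_db: float
    channel: str = "lung"


@dataclass
class Spectrogram:
    """Frame x frequency-bin grid of levels in dB for one channel.

    ``levels`` has shape (n_frames, n_bins); ``frame_times_s`` holds the
    start time of each analysis window.
    """

    levels: np.ndarray
    frame_times_s: np.ndarray
    bin_freqs_hz: np.ndarray
    params: StftParams

    @property
    def n_frames(self) -> int:
        return self.levels.shape[0]

    @property
    def n_bins(self) -> int:
        return self.levels.shape[1]


def compute_spectrogram(waveform: np.ndarray, params: StftParams = StftParams()) -> Spectrogram:
    """Windowed-periodogram spectrogram in dB.

    Frames start every ``hop`` samples; frame count is
    floor((n - window_len) / hop) + 1 (no padding). Levels are
    20*log10(2|X_k| / sum(w)), floored at -120 dB, so a full-scale
    bin-centered sine reads 0 dB at its peak bin.
    """
    x = np.asarray(waveform, dtype=np.float64)
    n = x.shape[0]
    win_len, hop = params.window_len, params.hop
    if n < win_len:
        raise ValueError(f"waveform ({n} samples) shorter than one window ({win_len})")
    n_frames = (n - win_len) // hop + 1
    window = get_window(params.window_kind, win_len, fftbins=True)
    idx = np.arange(win_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * window
    spectra = np.fft.rfft(frames, axis=1)
    amp = 2.0 * np.abs(spectra) / window.sum()
    with np.errstate(divide="ignore"):
        levels = 20.0 * np.log10(amp)
    levels = np.maximum(levels, DB_FLOOR)
    frame_times = hop * np.arange(n_frames) / params.fs
    bin_freqs = np.arange(win_len // 2 + 1) * params.fs / win_len
    return Spectrogram(levels=levels, frame_times_s=frame_times, bin_freqs_hz=bin_freqs, params=params)


def export_levels(spect: Spectrogram, path: str) -> None:
    """Write the level grid as tab-delimited text for external inspection.

    First row: bin centre frequencies (Hz); first column: frame start times
    (s); body: levels in dB."""
    header = "time_s\t" + "\t".join(f"{f:.4f}" for f in spect.bin_freqs_hz)
    body = np.column_stack([spect.frame_times_s, spect.levels])
    np.savetxt(path, body, fmt="%.3f", delimiter="\t", header=header, comments="")


def _band_mask(spect: Spectrogram, low_hz: float, high_hz: float) -> np.ndarray:
    return (spect.bin_freqs_hz >= low_hz) & (spect.bin_freqs_hz <= high_hz)


def all_thresholds(spect: Spectrogram, policy: ThresholdPolicy = ThresholdPolicy()) -> np.ndarray:
    """Per-frame adaptive threshold: power-mean band level + offset (dB)."""
    mask = _band_mask(spect, policy.band_low_hz, policy.band_high_hz)
    if not mask.any():
        raise ValueError("threshold band contains no FFT bins")
    band_power = np.power(10.0, spect.levels[:, mask] / 10.0)
    return 10.0 * np.log10(band_power.mean(axis=1)) + policy.offset_db


def frame_threshold(
    spect: Spectrogram, frame_index: int, policy: ThresholdPolicy = ThresholdPolicy()
) -> float:
    """Threshold (dB) for one frame; see :func:`all_thresholds`."""
    if not (0 <= frame_index < spect.n_frames):
        raise IndexError(f"frame {frame_index} out of range")
    return float(all_thresholds(spect, policy)[frame_index])


def extract_peaks(
    spect: Spectrogram,
    policy: ThresholdPolicy = ThresholdPolicy(),
    search_low_hz: float = 100.0,
    search_high_hz: float = 5000.0,
    channel: str = "lung",
) -> List[List[SpectralPeak]]:
    """Per-frame strict local maxima at or above the adaptive threshold.

    A bin qualifies iff its level strictly exceeds both immediate neighbors,
    is >= the frame threshold, and lies within the search band. Returns one
    (possibly empty) list per frame, peaks ordered by bin.
    """
    thresholds = all_thresholds(spect, policy)
    lv = spect.levels
    interior = np.zeros_like(lv, dtype=bool)
    interior[:, 1:-1] = (lv[:, 1:-1] > lv[:, :-2]) & (lv[:, 1:-1] > lv[:, 2:])
    in_band = _band_mask(spect, search_low_hz, search_high_hz)
    is_peak = interior & in_band[None, :] & (lv >= thresholds[:, None])
    out: List[List[SpectralPeak]] = []
    for t in range(spect.n_frames):
        bins = np.nonzero(is_peak[t])[0]
        out.append(
            [
                SpectralPeak(
                    frame_index=t,
                    bin_index=int(b),
                    freq_hz=float(spect.bin_freqs_hz[b]),
                    level_db=float(lv[t, b]),
                    channel=channel,
                )
                for b in bins
            ]
        )
    return out
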