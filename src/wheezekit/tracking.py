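"""Linking of per-frame spectral peaks into time-frequency tracks.

A wheeze candidate is a chain of local maxima occupying consecutive STFT
frames with bounded frame-to-frame frequency jumps. Tracks shorter than the
minimum duration (heartbeat-scale transients) or outside the wheeze band
are filtered out before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .spectral import SpectralPeak


@dataclass
class PeakTrack:
    """A chain of spectral peaks on consecutive frames (gap frames allowed
    up to the configured tolerance; missing frames carry no peak)."""

    peaks: List[SpectralPeak]
    hop_s: float

    @property
    def n_frames(self) -> int:
        return len(self.peaks)

    @property
    def first_frame(self) -> int:
        return self.peaks[0].frame_index

    @property
    def last_frame(self) -> int:
        return self.peaks[-1].frame_index

    @property
    def start_s(self) -> float:
        return self.first_frame * self.hop_s

    @property
    def end_s(self) -> float:
        # duration convention: n_frames * hop
        return self.start_s + self.duration_ms / 1000.0

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.hop_s * 1000.0

    @property
    def freqs_hz(self) -> np.ndarray:
        return np.array([p.freq_hz for p in self.peaks])

    @property
    def mean_freq_hz(self) -> float:
        return float(self.freqs_hz.mean())

    @property
    def freq_sd_hz(self) -> float:
        """Population standard deviation of the per-frame peak frequencies."""
        return float(self.freqs_hz.std(ddof=0))

    @property
    def levels_db(self) -> np.ndarray:
        return np.array([p.level_db for p in self.peaks])

    @property
    def mean_level_db(self) -> float:
        """Power-mean of the per-frame peak levels (dB)."""
        return float(10.0 * np.log10(np.power(10.0, self.levels_db / 10.0).mean()))


def link_peaks(
    peaks_by_frame: Sequence[Sequence[SpectralPeak]],
    max_bin_jump: int = 3,
    gap_frames: int = 0,
    hop_s: float = 0.018,
) -> List[PeakTrack]:
    """Greedy nearest-frequency linking of peaks across frames.

    For each frame, open tracks (last peak no more than ``gap_frames + 1``
    frames back) compete for the frame's peaks: candidate pairs are taken in
    order of |bin difference| (ties: lower peak bin, then lower track bin),
    and a pair is linked iff the jump is <= ``max_bin_jump``. Each peak
    extends at most one track; unmatched peaks start new tracks, so every
    peak belongs to exactly one track.
    """
    open_tracks: List[PeakTrack] = []
    done: List[PeakTrack] = []
    for frame_peaks in peaks_by_frame:
        frame_peaks = list(frame_peaks)
        if frame_peaks:
            t = frame_peaks[0].frame_index
            still_open = [tr for tr in open_tracks if t - tr.last_frame <= gap_frames + 1]
            expired = [tr for tr in open_tracks if t - tr.last_frame > gap_frames + 1]
        else:
            continue  # frame index unknown for empty frames; expiry handled below
        done.extend(expired)

        candidates = sorted(
            (
                (abs(p.bin_index - tr.peaks[-1].bin_index), p.bin_index, tr.peaks[-1].bin_index, pi, ti)
                for pi, p in enumerate(frame_peaks)
                for ti, tr in enumerate(still_open)
            ),
        )
        used_peaks: set[int] = set()
        used_tracks: set[int] = set()
        for jump, _pb, _tb, pi, ti in candidates:
            if jump > max_bin_jump:
                break
            if pi in used_peaks or ti in used_tracks:
                continue
            still_open[ti].peaks.append(frame_peaks[pi])
            used_peaks.add(pi)
            used_tracks.add(ti)
        new_tracks = [
            PeakTrack(peaks=[p], hop_s=hop_s)
            for pi, p in enumerate(frame_peaks)
            if pi not in used_peaks
        ]
        open_tracks = still_open + new_tracks
    done.extend(open_tracks)
    done.sort(key=lambda tr: (tr.first_frame, tr.peaks[0].bin_index))
    return done


def duration_filter(tracks: Sequence[PeakTrack], min_duration_ms: float = 100.0) -> List[PeakTrack]:
    """Keep tracks lasting at least ``min_duration_ms``.

    With the default 18 ms hop this means >= 6 frames (6 x 18 = 108 ms,
    whereas 5 frames = 90 ms fails).
    """
    return [tr for tr in tracks if tr.duration_ms >= min_duration_ms]


def band_filter(
    tracks: Sequence[PeakTrack], low_hz: float = 100.0, high_hz: float = 5000.0
) -> List[PeakTrack]:
    """Keep tracks whose mean frequency lies within [low_hz, high_hz]."""
    return [tr for tr in tracks if low_hz <= tr.mean_freq_hz <= high_hz]
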