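"""Noise elimination, wheeze typing, and the file-level wheeze decision.

Candidate tracks surviving the duration and band filters are screened by a
small decision tree realizing the device's qualitative noise rules:

* heartbeat-like transients are removed by the duration criterion,
* ambient sounds (voices, room noise) register louder on the environment
  microphone than on the lung-contact microphone,
* crying is louder on the lung microphone but shows an unstable frequency
  trajectory, unlike the narrow glide of a wheeze.

A file is labelled "wheeze" iff at least one accepted wheeze event remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .audio_io import DualChannelRecording, bandpass_precondition, canonicalize
from .config import NoiseRuleConfig, RunConfig, ThresholdPolicy
from .spectral import Spectrogram, all_thresholds, compute_spectrogram, extract_peaks
from .tracking import PeakTrack, band_filter, duration_filter, link_peaks

ACCEPTED = "accepted"
REASON_TOO_SHORT = "too_short"
REASON_OUT_OF_BAND = "out_of_band"
REASON_AMBIENT = "ambient"
REASON_CRY = "cry_pattern"


@dataclass
class TrackFeatures:
    """Feature vector of one candidate track used by the noise rules."""

    duration_ms: float
    mean_freq_hz: float
    freq_sd_hz: float
    lung_level_db: float
    env_level_db: Optional[float]
    prominence_db: float = np.inf
    octave_excess_db: float = -np.inf
    concurrency: int = 1

    @property
    def lung_env_margin_db(self) -> Optional[float]:
        if self.env_level_db is None:
            return None
        return self.lung_level_db - self.env_level_db


@dataclass
class WheezeEvent:
    """An accepted wheeze with its type and summary acoustics."""

    track: PeakTrack
    wtype: str  # "monophonic" | "polyphonic"
    n_local_maxima: int
    start_s: float
    end_s: float
    dominant_freq_hz: float
    intensity_db: float


@dataclass
class FileDecision:
    """File-level result: label, accepted events and rejected candidates."""

    label: str  # "wheeze" | "no-wheeze"
    events: List[WheezeEvent]
    rejected: List[Tuple[PeakTrack, str]]
    single_channel_mode: bool = False

    @property
    def is_wheeze(self) -> bool:
        return self.label == "wheeze"


def _power_mean_db(levels: np.ndarray) -> float:
    return float(10.0 * np.log10(np.power(10.0, np.asarray(levels) / 10.0).mean()))


def compute_features(
    track: PeakTrack,
    lung_spect: Spectrogram,
    env_spect: Optional[Spectrogram] = None,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> TrackFeatures:
    """Features of one candidate track.

    The environment level is the power-mean of the environment-channel
    levels over the track's (frame, bin +/- 1) cells — the same
    time-frequency footprint the candidate occupies on the lung channel.
    The spectral prominence is the mean excess (dB) of the peak level over
    the power-mean lung level 6-10 bins (16-27 Hz) to either side. The
    octave excess is the level one octave above or below the track
    (whichever is hotter) relative to the frame's 90-5000 Hz band
    reference; harmonic (voiced) sounds score high, wheeze lines low.
    """
    frames = np.array([p.frame_index for p in track.peaks])
    bins = np.array([p.bin_index for p in track.peaks])
    if frames.max() >= lung_spect.n_frames or bins.max() >= lung_spect.n_bins:
        raise IndexError("track extends beyond the lung spectrogram")
    neigh = []
    for db in list(range(-10, -5)) + list(range(6, 11)):
        b = np.clip(bins + db, 0, lung_spect.n_bins - 1)
        neigh.append(lung_spect.levels[frames, b])
    prominence = track.mean_level_db - _power_mean_db(np.concatenate(neigh))

    band_ref = all_thresholds(lung_spect, ThresholdPolicy(policy.band_low_hz, policy.band_high_hz, 0.0))
    ref_db = _power_mean_db(band_ref[frames])
    bin_hz = lung_spect.params.bin_width_hz
    octave_excess = -np.inf
    for centers, valid in (
        (2 * bins, 2 * track.mean_freq_hz <= policy.band_high_hz),
        (bins // 2, track.mean_freq_hz / 2 >= policy.band_low_hz),
    ):
        if not valid:
            continue
        cells = []
        for db in range(-6, 7):
            b = np.clip(centers + db, 0, lung_spect.n_bins - 1)
            cells.append(lung_spect.levels[frames, b])
        octave_excess = max(octave_excess, _power_mean_db(np.concatenate(cells)) - ref_db)
    env_level: Optional[float] = None
    if env_spect is not None:
        if frames.max() >= env_spect.n_frames:
            raise IndexError("track extends beyond the environment spectrogram")
        cells = []
        for db in (-1, 0, 1):
            b = np.clip(bins + db, 0, env_spect.n_bins - 1)
            cells.append(env_spect.levels[frames, b])
        env_level = _power_mean_db(np.concatenate(cells))
    return TrackFeatures(
        duration_ms=track.duration_ms,
        mean_freq_hz=track.mean_freq_hz,
        freq_sd_hz=track.freq_sd_hz,
        lung_level_db=track.mean_level_db,
        env_level_db=env_level,
        prominence_db=prominence,
        octave_excess_db=octave_excess,
    )


def classify_track(f: TrackFeatures, rules: NoiseRuleConfig = NoiseRuleConfig()) -> str:
    """Apply the noise decision tree; returns ``"accepted"`` or a reason.

    Rule order: duration, band, ambient margin, cry pattern. The ambient
    rule is skipped in single-channel mode (no environment level).
    """
    if f.duration_ms < 100.0:
        return REASON_TOO_SHORT
    if not (100.0 <= f.mean_freq_hz <= 5000.0):
        return REASON_OUT_OF_BAND
    margin = f.lung_env_margin_db
    if margin is not None and margin < rules.min_margin_db:
        return REASON_AMBIENT
    # crying: unstable pitch trajectory, no well-defined narrowband peak
    # (broadband burst ripples rather than a wheeze line), or a harmonic
    # stack lighting up the octave bins (voiced sound)
    if (
        f.freq_sd_hz > rules.max_freq_sd_hz
        or f.prominence_db < rules.min_prominence_db
        or f.octave_excess_db > rules.max_octave_excess_db
    ):
        return REASON_CRY
    return ACCEPTED


def type_events(accepted_tracks: List[PeakTrack]) -> List[WheezeEvent]:
    """Type accepted tracks as monophonic or polyphonic.

    ``n_local_maxima`` of a track is the maximum number of simultaneously
    active accepted tracks over its span (counting itself); a single
    simultaneous peak is a monophonic wheeze, two or more are polyphonic.
    """
    if not accepted_tracks:
        return []
    lo = min(tr.first_frame for tr in accepted_tracks)
    hi = max(tr.last_frame for tr in accepted_tracks)
    active = np.zeros(hi - lo + 1, dtype=int)
    for tr in accepted_tracks:
        active[tr.first_frame - lo : tr.last_frame - lo + 1] += 1
    events = []
    for tr in accepted_tracks:
        n_max = int(active[tr.first_frame - lo : tr.last_frame - lo + 1].max())
        events.append(
            WheezeEvent(
                track=tr,
                wtype="monophonic" if n_max == 1 else "polyphonic",
                n_local_maxima=n_max,
                start_s=tr.start_s,
                end_s=tr.end_s,
                dominant_freq_hz=tr.mean_freq_hz,
                intensity_db=tr.mean_level_db,
            )
        )
    return events


def decide_file(rec: DualChannelRecording, config: RunConfig = RunConfig()) -> FileDecision:
    """Run the full recognition chain on one recording.

    canonicalize -> band-pass -> spectrograms -> peak extraction ->
    continuity tracking -> duration/band filters -> noise decision tree ->
    wheeze typing -> file label. Deterministic for fixed input and config.
    """
    rec = canonicalize(rec)
    rec = bandpass_precondition(
        rec, config.bandpass.low_hz, config.bandpass.high_hz, config.bandpass.order
    )
    lung_spect = compute_spectrogram(rec.lung, config.stft)
    env_spect = compute_spectrogram(rec.env, config.stft) if rec.env is not None else None
    peaks = extract_peaks(
        lung_spect, config.threshold, config.peaks.low_hz, config.peaks.high_hz, channel="lung"
    )
    tracks = link_peaks(
        peaks,
        max_bin_jump=config.tracking.max_bin_jump,
        gap_frames=config.tracking.gap_frames,
        hop_s=config.stft.hop / config.stft.fs,
    )
    rejected: List[Tuple[PeakTrack, str]] = []
    long_enough = duration_filter(tracks, config.tracking.min_duration_ms)
    kept = {id(tr) for tr in long_enough}
    rejected.extend((tr, REASON_TOO_SHORT) for tr in tracks if id(tr) not in kept)
    in_band = band_filter(long_enough, config.tracking.band_low_hz, config.tracking.band_high_hz)
    kept = {id(tr) for tr in in_band}
    rejected.extend((tr, REASON_OUT_OF_BAND) for tr in long_enough if id(tr) not in kept)
    accepted: List[PeakTrack] = []
    for tr in in_band:
        feats = compute_features(tr, lung_spect, env_spect, config.threshold)
        verdict = classify_track(feats, config.rules)
        if verdict == ACCEPTED:
            accepted.append(tr)
        else:
            rejected.append((tr, verdict))
    events = type_events(accepted)
    return FileDecision(
        label="wheeze" if events else "no-wheeze",
        events=events,
        rejected=rejected,
        single_channel_mode=rec.env is None,
    )
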