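"""Synthetic two-channel auscultation recordings with known ground truth.

The generator emulates 30-second tidal-breathing recordings from a
chest-contact microphone paired with an ambient-facing microphone:

* breath sounds: band-limited, gently low-frequency-weighted noise
  amplitude-modulated by a respiratory envelope (lung channel), with
  uncorrelated low-level room noise on the environment channel;
* wheezes: one (monophonic) or several simultaneous (polyphonic) slowly
  gliding tones added to the lung channel, with frequency, duration and
  level-above-breath-noise drawn from the published wheeze statistics
  (frequency mean 321 Hz, SD 178, range 100-1600 Hz; duration mean 331 ms,
  SD 220, range 100-2538 ms; intensity mean 21.2 dB, SD 7.0);
* confounders: heartbeat thumps (< 100 ms), voice bursts (louder on the
  environment channel), cries (louder on the lung channel but with a fast
  pitch trajectory), and nasal-congestion rumble.

Every operation is deterministic given its seed / generator.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .audio_io import DualChannelRecording, write_recording
from .config import CANONICAL_FS, StftParams
from .spectral import compute_spectrogram

# Published wheeze-sound statistics (mean, SD, low, high).
FREQ_STATS = (321.0, 178.0, 100.0, 1600.0)
DURATION_STATS = (331.0, 220.0, 100.0, 2538.0)
INTENSITY_STATS = (21.2, 7.0, 5.0, 45.0)
MONOPHONIC_SHARE = 0.381
# Empirical distribution of simultaneous local-maximum counts 1..10.
LOCAL_MAXIMA_COUNTS = (457, 352, 187, 104, 58, 18, 16, 3, 5, 1)

DEFAULT_PREVALENCE = 177 / 374
DEFAULT_NOISE_RATES: Dict[str, float] = {
    "heartbeat": 8.0,
    "voice": 0.8,
    "cry": 0.4,
    "nasal": 0.3,
}

# Breath-noise spectral shape: support and power slope (dB per octave)
# of the lung-channel noise, plus a steeper shelf above the knee.
BREATH_BAND = (90.0, 1600.0)
BREATH_SLOPE_DB_PER_OCT = -1.0
BREATH_SHELF_TOP_HZ = 3000.0
BREATH_SHELF_SLOPE_DB_PER_OCT = -12.0
BREATH_RMS = 0.05
ENV_NOISE_RMS = 0.002
# per-18 ms step SD of the cry fundamental's random-walk pitch (Hz)
CRY_PITCH_STEP_HZ = 25.0


@dataclass
class WheezeSpec:
    """Parameters of one synthetic wheeze event."""

    freq_hz: float
    duration_ms: float
    snr_db: float
    wtype: str  # "monophonic" | "polyphonic"
    n_components: int = 1
    component_freqs_hz: List[float] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Per-file label plus the injected events and confounders."""

    file_label: str = "no-wheeze"
    events: List[Tuple[float, float, float, str]] = field(default_factory=list)
    noises: List[Tuple[str, float, float]] = field(default_factory=list)

    def add_event(self, start_s: float, end_s: float, freq_hz: float, wtype: str) -> None:
        self.events.append((round(start_s, 4), round(end_s, 4), round(freq_hz, 1), wtype))
        self.file_label = "wheeze"

    def add_noise(self, kind: str, start_s: float, end_s: float) -> None:
        self.noises.append((kind, round(start_s, 4), round(end_s, 4)))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, low: float, high: float) -> float:
    a, b = (low - mean) / sd, (high - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_wheeze_spec(
    rng: np.random.Generator, snr_range: Tuple[float, float] = (5.0, 45.0)
) -> WheezeSpec:
    """Draw one wheeze spec from the published marginal distributions."""
    freq = _truncnorm(rng, *FREQ_STATS)
    duration = _truncnorm(rng, *DURATION_STATS)
    snr_low = max(INTENSITY_STATS[2], snr_range[0])
    snr_high = min(INTENSITY_STATS[3], snr_range[1])
    snr = _truncnorm(rng, INTENSITY_STATS[0], INTENSITY_STATS[1], snr_low, snr_high)
    if rng.random() < MONOPHONIC_SHARE:
        wtype, n_comp = "monophonic", 1
    else:
        wtype = "polyphonic"
        weights = np.array(LOCAL_MAXIMA_COUNTS[1:], dtype=float)
        n_comp = int(rng.choice(np.arange(2, 11), p=weights / weights.sum()))
    freqs = [freq]
    attempts = 0
    while len(freqs) < n_comp and attempts < 200:
        cand = _truncnorm(rng, *FREQ_STATS)
        # distinct pitches, and no near-octave pairs (a 2:1 pair is one
        # harmonic sound, not polyphony)
        separated = all(abs(cand - f) >= 60.0 for f in freqs)
        inharmonic = all(
            not (1.85 <= max(cand, f) / min(cand, f) <= 2.15) for f in freqs
        )
        if separated and inharmonic:
            freqs.append(cand)
        attempts += 1
    return WheezeSpec(
        freq_hz=freq,
        duration_ms=duration,
        snr_db=snr,
        wtype=wtype,
        n_components=len(freqs),
        component_freqs_hz=freqs,
    )


def _amplitude_shape(freqs: np.ndarray) -> np.ndarray:
    """|H(f)| of the breath-noise shaping filter."""
    lo, knee = BREATH_BAND
    f = np.maximum(freqs, 1e-6)
    # power gain in dB relative to the band's low edge
    gain_db = np.full_like(f, -np.inf)
    in_band = (f >= lo) & (f <= knee)
    gain_db[in_band] = BREATH_SLOPE_DB_PER_OCT * np.log2(f[in_band] / lo)
    shelf = (f > knee) & (f <= BREATH_SHELF_TOP_HZ)
    knee_db = BREATH_SLOPE_DB_PER_OCT * np.log2(knee / lo)
    gain_db[shelf] = knee_db + BREATH_SHELF_SLOPE_DB_PER_OCT * np.log2(f[shelf] / knee)
    amp = np.power(10.0, gain_db / 20.0)
    amp[~np.isfinite(amp)] = 0.0
    return amp


def _respiratory_envelope(
    n: int, fs: int, cycle_s: float = 2.0, insp_fraction: float = 0.4, exp_gain: float = 0.8
) -> np.ndarray:
    """Amplitude envelope of tidal breathing: alternating inspiration /
    expiration half-sines over a never-fully-silent base level."""
    t = np.arange(n) / fs
    phase = (t % cycle_s) / cycle_s
    env = np.empty(n)
    insp = phase < insp_fraction
    env[insp] = np.sin(np.pi * phase[insp] / insp_fraction)
    env[~insp] = exp_gain * np.sin(np.pi * (phase[~insp] - insp_fraction) / (1 - insp_fraction))
    return 0.3 + 0.7 * np.abs(env)


def synth_breath(
    duration_s: float = 30.0,
    fs: int = CANONICAL_FS,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    cycle_s: float = 2.0,
    insp_fraction: float = 0.4,
    exp_gain: float = 0.8,
) -> DualChannelRecording:
    """Wheeze-free tidal-breathing background recording.

    Lung channel: spectrally shaped noise (gentle low-frequency weighting
    over 90-1600 Hz, steeper shelf to 3 kHz) modulated by the respiratory
    envelope. Environment channel: uncorrelated low-level room noise.
    """
    if duration_s <= 1:
        raise ValueError("duration_s must exceed 1 second")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shaped = np.fft.irfft(spectrum * _amplitude_shape(freqs), n=n)
    shaped *= BREATH_RMS / max(np.sqrt(np.mean(shaped**2)), 1e-12)
    lung = shaped * _respiratory_envelope(n, fs, cycle_s, insp_fraction, exp_gain)
    env = ENV_NOISE_RMS * rng.standard_normal(n)
    return DualChannelRecording(lung=lung, env=env, fs=fs)


def _local_noise_level_db(
    lung: np.ndarray, fs: int, freq_hz: float, start: int, stop: int, halfwidth_hz: float = 40.0
) -> float:
    """Per-bin breath-noise level (dB, spectrogram convention) near one
    frequency over one time interval, measured before injection."""
    params = StftParams(fs=fs)
    need = params.window_len + params.hop
    lo = max(0, start - (need - (stop - start)) // 2) if stop - start < need else start
    hi = min(len(lung), max(stop, lo + need))
    lo = max(0, hi - max(stop - start, need))
    spect = compute_spectrogram(lung[lo:hi], params)
    mask = np.abs(spect.bin_freqs_hz - freq_hz) <= halfwidth_hz
    power = np.power(10.0, spect.levels[:, mask] / 10.0)
    return float(10.0 * np.log10(power.mean()))


def _raised_cosine_edges(n: int, fs: int, edge_s: float = 0.02) -> np.ndarray:
    ramp = min(int(edge_s * fs), n // 2)
    env = np.ones(n)
    if ramp > 0:
        win = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = win
        env[-ramp:] = win[::-1]
    return env


def _gliding_tone(
    rng: np.random.Generator,
    n: int,
    fs: int,
    freq_hz: float,
    max_glide_hz_per_s: float = 25.0,
    freq_limits: Tuple[float, float] = (100.0, 1600.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude tone with a slow linear glide (<= 1 FFT bin per hop)."""
    rate = rng.uniform(-max_glide_hz_per_s, max_glide_hz_per_s)
    t = np.arange(n) / fs
    inst = np.clip(freq_hz + rate * (t - t[-1] / 2), *freq_limits)
    phase = 2 * np.pi * np.cumsum(inst) / fs + rng.uniform(0, 2 * np.pi)
    return np.sin(phase) * _raised_cosine_edges(n, fs), inst


def inject_wheeze(
    rec: DualChannelRecording,
    spec: WheezeSpec,
    start_s: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[GroundTruth] = None,
) -> Tuple[DualChannelRecording, GroundTruth]:
    """Add one wheeze to the lung channel and record it in the ground truth.

    Each component is a slowly gliding tone whose spectral peak sits
    ``spec.snr_db`` dB above the concurrent breath-noise level measured in
    the component's own frequency neighbourhood. The environment channel is
    untouched.
    """
    if truth is None:
        truth = GroundTruth()
    fs = rec.fs
    n_event = int(round(spec.duration_ms / 1000.0 * fs))
    start = int(round(start_s * fs))
    stop = start + n_event
    if start < 0 or stop > rec.n_samples:
        raise ValueError("wheeze event exceeds recording bounds")
    if rng is None:
        rng = np.random.default_rng(seed)
    lung = rec.lung.copy()
    freqs = spec.component_freqs_hz or [spec.freq_hz]
    for f in freqs:
        noise_db = _local_noise_level_db(rec.lung, fs, f, start, stop)
        amp = np.power(10.0, (noise_db + spec.snr_db) / 20.0)
        tone, _ = _gliding_tone(rng, n_event, fs, f)
        lung[start:stop] += amp * tone
    out = DualChannelRecording(lung=lung, env=rec.env, fs=fs, source_path=rec.source_path)
    truth.add_event(start_s, start_s + spec.duration_ms / 1000.0, spec.freq_hz, spec.wtype)
    return out, truth


def inject_noise(
    rec: DualChannelRecording,
    kind: str,
    start_s: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[GroundTruth] = None,
) -> Tuple[DualChannelRecording, GroundTruth]:
    """Add one confounding sound; see the module docstring for the kinds."""
    if truth is None:
        truth = GroundTruth()
    if rng is None:
        rng = np.random.default_rng(seed)
    fs = rec.fs
    lung = rec.lung.copy()
    env = rec.env.copy() if rec.env is not None else None

    if kind == "heartbeat":
        dur_s = 0.06
        n = int(dur_s * fs)
        start = int(round(start_s * fs))
        if start < 0 or start + n > rec.n_samples:
            raise ValueError("noise event exceeds recording bounds")
        f = rng.uniform(40.0, 80.0)
        t = np.arange(n) / fs
        thump = 0.3 * np.sin(2 * np.pi * f * t) * np.hanning(n)
        lung[start : start + n] += thump
    elif kind == "voice":
        dur_s = rng.uniform(0.2, 0.8)
        n = int(dur_s * fs)
        start = int(round(start_s * fs))
        if start < 0 or start + n > rec.n_samples:
            raise ValueError("noise event exceeds recording bounds")
        f0 = rng.uniform(180.0, 320.0)
        burst = np.zeros(n)
        t = np.arange(n) / fs
        vibrato = 5.0 * np.sin(2 * np.pi * rng.uniform(3, 5) * t + rng.uniform(0, 2 * np.pi))
        for h in range(1, 5):
            inst = h * (f0 + vibrato)
            phase = 2 * np.pi * np.cumsum(inst) / fs + rng.uniform(0, 2 * np.pi)
            burst += np.sin(phase) / h
        burst *= _raised_cosine_edges(n, fs)
        noise_db = _local_noise_level_db(rec.lung, fs, f0, start, start + n)
        lung_amp = np.power(10.0, (noise_db + 20.0) / 20.0)
        lung[start : start + n] += lung_amp * burst
        if env is not None:
            # louder on the ambient-facing microphone
            env[start : start + n] += lung_amp * np.power(10.0, 8.0 / 20.0) * burst
    elif kind == "cry":
        dur_s = rng.uniform(0.8, 2.0)
        n = int(dur_s * fs)
        start = int(round(start_s * fs))
        if start < 0 or start + n > rec.n_samples:
            raise ValueError("noise event exceeds recording bounds")
        f0 = rng.uniform(350.0, 480.0)
        # rough, rapidly wandering pitch: random-walk fundamental
        hop = int(0.018 * fs)
        n_hops = n // hop + 2
        walk = np.cumsum(rng.normal(0.0, CRY_PITCH_STEP_HZ, n_hops))
        walk -= walk.mean()
        inst0 = f0 + np.repeat(walk, hop)[:n]
        inst0 = np.clip(inst0, 250.0, 900.0)
        burst = np.zeros(n)
        for h, amp in ((1, 1.0), (2, 1.0)):
            phase = 2 * np.pi * np.cumsum(h * inst0) / fs + rng.uniform(0, 2 * np.pi)
            burst += amp * np.sin(phase)
        burst *= _raised_cosine_edges(n, fs)
        noise_db = _local_noise_level_db(rec.lung, fs, f0, start, start + n)
        lung_amp = np.power(10.0, (noise_db + 30.0) / 20.0)
        lung[start : start + n] += lung_amp * burst
        if env is not None:
            # body-coupled: only a faint bleed reaches the ambient microphone
            env[start : start + n] += lung_amp * np.power(10.0, -12.0 / 20.0) * burst
    elif kind == "nasal":
        dur_s = rng.uniform(1.0, 3.0)
        n = int(dur_s * fs)
        start = int(round(start_s * fs))
        if start < 0 or start + n > rec.n_samples:
            raise ValueError("noise event exceeds recording bounds")
        white = rng.standard_normal(n)
        spectrum = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, 1 / fs)
        shape = np.exp(-((freqs - 55.0) ** 2) / (2 * 15.0**2))
        rumble = np.fft.irfft(spectrum * shape, n=n)
        rumble *= 0.08 / max(np.sqrt(np.mean(rumble**2)), 1e-12)
        lung[start : start + n] += rumble * _raised_cosine_edges(n, fs)
    else:
        raise ValueError(f"unknown noise kind: {kind!r}")

    truth.add_noise(kind, start_s, start_s + dur_s)
    out = DualChannelRecording(lung=lung, env=env, fs=fs, source_path=rec.source_path)
    return out, truth


def generate_recording(
    wheeze: bool,
    rng: np.random.Generator,
    duration_s: float = 30.0,
    fs: int = CANONICAL_FS,
    snr_range: Tuple[float, float] = (5.0, 45.0),
    noise_rates: Optional[Dict[str, float]] = None,
    n_events_range: Tuple[int, int] = (1, 5),
) -> Tuple[DualChannelRecording, GroundTruth]:
    """One labelled synthetic recording: breath + confounders (+ wheezes)."""
    if noise_rates is None:
        noise_rates = DEFAULT_NOISE_RATES
    rec = synth_breath(duration_s, fs, rng=rng)
    truth = GroundTruth()
    for kind, rate in noise_rates.items():
        for _ in range(rng.poisson(rate)):
            max_dur = {"heartbeat": 0.06, "voice": 0.8, "cry": 2.0, "nasal": 3.0}[kind]
            start = rng.uniform(0.5, duration_s - max_dur - 0.5)
            rec, truth = inject_noise(rec, kind, start, rng=rng, truth=truth)
    if wheeze:
        n_events = int(rng.integers(n_events_range[0], n_events_range[1] + 1))
        for _ in range(n_events):
            spec = sample_wheeze_spec(rng, snr_range)
            start = rng.uniform(0.5, duration_s - spec.duration_ms / 1000.0 - 0.5)
            rec, truth = inject_wheeze(rec, spec, start, rng=rng, truth=truth)
    return rec, truth


def iter_corpus(
    n_files: int,
    wheeze_prevalence: float = DEFAULT_PREVALENCE,
    noise_rates: Optional[Dict[str, float]] = None,
    seed: int = 0,
    duration_s: float = 30.0,
    snr_range: Tuple[float, float] = (5.0, 45.0),
    label_exact: bool = False,
    n_events_range: Tuple[int, int] = (1, 5),
):
    """Yield ``(name, recording, ground_truth)`` for a reproducible corpus.

    Labels are Bernoulli(prevalence) per file, or an exact permutation of
    round(prevalence * n) wheeze labels when ``label_exact`` is set. Each
    file uses its own child generator, so the corpus is reproducible from
    (seed, parameters) alone.
    """
    if n_files < 1:
        raise ValueError("n_files must be >= 1")
    label_rng = np.random.default_rng([seed, 0xA5])
    if label_exact:
        n_pos = int(round(wheeze_prevalence * n_files))
        labels = np.zeros(n_files, dtype=bool)
        labels[:n_pos] = True
        label_rng.shuffle(labels)
    else:
        labels = label_rng.random(n_files) < wheeze_prevalence
    for i in range(n_files):
        rng = np.random.default_rng([seed, i])
        rec, truth = generate_recording(
            bool(labels[i]),
            rng,
            duration_s=duration_s,
            snr_range=snr_range,
            noise_rates=noise_rates,
            n_events_range=n_events_range,
        )
        yield f"rec_{i:04d}.wav", rec, truth


def generate_corpus(
    n_files: int,
    wheeze_prevalence: float = DEFAULT_PREVALENCE,
    noise_rates: Optional[Dict[str, float]] = None,
    seed: int = 0,
    out_dir: Optional[str] = None,
    duration_s: float = 30.0,
    snr_range: Tuple[float, float] = (5.0, 45.0),
    label_exact: bool = False,
) -> pd.DataFrame:
    """Generate a corpus; write WAVs + a tab-delimited manifest if ``out_dir``.

    Manifest columns: file, label, n_events, events (JSON), noises (JSON),
    seed. Running twice with the same arguments is byte-identical.
    """
    rows = []
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
    for name, rec, truth in iter_corpus(
        n_files,
        wheeze_prevalence,
        noise_rates,
        seed,
        duration_s,
        snr_range,
        label_exact,
    ):
        if out_dir is not None:
            write_recording(os.path.join(out_dir, name), rec)
        rows.append(
            {
                "file": name,
                "label": truth.file_label,
                "n_events": len(truth.events),
                "events": json.dumps(truth.events),
                "noises": json.dumps(truth.noises),
                "seed": seed,
            }
        )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    return manifest
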