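# Methods

## Signal model and recognition chain

The detector treats a wheeze as a narrowband, slowly gliding spectral line
superimposed on breath noise: dominant frequency above 100 Hz (search band
100–5000 Hz) and duration above 100 ms, the standard definition for
continuous adventitious lung sounds. All analysis runs at a canonical
11.025 kHz sample rate with 16-bit quantization; arbitrary input rates are
converted by polyphase rational resampling (output length
`ceil(n·fs_out/fs_in)`, so duration is preserved to within one sample) and
a zero-phase order-5 Butterworth band-pass at 90–5000 Hz is applied
identically to both channels, guaranteeing no group-delay shift between the
lung and environment microphones.

The STFT uses a 4096-point periodic Hamming window (372 ms) with an 18 ms
hop (198 samples; the frame step is evidenced by consecutive analysis
frames 372 ms long spaced 18 ms apart, and a configuration flag restores a
128-sample hop for users who want the alternative reading). Levels are
20·log10(2|X|/Σw), i.e. dB relative to a full-scale sine, floored at
−120 dB. Only level differences matter anywhere in the chain, which yields
exact gain invariance of the final decision (asserted by tests).

### Threshold calibration

The per-frame extraction threshold is the power-mean level of all bins in
90–5000 Hz plus a margin. The margin default (18 dB) was calibrated on
pilot synthetic corpora before the validation suites were frozen. The
governing trade-off: periodogram bins of Gaussian breath noise are
exponentially distributed, and with a 95 % frame overlap an excursion above
threshold persists for roughly the window duration (≈ 20 frames), sailing
through the 100 ms duration criterion; margins of 14 dB or less flooded
wheeze-free recordings with false tracks, while margins of 20 dB or more
began to miss wheezes of typical intensity. 18 dB left no false positives
in 100 pilot no-wheeze files while keeping the file-level miss rate under
3 %.

### Tracking

Peaks are linked greedily across frames by nearest frequency, with a jump
bound of 3 bins (≈ 8 Hz per 18 ms, i.e. ≈ 450 Hz/s), no gap tolerance by
default (a configurable gap of one frame is offered; it made no measurable
difference in pilot runs), and ties broken toward the lower bin. Track
duration is `n_frames × hop`; at the default hop the ≥ 100 ms criterion
means six frames. The greedy rule is a deliberate simplification — globally
optimal assignment was not needed because wheeze lines are sparse — and is
cross-checked in tests against an independent re-implementation on random
peak sets.

### Noise decision tree

Candidates surviving the duration and band filters are screened in a fixed
order (cheapest, most certain rules first; the order changes only rejection
labels, never the file decision):

1. *too_short* — duration < 100 ms (heartbeat-scale transients; normally
   already removed by the tracking filter).
2. *out_of_band* — mean frequency outside 100–5000 Hz.
3. *ambient* — lung-minus-environment margin < 6 dB over the track's
   (frame, bin ± 1) cells. Voices and room sounds register louder on the
   ambient-facing microphone; skipped in single-channel mode (decision then
   flagged accordingly).
4. *cry_pattern* — any of: pitch trajectory SD > 30 Hz; spectral prominence
   < 8 dB (track level over the power-mean level 6–10 bins to either side);
   octave-energy excess > 8 dB (level in the bins one octave above or below
   the track, relative to the frame's band reference level).

The prominence and octave rules deserve comment because they go beyond the
minimal feature set one might first write down. Loud broadband bursts —
crying above all — produce spectral blobs whose fine ripples are *static*
across heavily overlapped frames: they form tracks hundreds of
milliseconds long with near-zero frequency SD, indistinguishable from
wheezes by duration, band, level margin or pitch stability. What does
distinguish them physically is (a) that their local maxima are shallow
ripples rather than narrow lines, and (b) that voiced sounds carry a
harmonic stack, so the octave bins are far above the ambient spectral
baseline, whereas a wheeze line sits on plain breath noise (for which the
octave-to-reference excess stayed below ≈ 6 dB in pilot measurements,
versus ≥ 10 dB for cry fragments). Both thresholds were calibrated jointly
with the extraction margin on pilot corpora and then frozen.

Accepted tracks are typed by the maximum number of simultaneously active
accepted tracks over their span: one simultaneous peak is a monophonic
wheeze, two or more polyphonic. A file is *wheeze* iff at least one event
is accepted; no minimum event count or intensity beyond that is imposed.

## Synthetic data generator

The simulator emulates the study conditions the detector is meant for:
30-second tidal-breathing recordings from a chest-contact microphone with a
paired ambient microphone.

* **Breath noise** — spectrally shaped Gaussian noise: −1 dB/octave tilt
  across 90–1600 Hz, −12 dB/octave shelf to 3 kHz, amplitude-modulated by a
  respiratory envelope (0.5 Hz cycle, 40 % inspiratory fraction, expiratory
  gain 0.8, never fully silent). Lung-channel RMS 0.05 full scale; the
  environment channel carries uncorrelated room noise at RMS 0.002.
* **Wheezes** — monophonic events are single tones; polyphonic events carry
  2–10 simultaneous tones with counts drawn from the empirical
  simultaneous-local-maximum distribution (457, 352, 187, 104, 58, 18, 16,
  3, 5, 1 over counts 1–10, renormalized over ≥ 2). Frequency, duration and
  intensity are truncated normals matching the published corpus statistics:
  321 ± 178 Hz on [100, 1600]; 331 ± 220 ms on [100, 2538]; 21.2 ± 7.0 dB on
  a configurable range (default [5, 45]). Intensity is realized as SNR: the
  tone's spectral peak is set that many dB above the concurrent
  breath-noise level measured in the tone's own frequency neighbourhood
  (the published intensity figures carry no absolute dB reference, so a
  signal-to-noise reading is the only reproducible interpretation). Tones
  glide linearly at up to 25 Hz/s — under one bin per hop — with 20 ms
  raised-cosine edges, on the lung channel only. Components of one
  polyphonic event are kept ≥ 60 Hz apart and away from 2:1 ratios, since a
  harmonic pair is one voiced sound rather than two independent pitches.
* **Confounders** — *heartbeat*: 60 ms, 40–80 Hz thump (lung only);
  *voice*: 0.2–0.8 s harmonic burst (4 harmonics, slight vibrato), 20 dB
  above local breath noise on the lung channel and 8 dB louder again on the
  environment channel; *cry*: 0.8–2 s two-harmonic stack 30 dB above local
  breath noise on the lung channel with a faint (−12 dB) ambient bleed and
  a violently wandering fundamental (random-walk pitch, step SD 25 Hz per
  18 ms); *nasal*: 1–3 s low-frequency rumble centred at 55 Hz. Default
  per-file expected counts: 8 heartbeats, 0.8 voices, 0.4 cries, 0.3 nasal
  events (Poisson).

A note on the cry model: a smoothly swept tone cannot simultaneously be
trackable under the 3-bin jump bound and have a pitch SD above 30 Hz at
this window/hop geometry — fast sweeps smear across many bins per window
and fragment into short, locally stable pieces. Crying is therefore
modelled with the rough, rapidly wandering pitch real infant cries exhibit,
and its rejection in practice comes from the fragment-duration, prominence
and octave (harmonicity) rules rather than from the per-track frequency-SD
rule. The frequency-SD rule is retained for moderately unstable tonal
noises.

Wheeze-file event counts are uniform on 1–5 (per-file counts are not
published; the choice is configurable). Corpus labels are Bernoulli at the
configured prevalence (default 177/374 ≈ 0.473), or an exact permutation in
label-exact mode. Every file has its own child generator derived from
(seed, file index), so corpora are exactly reproducible.

### What the simulator does and does not capture

It reproduces the first-order statistics that drive the detector: spectral
shapes, level relations between the two microphones, event durations and
densities. It does not model airway acoustics, microphone/skin coupling,
room reverberation, body movement artifacts, or the correlation structure
of real breath sounds beyond a stationary spectrum with a periodic
envelope. Passing the synthetic validation therefore demonstrates the
internal consistency of the chain under the stated conditions — not
clinical performance; the published clinical figures are reproduced only
as arithmetic on the published counts.

## Accuracy statistics

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP), NPV
TN/(TN+FN), displayed as percentages rounded half-up to one decimal.
Confidence intervals are exact binomial (Clopper–Pearson) by default, with
Wilson as an option; the interval method behind the published tables is not
stated, so printed intervals are not asserted (the exact method does
reproduce, e.g., 92.8–98.7 for 171/177). Subgroup reports break sensitivity
and specificity down by configurable age bands (default 0–11, 12–23, 24–35,
36–107 months) and sex; rows with empty denominators are flagged undefined
rather than dropped.

The Jonckheere–Terpstra trend statistic sums pairwise Mann–Whitney counts
over ordered group pairs (ties ½). The p value is an exact full permutation
when the pooled n ≤ 12, otherwise a normal approximation with tie-corrected
variance and a 0.5 continuity correction (agreement with the exact
distribution is within 0.02 on tie-free instances of that size, asserted in
tests). Two-sided by default, as the sidedness behind the published
analysis is unstated.

## Numerical conventions and degenerate inputs

* Integer PCM scales by 1/32768; quantization snaps to the 16-bit grid with
  the positive rail clipped at 32767/32768 so write→read round trips are
  sample-exact.
* Zero-power spectrogram bins sit at the −120 dB floor; an all-zero
  recording is a clean no-wheeze.
* Plateau ties in peak extraction are broken by strictness (a flat
  spectrum has no local maxima); linking ties go to the lower bin.
* Population (ddof = 0) convention for the track frequency SD.
* Mono recordings are processed with the ambient rule skipped and the
  decision flagged `single_channel_mode`.

## Known limitations

* The published step-5 feature set and thresholds of the original device
  are unpublished; the concrete features here (level margin, frequency SD,
  prominence, octave excess) and their defaults are this package's own
  design, so no numerical equivalence with the device is claimed.
* Very short (≈ 100–200 ms), weak wheezes lose peak level to the 372 ms
  analysis window and can fall below threshold; these account for
  essentially all residual misses in synthetic validation (≈ 2–3 % of
  wheeze files at the default conditions).
* A wheeze occurring inside a loud cry can be masked (flagged as part of
  the cry); a clinician would face the same recording conditions.
* Low-frequency rumble that extends above 100 Hz with narrowband structure
  is indistinguishable from a low wheeze under this feature set; the
  simulated nasal-congestion rumble is kept below the search band.
* Whole-file thresholding (as opposed to per-frame) cannot be ruled out as
  the original design; per-frame adaptation was chosen for gain robustness.
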