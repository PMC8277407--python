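# wheezekit

Automatic wheeze recognition for pediatric home-auscultation audio, plus a
synthetic lung-sound simulator and the diagnostic-accuracy statistics used
to validate file-level wheeze decisions.

## The problem

Wheezes — continuous adventitious lung sounds with a dominant frequency
above 100 Hz lasting longer than 100 ms — are the key exacerbation sign in
childhood asthma, but parents, nurses and physicians often disagree about
whether a child is wheezing. Handheld devices that press a contact
microphone to the chest for a 30-second tidal-breathing recording can make
that judgment objective, provided the recognition algorithm tells wheezes
apart from heartbeats, the physician's voice, ambient noise and crying — all
routine in a pediatric consultation room. `wheezekit` implements such a
recognition chain for two-channel recordings (skin-coupled lung microphone
plus ambient-facing environment microphone) and the statistical machinery
for evaluating it (sensitivity, specificity, PPV, NPV with exact binomial
intervals; Jonckheere–Terpstra trend test across age bands).

## The algorithm

For a recording `x` (resampled to 11.025 kHz, 16-bit, band-passed
90–5000 Hz):

1. **STFT** with a 4096-point Hamming window (372 ms) advanced every 18 ms,
   giving levels `L[t, f]` in dB.
2. **Adaptive threshold** per frame: `T[t] = 10·log10(mean_f 10^(L[t,f]/10))
   + Δ` over the 90–5000 Hz band (default margin Δ = 18 dB), making the
   peak set invariant to overall gain.
3. **Peak extraction**: strict spectral local maxima with `L[t,f] ≥ T[t]`
   inside 100–5000 Hz.
4. **Continuity tracking**: greedy nearest-frequency linking across frames
   (jump ≤ 3 bins ≈ 8 Hz per 18 ms); tracks shorter than 100 ms (heartbeat
   scale) or outside 100–5000 Hz are dropped.
5. **Noise decision tree** on each surviving track: rejected as *ambient*
   when the environment channel is within 6 dB of the lung channel over the
   track's time-frequency cells; rejected as *cry-like* when the pitch
   trajectory is unstable (frequency SD > 30 Hz), the peak is not a
   narrowband line (spectral prominence < 8 dB), or the octave bins are hot
   (harmonic stack of a voiced sound). Surviving tracks are wheezes; a
   single simultaneous track is a *monophonic* wheeze, two or more are
   *polyphonic*. A file is labelled **wheeze** iff at least one accepted
   wheeze event exists.

The simulator (`wheezekit.synth`) generates labelled 30-second two-channel
recordings: breath noise shaped and amplitude-modulated by a respiratory
envelope, wheezes drawn from the published corpus statistics (frequency
321 ± 178 Hz in 100–1600 Hz; duration 331 ± 220 ms in 100–2538 ms; intensity
21.2 ± 7.0 dB; 38.1% monophonic), and heartbeat / voice / cry / nasal
confounders.

## Worked example

```bash
$ wheezekit synth --n 3 --seed 4 --out corpus/ --duration 10
wrote 3 files (2 wheeze) to corpus/

$ wheezekit detect corpus/rec_0001.wav
wheeze
 start_s    end_s  freq_hz         type  intensity_db
   2.891    3.161    371.6   polyphonic         -34.0
   2.945    3.125    517.1   polyphonic         -35.4
   5.226    5.460    314.9   monophonic         -35.2
$ echo $?
1
```

The event table lists each accepted wheeze with its span, dominant
frequency, type and mean level (dB relative to digital full scale); the
exit code is 1 for wheeze, 0 for no-wheeze, 2 on error. `--json` writes the
full report including rejected candidate tracks and their rejection
reasons. Evaluating predictions against a labelled manifest:

```bash
$ wheezekit evaluate --manifest manifest.tsv --predictions preds.tsv
TP=171 FP=3 FN=6 TN=194 (n=374)
 sensitivity:  96.6% (171/177) 95% CI 92.8-98.7
 specificity:  98.5% (194/197) 95% CI 95.6-99.7
         PPV:  98.3% (171/174) 95% CI 95.0-99.6
         NPV:  97.0% (194/200) 95% CI 93.6-98.9
```

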