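"""Synthetic corpus generator: determinism, spectra, marginals, end-to-end."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal, stats

from wheezekit.classify import REASON_AMBIENT, decide_file
from wheezekit.synth import (
    DURATION_STATS,
    FREQ_STATS,
    GroundTruth,
    WheezeSpec,
    generate_corpus,
    inject_noise,
    inject_wheeze,
    sample_wheeze_spec,
    synth_breath,
)


class TestBreath:
    def test_same_seed_reproduces_waveforms(self):
        a = synth_breath(5, seed=7)
        b = synth_breath(5, seed=7)
        np.testing.assert_array_equal(a.lung, b.lung)
        np.testing.assert_array_equal(a.env, b.env)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_pure_breath_is_no_wheeze(self, seed):
        assert decide_file(synth_breath(30, seed=seed)).label == "no-wheeze"

    def test_lung_spectrum_slopes_down_between_200_and_1000(self):
        rec = synth_breath(30, seed=11)
        f, pxx = signal.welch(rec.lung, fs=rec.fs, nperseg=4096)
        band = (f >= 200) & (f <= 1000)
        slope = np.polyfit(np.log2(f[band]), 10 * np.log10(pxx[band]), 1)[0]
        assert slope < 0

    def test_env_channel_uncorrelated_and_quiet(self):
        rec = synth_breath(10, seed=12)
        assert np.std(rec.env) < 0.2 * np.std(rec.lung)
        r = np.corrcoef(rec.lung, rec.env)[0, 1]
        assert abs(r) < 0.05

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            synth_breath(0.5)


class TestWheezeSpecSampling:
    def test_marginals_match_published_statistics(self):
        """At n=10,000 the sampled mean frequency lies within 321 +/- 6 Hz."""
        rng = np.random.default_rng(100)
        specs = [sample_wheeze_spec(rng) for _ in range(10_000)]
        freqs = np.array([s.freq_hz for s in specs])
        durs = np.array([s.duration_ms for s in specs])
        mean, sd, lo, hi = FREQ_STATS
        a, b = (lo - mean) / sd, (hi - mean) / sd
        expected_freq_mean = stats.truncnorm.mean(a, b, loc=mean, scale=sd)
        assert abs(freqs.mean() - expected_freq_mean) < 6
        assert freqs.min() >= lo and freqs.max() <= hi
        assert durs.min() >= DURATION_STATS[2] and durs.max() <= DURATION_STATS[3]

    def test_type_mix_near_published_shares(self):
        rng = np.random.default_rng(101)
        specs = [sample_wheeze_spec(rng) for _ in range(4000)]
        mono = np.mean([s.wtype == "monophonic" for s in specs])
        assert abs(mono - 0.381) < 0.03
        comps = [s.n_components for s in specs if s.wtype == "polyphonic"]
        assert min(comps) >= 2 and max(comps) <= 10

    def test_polyphonic_components_are_separated_and_inharmonic(self):
        rng = np.random.default_rng(102)
        for _ in range(300):
            s = sample_wheeze_spec(rng)
            fs = sorted(s.component_freqs_hz)
            for i in range(len(fs) - 1):
                for j in range(i + 1, len(fs)):
                    assert fs[j] - fs[i] >= 60
                    assert not (1.85 <= fs[j] / fs[i] <= 2.15)

    def test_snr_respects_configured_range(self):
        rng = np.random.default_rng(103)
        snrs = [sample_wheeze_spec(rng, snr_range=(10, 45)).snr_db for _ in range(500)]
        assert min(snrs) >= 10 and max(snrs) <= 45


class TestInjection:
    def test_polyphonic_event_typed_with_two_maxima(self):
        rng = np.random.default_rng(200)
        rec = synth_breath(10, rng=rng)
        spec = WheezeSpec(freq_hz=300, duration_ms=400, snr_db=20, wtype="polyphonic",
                          n_components=2, component_freqs_hz=[300.0, 700.0])
        rec, truth = inject_wheeze(rec, spec, start_s=4.0, rng=rng)
        decision = decide_file(rec)
        assert decision.label == "wheeze"
        overlapping = [e for e in decision.events if e.end_s > 4.0 and e.start_s < 4.4]
        assert any(e.wtype == "polyphonic" and e.n_local_maxima >= 2 for e in overlapping)

    def test_sub_noise_event_is_not_detected(self):
        rng = np.random.default_rng(201)
        rec = synth_breath(10, rng=rng)
        spec = WheezeSpec(freq_hz=400, duration_ms=500, snr_db=-20, wtype="monophonic",
                          n_components=1, component_freqs_hz=[400.0])
        rec, _ = inject_wheeze(rec, spec, start_s=4.0, rng=rng)
        assert decide_file(rec).label == "no-wheeze"

    def test_event_beyond_bounds_rejected(self):
        rec = synth_breath(5, seed=202)
        spec = WheezeSpec(freq_hz=400, duration_ms=500, snr_db=10, wtype="monophonic",
                          n_components=1, component_freqs_hz=[400.0])
        with pytest.raises(ValueError):
            inject_wheeze(rec, spec, start_s=4.8, seed=0)

    def test_env_channel_untouched_by_wheeze(self):
        rec = synth_breath(6, seed=203)
        spec = WheezeSpec(freq_hz=400, duration_ms=300, snr_db=20, wtype="monophonic",
                          n_components=1, component_freqs_hz=[400.0])
        out, _ = inject_wheeze(rec, spec, start_s=2.0, seed=0)
        np.testing.assert_array_equal(out.env, rec.env)


class TestNoiseInjection:
    def test_heartbeats_do_not_trigger_wheeze(self):
        rng = np.random.default_rng(300)
        rec = synth_breath(15, rng=rng)
        for start in (3.0, 7.0, 11.0):
            rec, _ = inject_noise(rec, "heartbeat", start, rng=rng)
        assert decide_file(rec).label == "no-wheeze"

    def test_voice_burst_rejected_as_ambient(self):
        rng = np.random.default_rng(301)
        rec = synth_breath(15, rng=rng)
        rec, _ = inject_noise(rec, "voice", 6.0, rng=rng)
        decision = decide_file(rec)
        assert decision.label == "no-wheeze"
        assert any(r == REASON_AMBIENT for _, r in decision.rejected)

    def test_cry_burst_is_no_wheeze_with_rejections(self):
        rng = np.random.default_rng(302)
        rec = synth_breath(15, rng=rng)
        rec, _ = inject_noise(rec, "cry", 6.0, rng=rng)
        decision = decide_file(rec)
        assert decision.label == "no-wheeze"
        assert len(decision.rejected) > 0

    def test_unknown_kind_rejected(self):
        rec = synth_breath(5, seed=303)
        with pytest.raises(ValueError):
            inject_noise(rec, "thunder", 1.0, seed=0)

    def test_ground_truth_records_noise_span(self):
        rec = synth_breath(10, seed=304)
        _, truth = inject_noise(rec, "voice", 3.0, seed=1)
        (kind, start, end) = truth.noises[0]
        assert kind == "voice" and start == 3.0 and 0.2 <= end - start <= 0.8
        assert truth.file_label == "no-wheeze"


class TestCorpus:
    def test_manifest_reproducible(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        m1 = generate_corpus(6, seed=5, out_dir=str(d1), duration_s=8.0)
        m2 = generate_corpus(6, seed=5, out_dir=str(d2), duration_s=8.0)
        assert (d1 / "manifest.tsv").read_text() == (d2 / "manifest.tsv").read_text()
        pd.testing.assert_frame_equal(m1, m2)

    def test_zero_prevalence_all_no_wheeze(self):
        m = generate_corpus(8, wheeze_prevalence=0.0, seed=6, duration_s=6.0)
        assert (m["label"] == "no-wheeze").all()

    def test_label_exact_mode_hits_count(self):
        m = generate_corpus(20, wheeze_prevalence=0.45, seed=7, duration_s=6.0, label_exact=True)
        assert (m["label"] == "wheeze").sum() == 9

    def test_label_matches_events(self):
        m = generate_corpus(10, seed=8, duration_s=6.0)
        assert ((m["n_events"] > 0) == (m["label"] == "wheeze")).all()

    def test_written_files_are_readable_and_processable(self, tmp_path):
        from wheezekit.audio_io import read_recording

        generate_corpus(2, seed=9, out_dir=str(tmp_path), duration_s=6.0)
        rec = read_recording(str(tmp_path / "rec_0000.wav"))
        assert rec.env is not None and rec.fs == 11025
        decide_file(rec)  # must run without error
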