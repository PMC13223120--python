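"""Acoustic feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vdt2 import acoustic, synth
from vdt2.exceptions import (
    InsufficientCyclesError,
    MetadataParseError,
    NoVoicedFramesError,
    VDT2Error,
)
from vdt2.features import FEATURE_NAMES


def _alternating_periods(ms_a=9.9, ms_b=10.1, n=40):
    periods = np.array([ms_a, ms_b] * (n // 2)) / 1000.0
    return acoustic.PeriodSequence(
        boundaries=np.concatenate(([0.0], np.cumsum(periods)))[:-1],
        periods=periods,
        amplitudes=np.ones(n),
    )


class TestJitterFormulas:
    def test_constant_periods_zero(self):
        p = _alternating_periods(10.0, 10.0)
        assert all(v == 0.0 for v in acoustic.jitter_metrics(p).values())

    def test_alternating_hand_values(self):
        # alternating 9.9/10.1 ms: |dT| = 0.2 ms everywhere, mean T = 10 ms;
        # a period deviates from its 3-point window mean by 4*delta/3 and
        # from its 5-point mean by 4*delta/5 (delta = 0.1 ms)
        j = acoustic.jitter_metrics(_alternating_periods())
        assert j["localJitter"] == pytest.approx(0.02, rel=1e-9)
        assert j["localabsJitter"] == pytest.approx(2.0e-4, rel=1e-9)
        assert j["rapJitter"] == pytest.approx(4 * 0.1 / 3 / 10, rel=1e-9)
        assert j["ppq5Jitter"] == pytest.approx(4 * 0.1 / 5 / 10, rel=1e-9)

    def test_nonpositive_period_rejected(self):
        p = _alternating_periods()
        p.periods[3] = -1e-3
        with pytest.raises(VDT2Error):
            acoustic.jitter_metrics(p)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-3, 2e-2), min_size=6, max_size=40))
    def test_time_reversal_invariance(self, periods):
        periods = np.asarray(periods)
        fwd = acoustic.PeriodSequence(np.cumsum(periods) - periods[0], periods,
                                      np.ones_like(periods))
        rev = acoustic.PeriodSequence(np.cumsum(periods[::-1]) - periods[-1],
                                      periods[::-1], np.ones_like(periods))
        a, b = acoustic.jitter_metrics(fwd), acoustic.jitter_metrics(rev)
        assert a["localJitter"] == pytest.approx(b["localJitter"], rel=1e-12)


class TestShimmerFormulas:
    def test_constant_amplitudes_zero(self):
        p = _alternating_periods()
        assert all(v == 0.0 for v in acoustic.shimmer_metrics(p).values())

    def test_alternating_hand_values(self):
        p = _alternating_periods(10, 10)
        p.amplitudes = np.array([0.9, 1.1] * 20)
        s = acoustic.shimmer_metrics(p)
        assert s["localShimmer"] == pytest.approx(0.2, rel=1e-9)
        assert s["localdbShimmer"] == pytest.approx(20 * np.log10(1.1 / 0.9), rel=1e-9)
        assert s["apq3Shimmer"] == pytest.approx(4 * 0.1 / 3, rel=1e-9)
        assert s["apq5Shimmer"] == pytest.approx(4 * 0.1 / 5, rel=1e-9)
        assert s["apq11Shimmer"] == pytest.approx(12 * 0.1 / 11, rel=1e-9)

    def test_too_few_amplitudes(self):
        p = _alternating_periods(n=10)
        with pytest.raises(InsufficientCyclesError):
            acoustic.shimmer_metrics(p)


class TestPitch:
    def test_sawtooth_100hz(self):
        t = np.arange(0, 2, 1 / 16000)
        saw = 0.9 * (2 * ((100 * t) % 1) - 1)
        contour = acoustic.f0_contour(acoustic.Waveform(saw, 16000))
        f0 = contour["f0"].dropna()
        assert f0.mean() == pytest.approx(100.0, abs=1.0)
        assert f0.std() < 1.0

    def test_white_noise_unvoiced(self):
        noise = np.random.default_rng(0).standard_normal(32000) * 0.5
        with pytest.raises(NoVoicedFramesError):
            acoustic.f0_contour(acoustic.Waveform(noise, 16000))

    def test_t2dm_u_preset_f0(self):
        spec = synth.vowel_preset(
            "T2DM", "u", duration_s=2.0, jitter_frac=0.0, shimmer_frac=0.0
        )
        res = synth.synth_vowel(spec)
        feats = acoustic.extract_features(acoustic.Waveform(res.samples, res.rate))
        assert feats["meanF0"] == pytest.approx(177.14, abs=2.0)


class TestMarkPeriods:
    def test_unperturbed_marks_match_ground_truth(self):
        res = synth.synth_vowel(
            synth.VowelSynthSpec(f0_hz=155.3, duration_s=2.0, seed=4)
        )
        w = acoustic.Waveform(res.samples, res.rate)
        seq = acoustic.mark_periods(w, acoustic.f0_contour(w))
        assert np.max(np.abs(seq.periods - 1 / 155.3)) * res.rate < 1.0

    def test_shimmer_amplitudes_correlate_with_truth(self, perturbed_vowel):
        _, res, _, _ = perturbed_vowel
        w = acoustic.Waveform(res.samples, res.rate)
        seq = acoustic.mark_periods(w, acoustic.f0_contour(w))
        truth = np.interp(seq.boundaries, res.boundaries, res.amplitudes)
        assert np.corrcoef(seq.amplitudes, truth)[0, 1] > 0.9

    def test_short_signal_insufficient_cycles(self):
        # 0.11 s at 100 Hz holds ~10 cycles, below the 12 apq11 needs
        res = synth.synth_vowel(
            synth.VowelSynthSpec(f0_hz=100.0, duration_s=0.6, sample_rate_hz=16000)
        )
        w = acoustic.Waveform(res.samples[: int(0.11 * 16000)], 16000)
        with pytest.raises(InsufficientCyclesError):
            acoustic.mark_periods(w, acoustic.f0_contour(w))


class TestHNR:
    def test_frame_formula_half_correlation_is_zero_db(self):
        assert acoustic.frame_hnr_db(0.5) == pytest.approx(0.0)

    def test_noiseless_hits_cap(self):
        t = np.arange(0, 2, 1 / 16000)
        w = acoustic.Waveform(np.sin(2 * np.pi * 100 * t), 16000)
        assert acoustic.hnr_metric(w, acoustic.f0_contour(w)) == pytest.approx(40.0, abs=0.01)

    def test_injected_hnr_recovered(self):
        spec = synth.VowelSynthSpec(f0_hz=155.3, hnr_db=20.0, duration_s=2.0, seed=3)
        res = synth.synth_vowel(spec)
        w = acoustic.Waveform(res.samples, res.rate)
        assert acoustic.hnr_metric(w, acoustic.f0_contour(w)) == pytest.approx(20.0, abs=2.0)


class TestIntensity:
    def test_full_scale_sine_level(self):
        t = np.arange(0, 1, 1 / 16000)
        mean_db, sd_db = acoustic.intensity_metrics(
            acoustic.Waveform(np.sin(2 * np.pi * 200 * t), 16000)
        )
        # RMS 1/sqrt(2) against the 2e-5 reference
        assert mean_db == pytest.approx(20 * np.log10((1 / np.sqrt(2)) / 2e-5), abs=0.05)
        assert sd_db < 0.05

    def test_halving_amplitude_drops_6db(self):
        t = np.arange(0, 1, 1 / 16000)
        x = np.sin(2 * np.pi * 200 * t)
        full, _ = acoustic.intensity_metrics(acoustic.Waveform(x, 16000))
        half, _ = acoustic.intensity_metrics(acoustic.Waveform(x / 2, 16000))
        assert full - half == pytest.approx(20 * np.log10(2), abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(VDT2Error):
            acoustic.intensity_metrics(acoustic.Waveform(np.zeros(16000), 16000))


class TestExtractFeatures:
    def test_unperturbed_vowel_near_clean_limits(self):
        res = synth.synth_vowel(
            synth.VowelSynthSpec(f0_hz=150.0, duration_s=2.0, seed=6)
        )
        feats = acoustic.extract_features(acoustic.Waveform(res.samples, res.rate))
        assert feats["localJitter"] < 1e-3
        assert feats["localShimmer"] < 1e-3
        assert feats["HNR"] > 30.0
        assert set(feats) == set(FEATURE_NAMES)

    def test_oracle_equivalence_at_two_percent(self, perturbed_vowel):
        # extractor vs formulas on the generator's ground-truth sequences
        _, _, feats, oracle = perturbed_vowel
        for name in ("localJitter", "localabsJitter", "rapJitter", "ppq5Jitter",
                     "localShimmer", "localdbShimmer", "apq3Shimmer",
                     "apq5Shimmer", "apq11Shimmer"):
            assert feats[name] == pytest.approx(oracle[name], rel=0.15), name

    def test_monotone_in_injected_jitter(self):
        ests = []
        for jf in (0.0, 0.01, 0.02, 0.04):
            spec = synth.VowelSynthSpec(
                f0_hz=150.0, jitter_frac=jf, duration_s=3.0, seed=7
            )
            res = synth.synth_vowel(spec)
            feats = acoustic.extract_features(
                acoustic.Waveform(res.samples, res.rate)
            )
            ests.append(feats["localJitter"])
        assert np.all(np.diff(ests) > 0)

    def test_gain_invariance(self):
        res = synth.synth_vowel(
            synth.VowelSynthSpec(
                f0_hz=150.0, jitter_frac=0.01, shimmer_frac=0.02,
                duration_s=1.5, sample_rate_hz=16000, seed=8,
            )
        )
        base = acoustic.extract_features(acoustic.Waveform(res.samples, res.rate))
        gained = acoustic.extract_features(
            acoustic.Waveform(res.samples * 0.25, res.rate)
        )
        for name in FEATURE_NAMES:
            if name in ("meanInten",):
                assert base[name] - gained[name] == pytest.approx(
                    20 * np.log10(4), abs=0.01
                )
            elif name != "stdevInten":
                assert gained[name] == pytest.approx(base[name], rel=1e-6), name

    def test_stereo_averaged_to_mono(self):
        res = synth.synth_vowel(
            synth.VowelSynthSpec(f0_hz=150.0, duration_s=1.0, sample_rate_hz=16000)
        )
        stereo = np.column_stack([res.samples, res.samples])
        w = acoustic.Waveform(stereo, 16000)
        assert w.samples.ndim == 1
        assert np.allclose(w.samples, res.samples)

    def test_too_short_recording_rejected(self):
        with pytest.raises(VDT2Error, match="0.5 s"):
            acoustic.extract_features(acoustic.Waveform(np.ones(1000), 16000))


class TestParseFilename:
    @pytest.mark.parametrize(
        "name, subject, sex, group, vowel, rep",
        [
            ("zhang_M_T_a_1.wav", "zhang", "M", "T2DM", "a", 1),
            ("li_F_N_u_2.wav", "li", "F", "ND", "u", 2),
            ("wang_hua_F_N_v_1.wav", "wang_hua", "F", "ND", "ü", 1),
            ("chen_M_sen_s_1.wav", "chen", "M", "sentence", "s", 1),
        ],
    )
    def test_valid_names(self, name, subject, sex, group, vowel, rep):
        meta = acoustic.parse_filename(name)
        assert (meta.subject, meta.sex, meta.group, meta.vowel, meta.repetition) == (
            subject, sex, group, vowel, rep,
        )

    @pytest.mark.parametrize(
        "name, field",
        [
            ("badname.wav", "fields"),
            ("zhang_X_T_a_1.wav", "sex"),
            ("zhang_M_Q_a_1.wav", "group"),
            ("zhang_M_T_q_1.wav", "vowel"),
            ("zhang_M_T_a_one.wav", "repetition"),
        ],
    )
    def test_malformed_names_name_the_field(self, name, field):
        with pytest.raises(MetadataParseError, match=field):
            acoustic.parse_filename(name)


def test_extract_directory_matches_cohort_schema(tmp_path):
    cfg = synth.CohortConfig(
        n_t2dm=1, n_control=1, vowels=("a", "o"), repetitions=1,
        dropout_n=0, seed=9,
    )
    synth.generate_wav_dataset(tmp_path, cfg, duration_s=1.0, sample_rate_hz=16000)
    table = acoustic.extract_directory(tmp_path)
    assert len(table) == 4
    assert list(table.columns) == [
        "subject", "sex", "group", "vowel", "repetition", *FEATURE_NAMES
    ]
    assert set(table["group"]) == {"T2DM", "ND"}
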