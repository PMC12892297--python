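import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from bimodalffr import stimuli as st


class TestSynthVowel:
    @pytest.mark.parametrize("spec", st.DEFAULT_VOWELS, ids=lambda s: s.label)
    def test_pitch_and_formant_fidelity(self, vowel_tokens, spec):
        """Synthesized vowels measure f0 = 130 ± 1 Hz and F1 ± 10 Hz."""
        sig = vowel_tokens[spec.label]
        assert st.estimate_f0(sig) == pytest.approx(spec.f0, abs=1.0)
        assert st.estimate_f1(sig) == pytest.approx(spec.f1, abs=10.0)

    def test_sample_count_follows_duration(self):
        sig = st.synth_vowel(st.VowelSpec("ε", duration=0.39), rate=44100.0)
        assert len(sig.samples) == 17199

    def test_resonance_on_fourth_harmonic(self, vowel_tokens):
        """With F1 = 4·f0 = 520 Hz, harmonic 4 is the strongest harmonic."""
        sig = vowel_tokens["ε"]
        spec = np.abs(np.fft.rfft(sig.samples))
        freqs = np.fft.rfftfreq(len(sig.samples), 1 / sig.rate)
        harm_amps = [
            spec[np.argmin(np.abs(freqs - k * 130.0))] for k in range(1, 8)
        ]
        assert np.argmax(harm_amps) == 3  # harmonic 4

    def test_peak_within_full_scale(self, vowel_tokens):
        for sig in vowel_tokens.values():
            assert np.max(np.abs(sig.samples)) <= 1.0

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            st.VowelSpec("x", f0=130.0, f1=100.0)  # F1 below f0
        with pytest.raises(ValueError):
            st.synth_vowel(st.DEFAULT_VOWELS[0], rate=4000.0)  # rate too low


class TestGreenwood:
    def test_default_bank_endpoints(self):
        edges = st.greenwood_edges(8, 200.0, 7000.0)
        assert len(edges) == 9
        assert edges[0] == 200.0 and edges[-1] == 7000.0

    def test_single_channel(self):
        assert np.allclose(st.greenwood_edges(1, 200.0, 7000.0), [200.0, 7000.0])

    def test_middle_edge_matches_closed_form(self):
        """Two channels: the interior edge is the Greenwood image of the
        midpoint in cochlear position, by direct inversion of the map."""
        a_const, alpha, k = 165.4, 2.1, 0.88
        x = lambda f: np.log10(f / a_const + k) / alpha
        xm = (x(200.0) + x(7000.0)) / 2.0
        expected = a_const * (10 ** (alpha * xm) - k)
        edges = st.greenwood_edges(2, 200.0, 7000.0)
        assert edges[1] == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(
        n=hst.integers(1, 64),
        f_lo=hst.floats(50.0, 1000.0),
        span=hst.floats(1.5, 30.0),
    )
    def test_strictly_increasing_endpoint_exact(self, n, f_lo, span):
        edges = st.greenwood_edges(n, f_lo, f_lo * span)
        assert np.all(np.diff(edges) > 0)
        assert edges[0] == f_lo and edges[-1] == pytest.approx(f_lo * span)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            st.greenwood_edges(4, 7000.0, 200.0)


class TestVocoder:
    def test_deterministic_under_seed(self, vowel_tokens):
        a = st.vocode(vowel_tokens["i"], seed=11)
        b = st.vocode(vowel_tokens["i"], seed=11)
        assert np.array_equal(a.samples, b.samples)

    def test_band_confinement(self, vowel_tokens):
        """Output power outside the 200-7000 Hz analysis range (beyond the
        rolloff skirts) sits ≥ 40 dB below in-band power."""
        out = st.vocode(vowel_tokens["ʊ"], seed=2)
        freqs = np.fft.rfftfreq(len(out.samples), 1 / out.rate)
        p = np.abs(np.fft.rfft(out.samples)) ** 2
        in_band = p[(freqs >= 200) & (freqs <= 7000)].sum()
        out_band = p[(freqs < 100) | (freqs > 14000)].sum()
        assert 10 * np.log10(in_band / max(out_band, 1e-300)) >= 40.0

    def test_silence_in_silence_out(self):
        silent = st.AudioSignal(np.zeros(44100), 44100.0)
        assert not np.any(st.vocode(silent, seed=0).samples)

    def test_rms_matched_to_input(self, vowel_tokens):
        sig = vowel_tokens["ε"]
        out = st.vocode(sig, seed=5)
        assert out.rms() == pytest.approx(sig.rms(), rel=1e-6)

    @pytest.mark.parametrize("label", ["ε", "i", "ʊ"])
    def test_envelope_periodicity_line_at_f0(self, vowel_tokens, label):
        """The f0 periodicity survives vocoding: the envelope spectrum shows
        a line near 130 Hz well above the 70-1000 Hz background (for /i/ the
        *dominant* envelope component is F1 = 260 Hz, so the f0 line need
        not be the global maximum)."""
        sums = None
        for seed in range(4):
            out = st.vocode(vowel_tokens[label], seed=seed)
            freqs, mag = st.envelope_spectrum(out)
            sums = mag if sums is None else sums + mag
        band = (freqs >= 70) & (freqs <= 1000)
        near_f0 = band & (np.abs(freqs - 130.0) <= 4.0)
        line = sums[near_f0].max()
        background = np.median(sums[band])
        assert line >= 4.0 * background

    def test_envelope_maximum_at_f0_for_open_vowel(self, vowel_tokens):
        """For /ε/ (F1 = 520 Hz, above the strongest envelope beats) the
        envelope-spectrum maximum in 70-1000 Hz falls at 130 ± 4 Hz."""
        sums = None
        for seed in range(4):
            out = st.vocode(vowel_tokens["ε"], seed=seed)
            freqs, mag = st.envelope_spectrum(out)
            sums = mag if sums is None else sums + mag
        band = (freqs >= 70) & (freqs <= 1000)
        peak = freqs[band][np.argmax(sums[band])]
        assert abs(peak - 130.0) <= 4.0


class TestLowpass:
    def test_tone_an_octave_above_cutoff_heavily_attenuated(self):
        """48 dB/octave: a tone at 2×cutoff loses ≥ 40 dB (analytic
        Butterworth magnitude 1/sqrt(1+(f/fc)^16) predicts ≈ 48 dB)."""
        rate = 44100.0
        t = np.arange(int(rate)) / rate
        tone = st.AudioSignal(0.5 * np.sin(2 * np.pi * 500.0 * t), rate)
        out = st.lowpass_branch(tone, 250.0)
        # discard the filter transient before measuring
        gain_db = 20 * np.log10(out.samples[4410:].std() / tone.samples[4410:].std())
        assert gain_db <= -40.0
        analytic = -10 * np.log10(1 + (500.0 / 250.0) ** 16)
        assert gain_db == pytest.approx(analytic, abs=3.0)

    def test_dc_preserved(self):
        sig = st.AudioSignal(np.full(4096, 0.25), 8000.0)
        out = st.lowpass_branch(sig, 250.0)
        assert out.samples[-1] == pytest.approx(0.25, rel=1e-3)

    def test_formant_passed_or_attenuated_by_cutoff(self, vowel_tokens):
        """/i/ (F1 = 260 Hz): a 250 Hz cutoff clips F1, a 500 Hz cutoff
        passes it within 1 dB."""
        sig = vowel_tokens["i"]

        def f1_amp(s):
            spec = np.abs(np.fft.rfft(s.samples))
            freqs = np.fft.rfftfreq(len(s.samples), 1 / s.rate)
            return spec[np.argmin(np.abs(freqs - 260.0))]

        ref = f1_amp(sig)
        passed = f1_amp(st.lowpass_branch(sig, 500.0))
        clipped = f1_amp(st.lowpass_branch(sig, 250.0))
        assert 20 * np.log10(passed / ref) > -1.0
        assert clipped < passed

    def test_passive_no_energy_gain(self, vowel_tokens):
        for cutoff in (125.0, 250.0, 500.0, 750.0):
            sig = vowel_tokens["ʊ"]
            out = st.lowpass_branch(sig, cutoff)
            assert np.sum(out.samples**2) <= np.sum(sig.samples**2) * (1 + 1e-6)

    def test_nonstandard_cutoff_warns_and_nyquist_errors(self, vowel_tokens):
        with pytest.warns(UserWarning):
            st.lowpass_branch(vowel_tokens["ε"], 300.0)
        with pytest.raises(ValueError):
            st.lowpass_branch(vowel_tokens["ε"], 30000.0)


class TestAlignment:
    def test_identical_envelopes_zero_lag(self, vowel_tokens):
        sig = vowel_tokens["ε"]
        lag, shifted = st.align_envelopes(sig, sig)
        assert lag == 0
        assert np.array_equal(shifted.samples, sig.samples)

    def test_planted_delay_recovered(self, vowel_tokens):
        """A 5 ms planted delay is undone by a −5 ms lag."""
        sig = vowel_tokens["ʊ"]
        d = int(round(0.005 * sig.rate))
        delayed = np.concatenate([np.zeros(d), sig.samples[:-d]])
        lag, shifted = st.align_envelopes(sig, st.AudioSignal(delayed, sig.rate))
        assert abs(lag + d) <= 1  # edge effects may shift the peak 1 sample
        r = np.corrcoef(shifted.samples[d:-d], sig.samples[d:-d])[0, 1]
        assert r > 0.95

    def test_vocoder_group_delay_within_search_window(self, vowel_tokens):
        sig = vowel_tokens["i"]
        voc = st.vocode(sig, seed=4)
        lp = st.lowpass_branch(sig, 500.0)
        lag, _ = st.align_envelopes(voc, lp)
        assert abs(lag) <= int(0.020 * sig.rate)

    def test_zero_envelope_rejected(self):
        z = st.AudioSignal(np.zeros(1000), 44100.0)
        with pytest.raises(ValueError):
            st.align_envelopes(z, z)


class TestBimodalSet:
    @pytest.fixture(scope="class")
    def stimset(self):
        return st.make_bimodal_set(seed=3)

    def test_fifteen_stimuli(self, stimset):
        assert len(stimset) == 15
        assert {s.condition for s in stimset} == set(st.CONDITIONS)

    def test_vocoder_only_has_no_acoustic_ear(self, stimset):
        for s in stimset:
            if s.condition == "Voc":
                assert s.left is None

    def test_right_ear_identical_across_conditions(self, stimset):
        for label in ("ε", "i", "ʊ"):
            rights = [s.right.samples for s in stimset if s.vowel.label == label]
            for r in rights[1:]:
                assert np.array_equal(r, rights[0])

    def test_binaural_lengths_match(self, stimset):
        for s in stimset:
            if s.left is not None:
                assert len(s.left.samples) == len(s.right.samples)

    def test_wav_roundtrip(self, stimset, tmp_path):
        stim = next(s for s in stimset if s.left is not None)
        path = tmp_path / "stim.wav"
        st.write_stimulus_wav(path, stim)
        left, right = st.read_wav(path)
        assert np.allclose(right.samples, stim.right.samples, atol=1e-6)
        assert np.allclose(left.samples, stim.left.samples, atol=1e-6)
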