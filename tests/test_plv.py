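import numpy as np
import pytest
from scipy import special, stats

from bimodalffr import plv as pl
from bimodalffr.preprocess import EpochSet

from conftest import make_sine_epochs

RATE = 10_000.0


class TestTrialSpectrogram:
    def test_window_arithmetic_and_grid(self):
        """A 550 ms epoch yields 491 full 60 ms windows at a 1 ms hop, on a
        1 Hz interpolated frequency grid."""
        spec, times, freqs = pl.trial_spectrogram(np.random.default_rng(0).standard_normal(5500))
        assert spec.shape == (491, 1001)
        assert len(times) == 491
        assert np.allclose(np.diff(freqs), 1.0)
        assert np.allclose(np.diff(times), 1.0)
        assert times[0] == pytest.approx(-20.0)  # first window center

    def test_pure_tone_phase_ramp(self):
        """The phase at 130 Hz advances by 2π·130·Δt per 1 ms hop."""
        t = np.arange(5500) / RATE
        spec, times, freqs = pl.trial_spectrogram(np.sin(2 * np.pi * 130.0 * t))
        phases = np.unwrap(np.angle(spec[100:200, 130]))
        mean_step = (phases[-1] - phases[0]) / (len(phases) - 1)
        assert mean_step == pytest.approx(2 * np.pi * 130.0 * 1e-3, abs=1e-3)

    def test_epoch_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            pl.trial_spectrogram(np.zeros(300))


class TestPLV:
    def test_identical_trials_fully_coherent(self):
        eps = make_sine_epochs(20, kappa=np.inf, alternate_polarity=False)
        spg = pl.plv(eps, "A", t_range_ms=(150, 250), hop_ms=10.0)
        assert np.all(spg.values <= 1.0 + 1e-12)
        spec = pl.plv_spectrum(spg)
        assert spec.at(130.0) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_phases_near_floor(self):
        eps = make_sine_epochs(500, kappa=0.0, seed=4, alternate_polarity=False)
        spg = pl.plv(eps, "A", t_range_ms=(150, 250), hop_ms=10.0)
        assert pl.plv_spectrum(spg).at(130.0) <= 2 / np.sqrt(500)

    def test_von_mises_jitter_matches_bessel_ratio(self):
        """κ = 1 planted jitter -> PLV ≈ I1(1)/I0(1) ≈ 0.446 at N = 1000."""
        eps = make_sine_epochs(1000, kappa=1.0, seed=9, alternate_polarity=False)
        spg = pl.plv(eps, "A", t_range_ms=(150, 250), hop_ms=10.0)
        expected = float(special.i1(1.0) / special.i0(1.0))
        assert pl.plv_spectrum(spg).at(130.0) == pytest.approx(expected, abs=0.05)

    def test_invariant_to_per_trial_amplitude_scaling(self):
        eps = make_sine_epochs(40, kappa=2.0, noise=0.3, seed=2, alternate_polarity=False)
        rng = np.random.default_rng(7)
        scales = rng.uniform(0.1, 10.0, 40)
        scaled = EpochSet(
            eps.trials * scales[:, None], eps.polarity, eps.rejected, eps.rate
        )
        a = pl.plv(eps, "A", t_range_ms=(100, 200), hop_ms=10.0)
        b = pl.plv(scaled, "A", t_range_ms=(100, 200), hop_ms=10.0)
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_needs_two_trials(self):
        eps = make_sine_epochs(1, alternate_polarity=False)
        with pytest.raises(ValueError):
            pl.plv(eps, "A")


class TestPLVSpectrum:
    def _const_spg(self, v, pol="A"):
        times = np.arange(140.0, 260.0)
        freqs = np.arange(0.0, 1001.0)
        return pl.PLVSpectrogram(
            np.full((len(times), len(freqs)), v), times, freqs, 100, pol
        )

    def test_constant_value_passes_through(self):
        spec = pl.plv_spectrum(self._const_spg(0.37), self._const_spg(0.37, "B"))
        assert np.allclose(spec.values, 0.37)

    def test_equal_polarities_equal_time_mean(self):
        eps = make_sine_epochs(30, kappa=3.0, noise=0.2, seed=5, alternate_polarity=False)
        spg = pl.plv(eps, "A", t_range_ms=(150, 250), hop_ms=5.0)
        spec = pl.plv_spectrum(spg, spg)
        assert np.allclose(spec.values, spg.values.mean(axis=0))

    def test_polarity_average_is_mean_of_plvs(self):
        a, b = self._const_spg(0.2), self._const_spg(0.6, "B")
        assert np.allclose(pl.plv_spectrum(a, b).values, 0.4)

    def test_grid_mismatch_rejected(self):
        a = self._const_spg(0.2)
        b = pl.PLVSpectrogram(
            np.full((120, 500), 0.2), np.arange(140.0, 260.0), np.arange(500.0), 10, "B"
        )
        with pytest.raises(ValueError):
            pl.plv_spectrum(a, b)

    def test_steady_component_only_in_window_towers_over_floor(self):
        """A 130 Hz component present only in the 150-250 ms steady state
        produces a spectrum peak ≥ 5× the prestimulus noise floor."""
        rng = np.random.default_rng(12)
        n, n_samp = 400, 5500
        t = np.arange(n_samp) / RATE
        gate = (t >= 0.200) & (t < 0.300)  # 150-250 ms post-onset
        trials = 0.5 * rng.standard_normal((n, n_samp))
        trials += 2.0 * np.sin(2 * np.pi * 130.0 * t) * gate
        eps = EpochSet(trials, np.array(["A", "B"] * 200), np.zeros(n, bool), RATE)
        spg_a = pl.plv(eps, "A", t_range_ms=(150, 250), hop_ms=5.0)
        spg_b = pl.plv(eps, "B", t_range_ms=(150, 250), hop_ms=5.0)
        floor = pl.noise_floor(eps)
        spec = pl.plv_spectrum(spg_a, spg_b, floor=floor)
        assert spec.at(130.0) >= 5.0 * spec.floor_at(130.0)
        assert int(np.argmax(spec.values)) == 130


class TestNoiseFloor:
    def _noise_epochs(self, n, seed=0):
        rng = np.random.default_rng(seed)
        trials = rng.standard_normal((n, 5500))
        pol = np.array(["A", "B"] * (n // 2))
        return EpochSet(trials, pol, np.zeros(n, bool), RATE)

    def test_pure_noise_floor_exchangeable_with_response_window(self):
        """On pure noise the prestimulus floor and a single response-window
        PLV (computed in the same manner) are draws from the same
        resultant-length distribution."""
        eps = self._noise_epochs(100, seed=3)
        spg_a = pl.plv(eps, "A", t_range_ms=(204, 206), hop_ms=25.0)
        spg_b = pl.plv(eps, "B", t_range_ms=(204, 206), hop_ms=25.0)
        assert spg_a.values.shape[0] == 1  # one 60 ms window, like the floor
        resp = pl.plv_spectrum(spg_a, spg_b, window_ms=(150.0, 250.0)).values
        floor = pl.noise_floor(eps)
        # compare distributions over ~independent bins: the 60 ms window has
        # ≈17 Hz resolution, so adjacent 1 Hz bins are strongly correlated
        assert stats.ks_2samp(resp[20::20], floor[30::20]).pvalue > 0.01

    def test_floor_shrinks_as_inverse_sqrt_n(self):
        floors = {}
        for n in (50, 200, 800):
            floors[n] = pl.noise_floor(self._noise_epochs(n, seed=n)).mean()
        assert floors[200] / floors[50] == pytest.approx(np.sqrt(50 / 200), rel=0.20)
        assert floors[800] / floors[200] == pytest.approx(np.sqrt(200 / 800), rel=0.20)

    def test_planted_response_beats_floor(self):
        eps = make_sine_epochs(50, kappa=np.inf, noise=0.5, seed=8)
        spg = pl.plv(eps, "A", t_range_ms=(150, 250), hop_ms=10.0)
        spec = pl.plv_spectrum(spg, floor=pl.noise_floor(eps))
        assert spec.at(130.0) > spec.floor_at(130.0)

    def test_floor_values_valid(self):
        floor = pl.noise_floor(self._noise_epochs(40))
        assert floor.shape == (1001,)
        assert np.all((floor >= 0) & (floor <= 1))


class TestNeuralBenefit:
    def _spectrum(self, peaks: dict, base=0.05):
        freqs = np.arange(0.0, 1001.0)
        vals = np.full(len(freqs), base)
        for f, v in peaks.items():
            vals[int(f)] = v
        return pl.PLVSpectrum(vals, freqs, 100)

    def test_identical_conditions_zero_benefit(self):
        spectra = {v: self._spectrum({130: 0.3}) for v in ("ε", "i", "ʊ")}
        f0b, f1b = pl.neural_benefit({"Voc": spectra, "Voc+750": spectra})
        assert f0b == 0.0 and f1b == 0.0

    def test_planted_f1_gain_detected_without_f0_change(self):
        lo = {
            "ε": self._spectrum({130: 0.3, 520: 0.1}),
            "i": self._spectrum({130: 0.3, 260: 0.1}),
            "ʊ": self._spectrum({130: 0.3, 390: 0.1}),
        }
        hi = {
            "ε": self._spectrum({130: 0.3, 520: 0.4}),
            "i": self._spectrum({130: 0.3, 260: 0.4}),
            "ʊ": self._spectrum({130: 0.3, 390: 0.4}),
        }
        f0b, f1b = pl.neural_benefit({"Voc": lo, "Voc+750": hi})
        assert f1b == pytest.approx(0.3, abs=1e-12)
        assert abs(f0b) < 1e-12

    def test_benefits_bounded(self):
        lo = {v: self._spectrum({}, base=0.0) for v in ("ε", "i", "ʊ")}
        hi = {v: self._spectrum({130: 1.0, 520: 1.0, 260: 1.0, 390: 1.0}, base=1.0)
              for v in ("ε", "i", "ʊ")}
        f0b, f1b = pl.neural_benefit({"Voc": lo, "Voc+750": hi})
        assert -1.0 <= f0b <= 1.0 and -1.0 <= f1b <= 1.0

    def test_missing_condition_rejected(self):
        spectra = {v: self._spectrum({130: 0.3}) for v in ("ε", "i", "ʊ")}
        with pytest.raises(KeyError):
            pl.neural_benefit({"Voc": spectra})
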