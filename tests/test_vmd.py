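import numpy as np
import pytest

from uwbvitals import VMDConfig, vmd_decompose
from uwbvitals.errors import (
    InvalidInputError,
    UndefinedFrequencyError,
)
from uwbvitals.vmd import (
    convergence_metric,
    update_center_frequency,
    update_mode_spectrum,
)

RATE = 20.0
FFT_BIN = 0.05  # Hz, for a 20 s record at 20 frames/s


def tones(t, *components):
    """Sum of cosine tones given as (freq, amp) pairs."""
    return sum(amp * np.cos(2 * np.pi * f * t) for f, amp in components)


def fft_peak(signal, rate):
    """Independent oracle: coarse spectral peak location."""
    mag = np.abs(np.fft.rfft(signal))
    return np.fft.rfftfreq(signal.size, 1 / rate)[np.argmax(mag)]


class TestModeUpdate:
    def test_zero_residual_and_dual_give_zero_mode(self):
        freqs = np.linspace(-0.5, 0.5, 16, endpoint=False)
        zero = np.zeros(16, dtype=complex)
        out = update_mode_spectrum(zero, [zero], zero, 0.1, 2000.0, freqs)
        assert np.allclose(out, 0.0)

    def test_denominator_is_one_at_the_center_frequency(self, rng):
        freqs = np.linspace(-0.5, 0.5, 16, endpoint=False)
        f_hat = rng.normal(size=16) + 1j * rng.normal(size=16)
        zero = np.zeros(16, dtype=complex)
        omega = freqs[10]
        out = update_mode_spectrum(f_hat, [zero], zero, omega, 5000.0, freqs)
        assert out[10] == pytest.approx(f_hat[10])

    def test_matches_elementwise_bruteforce(self, rng):
        """The Wiener update equals an independently coded per-bin evaluation."""
        n = 16
        freqs = np.linspace(-0.5, 0.5, n, endpoint=False)
        f_hat = rng.normal(size=n) + 1j * rng.normal(size=n)
        others = [rng.normal(size=n) + 1j * rng.normal(size=n) for _ in range(2)]
        dual = rng.normal(size=n) + 1j * rng.normal(size=n)
        omega, alpha = 0.17, 3000.0
        got = update_mode_spectrum(f_hat, others, dual, omega, alpha, freqs)
        expected = np.array(
            [
                (f_hat[i] - others[0][i] - others[1][i] + dual[i] / 2)
                / (1 + 2 * alpha * (freqs[i] - omega) ** 2)
                for i in range(n)
            ]
        )
        assert np.allclose(got, expected)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            update_mode_spectrum(
                np.zeros(8), [np.zeros(8)], np.zeros(8), 0.1, 100.0, np.zeros(9)
            )


class TestCenterFrequency:
    def test_point_mass_returns_its_bin(self):
        freqs = np.linspace(-0.5, 0.5, 40, endpoint=False)
        spectrum = np.zeros(40, dtype=complex)
        k = np.argmin(np.abs(freqs - 0.025))
        spectrum[k] = 3.0 + 1.0j
        assert update_center_frequency(spectrum, freqs) == pytest.approx(freqs[k])

    def test_symmetric_spectrum_returns_its_axis(self):
        freqs = np.linspace(0.0, 0.5, 51)
        spectrum = np.exp(-((freqs - 0.25) ** 2) / 1e-3)
        assert update_center_frequency(spectrum, freqs) == pytest.approx(0.25, abs=1e-9)

    def test_matches_bruteforce_weighted_mean(self, rng):
        freqs = np.linspace(-0.5, 0.5, 32, endpoint=False)
        spectrum = rng.normal(size=32) + 1j * rng.normal(size=32)
        num = den = 0.0
        for i in range(32):
            if freqs[i] >= 0:
                p = abs(spectrum[i]) ** 2
                num += freqs[i] * p
                den += p
        assert update_center_frequency(spectrum, freqs) == pytest.approx(num / den)

    def test_empty_spectrum_has_no_frequency(self):
        freqs = np.linspace(-0.5, 0.5, 16, endpoint=False)
        with pytest.raises(UndefinedFrequencyError):
            update_center_frequency(np.zeros(16), freqs)


class TestConvergenceMetric:
    def test_identical_sets_have_zero_change(self, rng):
        modes = rng.normal(size=(3, 20))
        assert convergence_metric(modes, modes) == 0.0

    def test_small_scaling_gives_epsilon_squared(self, rng):
        mode = rng.normal(size=(1, 50))
        eps = 1e-4
        assert convergence_metric(mode, (1 + eps) * mode) == pytest.approx(
            eps**2, rel=1e-6
        )

    def test_matches_direct_formula(self, rng):
        prev = rng.normal(size=(2, 10))
        cur = prev + 0.01 * rng.normal(size=(2, 10))
        expected = sum(
            np.sum((cur[k] - prev[k]) ** 2) / np.sum(prev[k] ** 2) for k in range(2)
        )
        assert convergence_metric(prev, cur) == pytest.approx(expected)

    def test_zero_previous_mode_uses_absolute_change(self):
        prev = np.zeros((1, 4))
        cur = np.full((1, 4), 0.5)
        assert convergence_metric(prev, cur) == pytest.approx(4 * 0.25)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            convergence_metric(np.zeros((2, 4)), np.zeros((2, 5)))


class TestDecompose:
    def test_zero_signal_yields_zero_modes_immediately(self):
        result = vmd_decompose(np.zeros(64), RATE, VMDConfig(n_modes=3))
        assert np.allclose(result.modes, 0.0)
        assert result.converged
        assert result.n_iterations == 0

    def test_single_tone_center_frequency_recovered(self):
        t = np.arange(400) / RATE
        signal = np.sin(2 * np.pi * 1.0 * t)
        result = vmd_decompose(signal, RATE, VMDConfig(n_modes=1, alpha=2000.0))
        oracle = fft_peak(signal, RATE)
        assert abs(result.center_freqs[0] - oracle) <= FFT_BIN
        assert abs(result.center_freqs[0] - 1.0) <= FFT_BIN

    def test_two_tone_separation_and_energy_order(self):
        """Respiration-scale + heartbeat-scale tones separate into two modes."""
        t = np.arange(400) / RATE
        signal = 1.0 * np.sin(2 * np.pi * 0.35 * t) + 0.25 * np.sin(2 * np.pi * 1.35 * t)
        result = vmd_decompose(signal, RATE, VMDConfig(n_modes=2, alpha=9000.0, tol=1e-6))
        assert abs(result.center_freqs[0] - 0.35) <= FFT_BIN
        assert abs(result.center_freqs[1] - 1.35) <= FFT_BIN
        assert result.mode_energy(0) > result.mode_energy(1)

    def test_reconstruction_of_bandlimited_input(self):
        """Sum of modes reproduces a noiseless in-band signal within 5%."""
        t = np.arange(400) / RATE
        signal = tones(t, (0.3, 1.0), (1.5, 0.5), (3.0, 0.3))
        result = vmd_decompose(signal, RATE, VMDConfig())
        assert result.reconstruction_residual <= 0.05

    def test_center_frequencies_are_a_fixed_point(self):
        """At convergence each reported frequency matches its own mode's centroid."""
        t = np.arange(400) / RATE
        signal = tones(t, (0.35, 1.0), (1.35, 0.25))
        result = vmd_decompose(signal, RATE, VMDConfig(n_modes=2, alpha=9000.0))
        for k in range(result.modes.shape[0]):
            spectrum = np.fft.rfft(result.modes[k])
            freqs = np.fft.rfftfreq(result.modes[k].size, 1 / RATE)
            centroid = float(
                np.dot(freqs, np.abs(spectrum) ** 2) / np.sum(np.abs(spectrum) ** 2)
            )
            assert centroid == pytest.approx(result.center_freqs[k], abs=2 * FFT_BIN)

    def test_modes_are_band_separated(self):
        t = np.arange(400) / RATE
        signal = tones(t, (0.35, 1.0), (1.35, 0.25))
        result = vmd_decompose(signal, RATE, VMDConfig(n_modes=2, alpha=9000.0))
        midpoint = result.center_freqs.mean()
        spectrum = np.abs(np.fft.rfft(result.modes[0])) ** 2
        freqs = np.fft.rfftfreq(result.modes[0].size, 1 / RATE)
        leak = spectrum[freqs > midpoint].sum() / spectrum.sum()
        assert leak < 0.10

    def test_deterministic_for_fixed_config(self):
        t = np.arange(200) / RATE
        signal = tones(t, (0.4, 1.0), (1.6, 0.5))
        a = vmd_decompose(signal, RATE, VMDConfig(n_modes=2))
        b = vmd_decompose(signal, RATE, VMDConfig(n_modes=2))
        assert np.array_equal(a.modes, b.modes)
        assert np.array_equal(a.center_freqs, b.center_freqs)

    def test_sorted_by_center_frequency(self):
        t = np.arange(400) / RATE
        signal = tones(t, (0.3, 0.4), (2.2, 1.0))
        result = vmd_decompose(signal, RATE, VMDConfig(n_modes=2, alpha=5000.0))
        assert np.all(np.diff(result.center_freqs) >= 0)

    def test_nonfinite_input_rejected(self):
        bad = np.ones(64)
        bad[10] = np.nan
        with pytest.raises(InvalidInputError):
            vmd_decompose(bad, RATE)

    def test_duplicate_modes_consolidated_on_a_single_tone(self):
        """Surplus modes that converge onto one tone are merged by default."""
        t = np.arange(400) / RATE
        signal = np.cos(2 * np.pi * 1.0 * t)
        merged = vmd_decompose(signal, RATE, VMDConfig(n_modes=3, alpha=9000.0))
        gaps = np.diff(merged.center_freqs)
        half_power = RATE / np.sqrt(2 * 9000.0)
        assert np.all(gaps >= half_power)


def test_human_signal_respiration_mode_dominates(human_standard):
    """On a human-preset echo the respiration-band mode out-powers heartbeat."""
    from uwbvitals import energy_indicator, locate_target, preprocess, synthesize_subject
    from uwbvitals.classify import select_vimfs

    cube = synthesize_subject("human", seed=40)
    filt = preprocess(cube)
    index, _ = locate_target(energy_indicator(filt))
    result = vmd_decompose(filt.amplitudes[index, ::2], filt.slow_time_rate / 2, VMDConfig())
    r_idx, h_idx = select_vimfs(result)
    assert result.mode_energy(r_idx) > result.mode_energy(h_idx)
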