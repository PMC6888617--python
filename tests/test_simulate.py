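import numpy as np
import pytest

from uwbvitals import (
    ChestMotion,
    PulseSpec,
    SceneSpec,
    chest_displacement,
    default_profiles,
    energy_indicator,
    locate_target,
    preprocess,
    remove_dc,
    synthesize_cube,
    synthesize_pulse,
    synthesize_subject,
    time_of_flight,
)
from uwbvitals.errors import InvalidConfigError, InvalidInputError
from uwbvitals.simulate import SPEED_OF_LIGHT


class TestChestDisplacement:
    def test_static_target_stays_at_nominal_range(self):
        motion = ChestMotion(d0=1.3)
        t = np.linspace(0, 10, 50)
        assert np.allclose(chest_displacement(motion, t), 1.3)

    def test_zero_phase_at_time_zero(self):
        motion = ChestMotion(d0=1.0, m_b=5e-3, f_b=0.35, m_h=2e-4, f_h=1.35)
        assert chest_displacement(motion, 0.0) == pytest.approx(1.0)

    def test_quarter_period_hits_full_respiration_amplitude(self):
        motion = ChestMotion(d0=1.0, m_b=5e-3, f_b=0.35)
        t = 1.0 / (4 * 0.35)
        assert chest_displacement(motion, t) == pytest.approx(1.0 + 5e-3)

    def test_validation(self):
        with pytest.raises(InvalidInputError):
            ChestMotion(d0=0.0)
        with pytest.raises(InvalidInputError):
            ChestMotion(d0=1.0, m_b=-1e-3)
        with pytest.raises(InvalidInputError):
            ChestMotion(d0=0.01, m_b=5e-3)  # displacement not small vs d0


class TestTimeOfFlight:
    def test_values_and_linearity(self):
        assert time_of_flight(0.0) == 0.0
        assert time_of_flight(1.0) == pytest.approx(2.0 / SPEED_OF_LIGHT)
        assert time_of_flight(1.0) == pytest.approx(6.671e-9, rel=1e-3)
        assert time_of_flight(2.4) == pytest.approx(2 * time_of_flight(1.2))

    def test_negative_distance_rejected(self):
        with pytest.raises(InvalidInputError):
            time_of_flight(-0.1)


class TestPulse:
    def test_unit_peak_at_zero_delay(self):
        spec = PulseSpec()
        assert spec.waveform(0.0) == pytest.approx(1.0)

    def test_spectrum_peaks_at_center_frequency(self):
        spec = PulseSpec()
        n = 4096
        tau = (np.arange(n) - n // 2) / spec.fast_time_rate
        pulse = synthesize_pulse(spec, tau)
        freqs = np.fft.rfftfreq(n, 1 / spec.fast_time_rate)
        mag = np.abs(np.fft.rfft(pulse))
        peak = freqs[np.argmax(mag)]
        assert abs(peak - spec.center_frequency) <= freqs[1]

    def test_minus_10db_width_matches_bandwidth(self):
        spec = PulseSpec()
        n = 16384
        tau = (np.arange(n) - n // 2) / spec.fast_time_rate
        mag = np.abs(np.fft.rfft(synthesize_pulse(spec, tau)))
        freqs = np.fft.rfftfreq(n, 1 / spec.fast_time_rate)
        above = freqs[mag >= mag.max() * 10 ** (-10 / 20)]
        width = above.max() - above.min()
        assert width == pytest.approx(spec.bandwidth, rel=0.10)

    def test_sub_nyquist_grid_rejected(self):
        spec = PulseSpec()
        coarse = np.arange(64) / 1e9  # 1 GS/s: far below the pulse band
        with pytest.raises(InvalidConfigError):
            synthesize_pulse(spec, coarse)


class TestSynthesizeCube:
    def test_static_scene_has_identical_frames(self):
        scene = SceneSpec(motion=ChestMotion(d0=1.0), noise_sigma=0.0, duration=1.0)
        cube = synthesize_cube(scene)
        assert np.allclose(cube.amplitudes, cube.amplitudes[:, :1])

    def test_same_seed_reproduces_bit_identical_cube(self):
        scene = SceneSpec(
            motion=ChestMotion(d0=1.0, m_b=4e-3, f_b=0.3),
            noise_sigma=0.05, duration=2.0, random_seed=7,
        )
        a = synthesize_cube(scene)
        b = synthesize_cube(scene)
        assert np.array_equal(a.amplitudes, b.amplitudes)

    def test_energy_scales_quadratically_with_target_amplitude(self):
        motion = ChestMotion(d0=1.0, m_b=4e-3, f_b=0.3)
        cubes = [
            synthesize_cube(SceneSpec(motion=motion, target_amplitude=a, duration=5.0))
            for a in (1.0, 2.0)
        ]
        energies = [
            float(np.sum(remove_dc(c).amplitudes ** 2)) for c in cubes
        ]
        assert energies[1] == pytest.approx(4 * energies[0], rel=1e-6)

    def test_moving_target_located_within_pulse_resolution(self):
        """The max-energy bin lands within the pulse's range resolution of d0.

        Bin-level accuracy is limited by carrier-phase nulls inside the pulse
        envelope, so the physical bound is c/(2B), not one bin.
        """
        scene = SceneSpec(
            motion=ChestMotion(d0=1.0, m_b=5e-3, f_b=0.35, m_h=2.5e-4, f_h=1.35),
            noise_sigma=0.0,
        )
        cube = synthesize_cube(scene)
        _, distance = locate_target(energy_indicator(preprocess(cube)))
        resolution = SPEED_OF_LIGHT / (2 * scene.pulse.bandwidth)
        assert abs(distance - 1.0) <= resolution

    def test_invalid_scene_rejected(self):
        with pytest.raises(InvalidConfigError):
            SceneSpec(duration=0.0)
        with pytest.raises(InvalidConfigError):
            SceneSpec(range_window=(2.0, 2.0))
        with pytest.raises(InvalidConfigError):
            SceneSpec(motion=ChestMotion(d0=6.0), range_window=(0.2, 5.0))


class TestSynthesizeSubject:
    def test_drawn_parameters_respect_preset_ranges(self):
        profile = default_profiles()["human"]
        cube = synthesize_subject("human", seed=3)
        motion = cube.provenance["motion"]
        assert profile.resp_freq_range[0] <= motion["f_b"] <= profile.resp_freq_range[1]
        assert profile.heart_freq_range[0] <= motion["f_h"] <= profile.heart_freq_range[1]

    def test_rabbit_gets_body_drift(self):
        motion = synthesize_subject("rabbit", seed=3).provenance["motion"]
        assert motion["drift_amp"] > 0
        assert motion["drift_freq"] > 0

    def test_different_seeds_draw_different_subjects(self):
        a = synthesize_subject("dog", seed=1).provenance["motion"]
        b = synthesize_subject("dog", seed=2).provenance["motion"]
        assert a["f_b"] != b["f_b"]

    def test_unknown_species_rejected(self):
        with pytest.raises(InvalidInputError):
            synthesize_subject("hamster")

    def test_presets_respect_slow_time_nyquist(self):
        rate = SceneSpec().slow_time_rate
        for profile in default_profiles().values():
            assert profile.heart_freq_range[1] < rate / 2


def test_respiration_only_signal_is_periodic():
    """With no heartbeat or noise, the target-bin signal repeats at 1/f_b."""
    f_b = 0.4
    scene = SceneSpec(
        motion=ChestMotion(d0=1.0, m_b=3e-3, f_b=f_b), noise_sigma=0.0, duration=20.0
    )
    cube = remove_dc(synthesize_cube(scene))
    index, _ = locate_target(energy_indicator(cube))
    sig = cube.amplitudes[index]
    lag = int(round(cube.slow_time_rate / f_b))
    # autocorrelation peak (excluding lag 0 neighborhood) sits at the period
    ac = np.correlate(sig, sig, mode="full")[sig.size - 1:]
    search = np.arange(lag // 2, min(sig.size, 2 * lag))
    best = search[np.argmax(ac[search])]
    assert abs(best - lag) <= 1
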