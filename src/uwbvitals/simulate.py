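"""Physics-based IR-UWB echo simulator.

The scene model is the standard stationary-subject vital-sign model: the
chest-wall distance oscillates around a nominal range,

    d(t) = d0 + m_b sin(2 pi f_b t + phi_b) + m_h sin(2 pi f_h t + phi_h)
                + drift_amp sin(2 pi drift_freq t + phi_d),

and each received frame is a superposition of static multipath pulses plus the
target pulse delayed by the round-trip time of flight of ``d(t)``:

    r(t, tau) = sum_i A_i p(tau - tau_i) + A_T p(tau - tau_d(t)).

The pulse ``p`` is a Gaussian-envelope cosine at the radar's center frequency;
the simulator evaluates it directly on the receiver's range grid (one bin per
fast-time sample), so millimeter chest motion modulates the carrier phase at
the target bins exactly as in a real receiver: the slow-time signal at a bin is
``cos(phi_0 + beta sin(...))`` with modulation depth ``beta = 4 pi f_c m / c``.
That phase-to-amplitude mechanism (including its harmonic distortion and
null-point dependence on ``phi_0``) is what the downstream pipeline has to
cope with, so it is reproduced rather than idealized away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .cube import RadarCube
from .errors import InvalidConfigError, InvalidInputError
from .physio import SpeciesProfile, amplitude_ratio_from_lhwr, default_profiles

#: propagation speed used for the range <-> time-of-flight conversion, m/s
SPEED_OF_LIGHT = 2.998e8


def time_of_flight(distance):
    """Round-trip time of flight ``2 R / c`` in seconds for a range in meters."""
    distance = np.asarray(distance, dtype=float)
    if np.any(distance < 0):
        raise InvalidInputError("distance must be non-negative")
    tof = 2.0 * distance / SPEED_OF_LIGHT
    return float(tof) if tof.ndim == 0 else tof


@dataclass(frozen=True)
class PulseSpec:
    """Transmit pulse: Gaussian-modulated cosine.

    Defaults match a low-band X4-class sensor: 7.29 GHz center, 1.4 GHz
    bandwidth (-10 dB definition), receiver sampling at 23.328 GS/s.  One
    fast-time sample per range bin gives a bin spacing of
    ``c / (2 * fast_time_rate)`` ~ 6.4 mm.
    """

    center_frequency: float = 7.29e9
    bandwidth: float = 1.4e9
    fast_time_rate: float = 23.328e9

    def __post_init__(self):
        if not (0 < self.bandwidth < 2 * self.center_frequency):
            raise InvalidConfigError("bandwidth must satisfy 0 < B < 2*f_c")
        if not self.fast_time_rate > 2 * (self.center_frequency + self.bandwidth / 2):
            raise InvalidConfigError("fast_time_rate violates Nyquist for the pulse band")

    @property
    def envelope_sigma(self) -> float:
        """Gaussian envelope time constant (s) set by the -10 dB spectral width."""
        sigma_f = self.bandwidth / (2.0 * math.sqrt(math.log(10.0)))
        return 1.0 / (2.0 * math.pi * sigma_f)

    @property
    def range_bin_spacing(self) -> float:
        return SPEED_OF_LIGHT / (2.0 * self.fast_time_rate)

    def waveform(self, tau) -> np.ndarray:
        """Pulse value at delay ``tau`` (s); peak magnitude 1 at ``tau = 0``."""
        tau = np.asarray(tau, dtype=float)
        return np.exp(-(tau**2) / (2.0 * self.envelope_sigma**2)) * np.cos(
            2.0 * math.pi * self.center_frequency * tau
        )


def synthesize_pulse(spec: PulseSpec, tau_grid: np.ndarray) -> np.ndarray:
    """Evaluate the pulse on a uniform delay grid.

    The grid must be uniformly spaced at the pulse's fast-time rate (within a
    small tolerance); a grid too coarse to satisfy Nyquist for the pulse band
    raises :class:`InvalidConfigError`.
    """
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size >= 2:
        steps = np.diff(tau_grid)
        dt = steps[0]
        if dt <= 0 or not np.allclose(steps, dt, rtol=1e-9):
            raise InvalidConfigError("tau_grid must be uniformly increasing")
        if 1.0 / dt < 2 * (spec.center_frequency + spec.bandwidth / 2):
            raise InvalidConfigError("tau_grid sampling rate violates Nyquist for the pulse")
    return spec.waveform(tau_grid)


@dataclass(frozen=True)
class ChestMotion:
    """Kinematic chest-displacement parameters (meters, Hz, radians)."""

    d0: float = 1.0
    m_b: float = 0.0
    f_b: float = 0.0
    m_h: float = 0.0
    f_h: float = 0.0
    drift_amp: float = 0.0
    drift_freq: float = 0.0
    phi_b: float = 0.0
    phi_h: float = 0.0
    phi_d: float = 0.0

    def __post_init__(self):
        if not self.d0 > 0:
            raise InvalidInputError("d0 must be > 0")
        if min(self.m_b, self.m_h, self.drift_amp) < 0:
            raise InvalidInputError("displacement amplitudes must be >= 0")
        if min(self.f_b, self.f_h, self.drift_freq) < 0:
            raise InvalidInputError("frequencies must be >= 0")
        if self.m_b + self.m_h + self.drift_amp > 0.1 * self.d0:
            raise InvalidInputError("total displacement must be small compared with d0")


def chest_displacement(motion: ChestMotion, t) -> np.ndarray:
    """Chest-wall distance d(t) in meters at time(s) ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    two_pi = 2.0 * math.pi
    d = (
        motion.d0
        + motion.m_b * np.sin(two_pi * motion.f_b * t + motion.phi_b)
        + motion.m_h * np.sin(two_pi * motion.f_h * t + motion.phi_h)
        + motion.drift_amp * np.sin(two_pi * motion.drift_freq * t + motion.phi_d)
    )
    return float(d) if d.ndim == 0 else d


@dataclass(frozen=True)
class SceneSpec:
    """One simulated monitoring scene.

    ``multipath`` lists static reflectors as ``(amplitude, delay_s)`` pairs;
    ``target_amplitude`` is the echo strength of the subject; ``noise_sigma``
    is the standard deviation of additive white Gaussian receiver noise per
    sample.  ``range_window`` (meters) must contain the nominal range ``d0``.
    """

    motion: ChestMotion = field(default_factory=ChestMotion)
    target_amplitude: float = 1.0
    multipath: tuple = ()
    noise_sigma: float = 0.0
    duration: float = 20.0
    slow_time_rate: float = 20.0
    range_window: tuple[float, float] = (0.2, 5.0)
    random_seed: int = 0
    pulse: PulseSpec = field(default_factory=PulseSpec)

    def __post_init__(self):
        if not self.duration > 0:
            raise InvalidConfigError("duration must be > 0")
        if not self.slow_time_rate > 0:
            raise InvalidConfigError("slow_time_rate must be > 0")
        # keep heartbeats (plus some margin for harmonic content) below Nyquist
        if self.slow_time_rate <= 2 * (self.motion.f_h + 0.5):
            raise InvalidConfigError("slow_time_rate too low for the configured heartbeat rate")
        lo, hi = self.range_window
        if not lo < hi:
            raise InvalidConfigError("range_window must be a non-empty interval")
        if not (lo <= self.motion.d0 <= hi):
            raise InvalidConfigError("range_window must contain the nominal range d0")
        if self.noise_sigma < 0 or self.target_amplitude < 0:
            raise InvalidConfigError("noise_sigma and target_amplitude must be >= 0")


def synthesize_cube(scene: SceneSpec) -> RadarCube:
    """Render a scene to a raw radar cube.

    Deterministic for a fixed ``scene.random_seed``; the seed and the motion
    parameters are recorded in the cube's provenance.
    """
    spec = scene.pulse
    dr = spec.range_bin_spacing
    lo, hi = scene.range_window
    n_bins = int(math.floor((hi - lo) / dr)) + 1
    n_frames = int(round(scene.duration * scene.slow_time_rate))
    if n_frames < 2:
        raise InvalidConfigError("scene too short: fewer than 2 frames")

    ranges = lo + dr * np.arange(n_bins)
    tau_x = time_of_flight(ranges)  # (X,)
    t = np.arange(n_frames) / scene.slow_time_rate

    static = np.zeros(n_bins)
    for amp, delay in scene.multipath:
        static += amp * spec.waveform(tau_x - delay)

    tau_d = time_of_flight(chest_displacement(scene.motion, t))  # (N,)
    dynamic = scene.target_amplitude * spec.waveform(tau_x[:, None] - tau_d[None, :])

    rng = np.random.default_rng(scene.random_seed)
    data = static[:, None] + dynamic
    if scene.noise_sigma > 0:
        data = data + rng.normal(0.0, scene.noise_sigma, size=data.shape)

    return RadarCube(
        amplitudes=data,
        range_bin_spacing=dr,
        slow_time_rate=scene.slow_time_rate,
        start_range=lo,
        stage="raw",
        provenance={
            "seed": int(scene.random_seed),
            "motion": asdict(scene.motion),
            "target_amplitude": float(scene.target_amplitude),
            "noise_sigma": float(scene.noise_sigma),
            "duration": float(scene.duration),
        },
    )


#: default static reflectors: a near wall and a far furniture echo
DEFAULT_MULTIPATH = ((0.6, time_of_flight(0.35)), (0.4, time_of_flight(2.3)))

#: default receiver noise level relative to a unit target echo
DEFAULT_NOISE_SIGMA = 0.02


def _draw_motion(profile: SpeciesProfile, rng: np.random.Generator, d0: float) -> ChestMotion:
    f_b = rng.uniform(*profile.resp_freq_range)
    f_h = rng.uniform(*profile.heart_freq_range)
    m_b = rng.uniform(*profile.resp_amp_range)
    m_h = rng.uniform(*profile.heart_amp_range)
    # When the two amplitude intervals overlap the draw alone cannot express
    # which component dominates; orient the pair by the anatomical expectation
    # encoded in the LHWR link (pets, ratio <= 1, present heartbeat-dominant
    # chests; ratio > 1 means respiration-dominant).  Disjoint intervals
    # already encode the dominance and are left as drawn.
    r_lo, r_hi = profile.resp_amp_range
    h_lo, h_hi = profile.heart_amp_range
    if max(r_lo, h_lo) < min(r_hi, h_hi):
        if amplitude_ratio_from_lhwr(profile.lhwr) <= 1.0:
            if m_b > m_h:
                m_b, m_h = m_h, m_b
        elif m_h > m_b:
            m_b, m_h = m_h, m_b
    drift_freq = rng.uniform(0.06, 0.14) if profile.body_drift_amp > 0 else 0.0
    phases = rng.uniform(0.0, 2.0 * math.pi, size=3)
    return ChestMotion(
        d0=d0, m_b=m_b, f_b=f_b, m_h=m_h, f_h=f_h,
        drift_amp=profile.body_drift_amp, drift_freq=drift_freq,
        phi_b=phases[0], phi_h=phases[1], phi_d=phases[2],
    )


def synthesize_subject(
    species: str,
    overrides: dict | None = None,
    seed: int = 0,
    profiles: dict[str, SpeciesProfile] | None = None,
) -> RadarCube:
    """Simulate one subject of ``species`` at the default 1 m monitoring range.

    Motion parameters are drawn from the species preset with the given seed.
    ``overrides`` may replace any drawn :class:`ChestMotion` field or any
    :class:`SceneSpec` field (e.g. ``{"f_b": 0.35, "noise_sigma": 0}``) after
    the draw.  The drawn parameters end up in the cube's provenance.
    """
    profiles = profiles if profiles is not None else default_profiles()
    if species not in profiles:
        raise InvalidInputError(f"unknown species {species!r}; expected one of {sorted(profiles)}")
    profile = profiles[species]
    overrides = dict(overrides or {})

    rng = np.random.default_rng(seed)
    d0 = float(overrides.pop("d0", 1.0))
    motion = _draw_motion(profile, rng, d0)

    motion_fields = set(asdict(motion))
    motion_overrides = {k: overrides.pop(k) for k in list(overrides) if k in motion_fields}
    if motion_overrides:
        motion = ChestMotion(**{**asdict(motion), **motion_overrides})

    scene_kwargs = {
        "motion": motion,
        "target_amplitude": profile.echo_amplitude,
        "multipath": DEFAULT_MULTIPATH,
        "noise_sigma": DEFAULT_NOISE_SIGMA,
        "random_seed": int(rng.integers(2**31)),
    }
    scene_kwargs.update(overrides)
    cube = synthesize_cube(SceneSpec(**scene_kwargs))
    cube.provenance["species"] = species
    cube.provenance["subject_seed"] = int(seed)
    return cube
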