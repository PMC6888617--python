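"""Slow-time clutter removal and low-pass filtering.

Static clutter (walls, furniture) appears as a constant offset plus slow
baseline drift along each range bin's slow-time signal; it is removed by
subtracting a sliding mean along slow time.  A linear-phase FIR low-pass at
5 Hz then discards receiver noise above the physiological band while keeping
respiration and heartbeat (and their relevant harmonics) intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, firwin, lfilter

from .cube import RadarCube
from .errors import InvalidConfigError


@dataclass(frozen=True)
class PreprocessConfig:
    """Clutter-removal and filter settings.

    ``window_q`` is the sliding-mean window length in frames; ``None`` means
    the full record (global per-bin mean), which is adequate for records of
    about 20 s.  ``fir_order`` is the FIR filter order (taps = order + 1),
    even so the linear-phase group delay is an integer number of frames.
    ``zero_phase`` compensates that delay so spectral peaks are not shifted
    in time; turn it off for a causal (real-time) filter.
    """

    window_q: int | None = None
    cutoff: float = 5.0
    fir_order: int = 100
    zero_phase: bool = True

    def __post_init__(self):
        if self.window_q is not None and self.window_q < 1:
            raise InvalidConfigError("window_q must be >= 1")
        if not self.cutoff > 0:
            raise InvalidConfigError("cutoff must be > 0")
        if self.fir_order < 8 or self.fir_order % 2:
            raise InvalidConfigError("fir_order must be even and >= 8")


def sliding_mean(data: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding mean of length ``window`` along the last axis.

    Interior frames get a window centered on them; near the record edges the
    window is shifted inward so it always spans exactly ``window`` frames
    (no padding, no shortened means).  ``window = N`` therefore reduces to
    the global mean for every frame.  For even windows the extra frame sits
    on the trailing side.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[-1]
    if not 1 <= window <= n:
        raise InvalidConfigError(f"window must be in [1, {n}], got {window}")
    left = (window - 1) // 2
    csum = np.concatenate(
        [np.zeros(data.shape[:-1] + (1,)), np.cumsum(data, axis=-1)], axis=-1
    )
    lo = np.clip(np.arange(n) - left, 0, n - window)
    hi = lo + window
    return (csum[..., hi] - csum[..., lo]) / window


def remove_dc(cube: RadarCube, window_q: int | None = None) -> RadarCube:
    """Subtract the slow-time sliding mean from every range bin.

    ``window_q = N`` (the default) degenerates to subtracting each bin's
    global mean.  Returns a new cube tagged ``dc_removed``.
    """
    n = cube.n_frames
    q = n if window_q is None else int(window_q)
    if not 1 <= q <= n:
        raise InvalidConfigError(f"window_q must be in [1, {n}], got {q}")
    cleaned = cube.amplitudes - sliding_mean(cube.amplitudes, q)
    return cube.with_amplitudes(cleaned, stage="dc_removed")


def design_lowpass(cutoff: float, rate: float, fir_order: int = 100) -> np.ndarray:
    """Windowed-sinc (Hamming) linear-phase FIR low-pass taps."""
    if not cutoff < rate / 2:
        raise InvalidConfigError(
            f"cutoff {cutoff} Hz must be below the slow-time Nyquist {rate / 2} Hz"
        )
    return firwin(fir_order + 1, cutoff, fs=rate, window="hamming")


def lowpass(cube: RadarCube, config: PreprocessConfig | None = None) -> RadarCube:
    """Low-pass every range bin along slow time.

    Zero-phase mode applies the filter once on a reflect-padded signal and
    keeps the centered samples, so there is no group delay and no startup
    transient; causal mode uses a plain direct-form filter with its inherent
    ``fir_order / 2`` frame delay.
    """
    config = config or PreprocessConfig()
    taps = design_lowpass(config.cutoff, cube.slow_time_rate, config.fir_order)
    data = cube.amplitudes
    if config.zero_phase:
        half = config.fir_order // 2
        if half >= cube.n_frames:
            raise InvalidConfigError(
                f"record of {cube.n_frames} frames too short for fir_order {config.fir_order}"
            )
        padded = np.pad(data, ((0, 0), (half, half)), mode="reflect")
        filtered = fftconvolve(padded, taps[None, :], mode="valid", axes=1)
    else:
        filtered = lfilter(taps, [1.0], data, axis=1)
    return cube.with_amplitudes(filtered, stage="filtered")


def preprocess(cube: RadarCube, config: PreprocessConfig | None = None) -> RadarCube:
    """Standard preprocessing chain: clutter/DC removal, then low-pass."""
    config = config or PreprocessConfig()
    return lowpass(remove_dc(cube, config.window_q), config)
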