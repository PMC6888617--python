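"""Respiration/heartbeat mode selection, the RHER statistic, and the label.

Humans breathe with millimeter-scale chest excursions while their precordial
heartbeat pulse is an order of magnitude smaller; for dogs, cats and rabbits
the heartbeat component of the radar echo is comparable to or stronger than
breathing.  The respiratory-and-heartbeat energy ratio

    RHER = sum_t u_r(t)^2 / sum_t u_h(t)^2

of the respiration-band mode ``u_r`` and heartbeat-band mode ``u_h`` is
therefore well above 1 for people and at or below 1 for pets; the decision is
taken on log10(RHER) against a configurable threshold (default 0).

Modes are selected by *human* physiological band, not by mode index: a pet's
decomposition can place body-motion drift in the lowest mode (rabbits), so
index-based selection is not species-invariant.  Within a band the
highest-energy mode wins.  If a band contains no mode the case is reported as
indeterminate rather than force-labelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    InvalidConfigError,
    InvalidInputError,
    ModeSelectionError,
    UndefinedFrequencyError,
    UndefinedRatioError,
)
from .vmd import VIMFSet


@dataclass(frozen=True)
class BandConfig:
    """Human physiological bands (Hz) and the log10 RHER decision threshold."""

    resp_band: tuple[float, float] = (0.1, 0.7)
    heart_band: tuple[float, float] = (0.8, 2.5)
    rher_log10_threshold: float = 0.0

    def __post_init__(self):
        for name, (lo, hi) in (("resp_band", self.resp_band), ("heart_band", self.heart_band)):
            if not 0 < lo < hi:
                raise InvalidConfigError(f"{name} must be a positive interval")
        if self.resp_band[1] >= self.heart_band[0]:
            raise InvalidConfigError("resp_band must lie strictly below heart_band")


@dataclass
class ClassificationResult:
    """Outcome of the RHER stage for one target."""

    rher: float
    log10_rher: float
    label: str
    resp_rate: float
    heart_rate: float
    resp_mode_index: int
    heart_mode_index: int


def _band_pick(vimfs: VIMFSet, band: tuple[float, float], band_name: str) -> int:
    lo, hi = band
    candidates = [
        k for k, w in enumerate(vimfs.center_freqs) if lo <= w <= hi
    ]
    if not candidates:
        raise ModeSelectionError(band_name)
    return max(candidates, key=vimfs.mode_energy)


def select_vimfs(
    vimfs: VIMFSet,
    bands: BandConfig | None = None,
    fixed_indices: bool = False,
) -> tuple[int, int]:
    """Indices of the respiration and heartbeat modes.

    Band-based by default (highest-energy mode whose center frequency falls in
    each band, boundaries inclusive).  ``fixed_indices=True`` reproduces the
    legacy convention of taking the first and second modes regardless of
    frequency.
    """
    if fixed_indices:
        if vimfs.n_modes < 2:
            raise ModeSelectionError("heartbeat", "need at least 2 modes for fixed-index selection")
        return 0, 1
    bands = bands or BandConfig()
    return (
        _band_pick(vimfs, bands.resp_band, "respiration"),
        _band_pick(vimfs, bands.heart_band, "heartbeat"),
    )


def rher(u_r: np.ndarray, u_h: np.ndarray) -> float:
    """Time-domain energy ratio of the respiration mode to the heartbeat mode."""
    u_r = np.asarray(u_r, dtype=float)
    u_h = np.asarray(u_h, dtype=float)
    heart_energy = float(np.sum(u_h**2))
    if heart_energy == 0:
        raise UndefinedRatioError("heartbeat mode has zero energy; RHER undefined")
    return float(np.sum(u_r**2)) / heart_energy


def classify_rher(rher_value: float, bands: BandConfig | None = None) -> str:
    """``human`` if log10(RHER) exceeds the threshold, else ``animal``.

    The boundary goes to ``animal`` (fail-safe for monitoring).
    """
    if not rher_value > 0:
        raise InvalidInputError("rher_value must be > 0")
    bands = bands or BandConfig()
    return "human" if np.log10(rher_value) > bands.rher_log10_threshold else "animal"


def spectral_peak_frequency(signal: np.ndarray, rate: float) -> float:
    """Frequency (Hz) of the FFT magnitude peak, quadratically interpolated.

    Raises :class:`UndefinedFrequencyError` for a flat (all-zero) spectrum.
    """
    signal = np.asarray(signal, dtype=float)
    magnitude = np.abs(np.fft.rfft(signal))
    if not np.any(magnitude > 0):
        raise UndefinedFrequencyError("flat spectrum: no peak frequency")
    peak = int(np.argmax(magnitude))
    df = rate / signal.size
    if 0 < peak < magnitude.size - 1:
        left, mid, right = magnitude[peak - 1: peak + 2]
        denom = left - 2 * mid + right
        if denom != 0:
            offset = 0.5 * (left - right) / denom
            return (peak + float(np.clip(offset, -0.5, 0.5))) * df
    return peak * df


def estimate_rates(u_r: np.ndarray, u_h: np.ndarray, rate: float) -> tuple[float, float]:
    """Respiration and heart rates (Hz) from the selected modes' spectral peaks."""
    return (
        spectral_peak_frequency(u_r, rate),
        spectral_peak_frequency(u_h, rate),
    )


def classify_target(vimfs: VIMFSet, bands: BandConfig | None = None) -> ClassificationResult:
    """Full RHER stage on a decomposition: select modes, ratio, label, rates."""
    bands = bands or BandConfig()
    r_idx, h_idx = select_vimfs(vimfs, bands)
    value = rher(vimfs.modes[r_idx], vimfs.modes[h_idx])
    label = classify_rher(value, bands)
    resp_rate, heart_rate = estimate_rates(
        vimfs.modes[r_idx], vimfs.modes[h_idx], vimfs.sample_rate
    )
    return ClassificationResult(
        rher=value,
        log10_rher=float(np.log10(value)),
        label=label,
        resp_rate=resp_rate,
        heart_rate=heart_rate,
        resp_mode_index=r_idx,
        heart_mode_index=h_idx,
    )
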