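"""Target localization and the stage-1 human/animal energy gate.

After clutter removal, only moving scatterers retain slow-time variance, so
summing squared amplitudes along slow time per range bin gives an energy
profile whose maximum locates the subject.  Because pets move their body
surface less than people do (and present a smaller radar cross-section), the
located target's energy, compared against a per-range-segment *human* energy
standard calibrated from known human recordings, provides a cheap first
decision: a target whose energy falls more than a factor ``threshold`` (10 by
default) below the human standard is declared an animal outright; otherwise it
proceeds to the mode-decomposition stage.

Range dependence of echo strength is handled by splitting the detection range
into ``M`` segments of ``I`` bins each and calibrating one human reference
energy per segment.  Bin indices are 0-based internally; segment numbers are
1-based, matching how monitoring reports are read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .cube import RadarCube
from .errors import (
    CalibrationError,
    InvalidConfigError,
    InvalidInputError,
    NoTargetError,
    OutOfRangeError,
)
from .preprocess import PreprocessConfig, preprocess

#: default stage-1 gate: animal if the human standard exceeds the target
#: energy by at least this factor
ENERGY_GATE_THRESHOLD = 10.0


@dataclass
class EnergyProfile:
    """Per-range-bin slow-time energy, with the cube's range geometry."""

    energies: np.ndarray
    range_bin_spacing: float
    start_range: float = 0.0

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float).ravel()
        if self.energies.size == 0:
            raise InvalidInputError("energy profile is empty")
        if np.any(self.energies < 0) or not np.all(np.isfinite(self.energies)):
            raise InvalidInputError("energies must be finite and non-negative")


def energy_indicator(cube: RadarCube) -> EnergyProfile:
    """Slow-time energy ``E_x = sum_n s_x(n)^2`` for every range bin.

    The cube must have been clutter-removed first (otherwise static multipath
    dominates every bin and the profile is meaningless).
    """
    if cube.stage == "raw":
        raise InvalidInputError("energy indicator requires a DC-removed cube, got stage 'raw'")
    return EnergyProfile(
        energies=np.sum(cube.amplitudes**2, axis=1),
        range_bin_spacing=cube.range_bin_spacing,
        start_range=cube.start_range,
    )


def locate_target(profile: EnergyProfile) -> tuple[int, float]:
    """Index and distance (m) of the maximum-energy range bin.

    Ties break toward the smaller index.  An all-zero profile means there is
    nothing moving in the scene and raises :class:`NoTargetError`.
    """
    if not np.any(profile.energies > 0):
        raise NoTargetError("all-zero energy profile: no moving target in view")
    index = int(np.argmax(profile.energies))
    return index, profile.start_range + index * profile.range_bin_spacing


@dataclass
class EnergyStandard:
    """Segment-wise human reference energies.

    ``reference_energies[m-1]`` is the calibrated human energy for segment
    ``m`` (1-based); ``inherited[m-1]`` flags segments that had no calibration
    recordings and borrowed the nearest calibrated segment's value.
    """

    n_segments: int
    segment_length: int
    reference_energies: np.ndarray
    inherited: tuple = ()
    range_bin_spacing: float = 1.0
    start_range: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_segments < 1 or self.segment_length < 1:
            raise InvalidConfigError("need n_segments >= 1 and segment_length >= 1")
        self.reference_energies = np.asarray(self.reference_energies, dtype=float).ravel()
        if self.reference_energies.size != self.n_segments:
            raise InvalidConfigError("one reference energy per segment required")
        if not np.all(self.reference_energies > 0):
            raise InvalidConfigError("reference energies must be > 0")
        if not self.inherited:
            self.inherited = (False,) * self.n_segments

    def to_yaml(self, path) -> None:
        payload = {
            "n_segments": int(self.n_segments),
            "segment_length": int(self.segment_length),
            "reference_energies": [float(v) for v in self.reference_energies],
            "inherited": [bool(v) for v in self.inherited],
            "range_bin_spacing": float(self.range_bin_spacing),
            "start_range": float(self.start_range),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EnergyStandard":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["inherited"] = tuple(payload.get("inherited") or ())
        return cls(**payload)


def segment_of(bin_index: int, standard: EnergyStandard) -> int:
    """Segment number ``m = floor(i / I) + 1`` for a 0-based bin index."""
    limit = standard.n_segments * standard.segment_length
    if not 0 <= bin_index < limit:
        raise OutOfRangeError(
            f"bin {bin_index} outside the calibrated range [0, {limit})"
        )
    return bin_index // standard.segment_length + 1


def alpha_e(target_energy: float, standard: EnergyStandard, bin_index: int) -> float:
    """Energy gate statistic: human reference energy over target energy."""
    if not target_energy > 0:
        raise NoTargetError("target energy must be > 0 to form an energy ratio")
    m = segment_of(bin_index, standard)
    return float(standard.reference_energies[m - 1] / target_energy)


def initial_decision(alpha: float, threshold: float = ENERGY_GATE_THRESHOLD) -> str:
    """Stage-1 label: ``human-candidate`` if the target is within a factor
    ``threshold`` of human energy (strictly below), else ``animal``.

    The boundary goes to ``animal``: for monitoring it is safer to reject a
    pet than to accept one as human.
    """
    return "human-candidate" if alpha < threshold else "animal"


def calibrate_standard(
    human_cubes: list[RadarCube],
    n_segments: int,
    preprocess_config: PreprocessConfig | None = None,
) -> EnergyStandard:
    """Build the human energy standard from human recordings.

    Each cube is preprocessed (unless already filtered), its target located,
    and its target energy assigned to the range segment containing the target
    bin; the per-segment reference is the mean of its samples.  Segments with
    no human sample inherit the nearest calibrated segment's value and are
    flagged.  All cubes must share range geometry.
    """
    if not human_cubes:
        raise CalibrationError("no calibration recordings supplied")
    geom = (human_cubes[0].n_bins, human_cubes[0].range_bin_spacing, human_cubes[0].start_range)
    for cube in human_cubes[1:]:
        if (cube.n_bins, cube.range_bin_spacing, cube.start_range) != geom:
            raise InvalidInputError("calibration cubes must share range geometry")

    n_bins = geom[0]
    segment_length = math.ceil(n_bins / n_segments)
    samples: dict[int, list[float]] = {m: [] for m in range(1, n_segments + 1)}
    for cube in human_cubes:
        if cube.stage != "filtered":
            cube = preprocess(cube, preprocess_config)
        profile = energy_indicator(cube)
        index, _ = locate_target(profile)
        m = index // segment_length + 1
        samples[m].append(float(profile.energies[index]))

    references = np.full(n_segments, np.nan)
    for m, values in samples.items():
        if values:
            references[m - 1] = np.mean(values)
    calibrated = np.where(np.isfinite(references))[0]
    if calibrated.size == 0:
        raise CalibrationError("no usable calibration recordings")
    inherited = []
    for m in range(n_segments):
        if np.isfinite(references[m]):
            inherited.append(False)
        else:
            nearest = calibrated[np.argmin(np.abs(calibrated - m))]
            references[m] = references[nearest]
            inherited.append(True)

    return EnergyStandard(
        n_segments=n_segments,
        segment_length=segment_length,
        reference_energies=references,
        inherited=tuple(inherited),
        range_bin_spacing=geom[1],
        start_range=geom[2],
        metadata={"n_recordings": len(human_cubes)},
    )
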