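"""The radar data cube: a fast-time x slow-time amplitude matrix with geometry metadata.

An IR-UWB vital-sign radar stores its echo stream as a matrix ``S(x, n)`` of
``X`` range bins by ``N`` frames.  Rows (fast time) map to round-trip range,
columns (slow time) to observation time; chest motion of a subject shows up as
amplitude modulation along slow time at the subject's range bin.

Cubes travel through the pipeline as :class:`RadarCube` instances and are
stored on disk as a delimited text matrix plus a YAML metadata sidecar with the
same basename (``foo.csv`` + ``foo.meta.yaml``), so recordings remain
inspectable with standard tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import FormatError, InvalidConfigError, InvalidInputError

#: processing stages a cube can be tagged with, in pipeline order
STAGES = ("raw", "dc_removed", "filtered")

_REQUIRED_METADATA = ("range_bin_spacing", "slow_time_rate", "start_range", "stage")


@dataclass
class RadarCube:
    """Fast-time x slow-time echo amplitude matrix with sampling metadata.

    Parameters
    ----------
    amplitudes
        ``(X, N)`` float array; rows are range bins, columns are frames.
    range_bin_spacing
        Distance between consecutive range bins, meters.
    slow_time_rate
        Frame rate along slow time, Hz.
    start_range
        Distance of range bin 0 from the antenna, meters.  Bin ``k`` covers the
        half-open interval ``[start_range + k*dr, start_range + (k+1)*dr)``.
    stage
        Processing stage tag, one of ``raw``, ``dc_removed``, ``filtered``.
    provenance
        Free-form metadata (simulation seed, drawn motion parameters, ...).
    """

    amplitudes: np.ndarray
    range_bin_spacing: float
    slow_time_rate: float
    start_range: float = 0.0
    stage: str = "raw"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.amplitudes = np.atleast_2d(np.asarray(self.amplitudes, dtype=float))
        if self.amplitudes.ndim != 2:
            raise InvalidInputError("amplitudes must be a 2-D matrix")
        x, n = self.amplitudes.shape
        if x < 1 or n < 2:
            raise InvalidInputError(
                f"cube needs at least 1 range bin and 2 frames, got {x}x{n}"
            )
        if not np.all(np.isfinite(self.amplitudes)):
            raise InvalidInputError("cube contains non-finite amplitudes")
        if not (self.range_bin_spacing > 0 and self.slow_time_rate > 0):
            raise InvalidConfigError("range_bin_spacing and slow_time_rate must be > 0")
        if self.stage not in STAGES:
            raise InvalidConfigError(f"unknown stage {self.stage!r}, expected one of {STAGES}")

    # -- geometry helpers -------------------------------------------------

    @property
    def n_bins(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def n_frames(self) -> int:
        return self.amplitudes.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_frames / self.slow_time_rate

    def bin_distance(self, index: int) -> float:
        """Distance (m) of the leading edge of range bin ``index``."""
        return self.start_range + index * self.range_bin_spacing

    def bin_of(self, distance: float) -> int:
        """Range-bin index whose half-open interval contains ``distance``."""
        return int(np.floor((distance - self.start_range) / self.range_bin_spacing))

    def slow_time(self) -> np.ndarray:
        """Slow-time axis in seconds, one entry per frame."""
        return np.arange(self.n_frames) / self.slow_time_rate

    def with_amplitudes(self, amplitudes: np.ndarray, stage: str) -> "RadarCube":
        """New cube sharing this cube's geometry, with updated data and stage tag."""
        return replace(self, amplitudes=amplitudes, stage=stage,
                       provenance=dict(self.provenance))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.yaml")


def _to_builtin(value):
    """Recursively convert numpy scalars/arrays so YAML can represent them."""
    if isinstance(value, dict):
        return {k: _to_builtin(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_to_builtin(v) for v in value]
    if isinstance(value, np.integer):
        return int(value)
    if isinstance(value, np.floating):
        return float(value)
    if isinstance(value, np.ndarray):
        return [_to_builtin(v) for v in value.tolist()]
    return value


def write_radar_cube(cube: RadarCube, path: str | Path) -> Path:
    """Write a cube as a delimited text matrix plus a YAML metadata sidecar.

    Values are stored at full double precision so write/read round-trips are
    lossless.  Returns the path of the matrix file.
    """
    path = Path(path)
    np.savetxt(path, cube.amplitudes, fmt="%.17e", delimiter=",")
    meta = {
        "range_bin_spacing": float(cube.range_bin_spacing),
        "slow_time_rate": float(cube.slow_time_rate),
        "start_range": float(cube.start_range),
        "stage": cube.stage,
        "provenance": _to_builtin(cube.provenance),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_radar_cube(path: str | Path) -> RadarCube:
    """Read a cube written by :func:`write_radar_cube`.

    Raises :class:`FormatError` naming the offending field or row for missing
    metadata, non-rectangular matrices, or non-finite entries.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise FormatError(f"matrix file not found: {path}")
    if not sidecar.exists():
        raise FormatError(f"metadata sidecar not found: {sidecar}")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh) or {}
    for key in _REQUIRED_METADATA:
        if key not in meta:
            raise FormatError(f"metadata sidecar missing required field '{key}'")
    try:
        amplitudes = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"matrix file {path} is not rectangular: {exc}") from exc
    if not np.all(np.isfinite(amplitudes)):
        bad = np.argwhere(~np.isfinite(amplitudes))[0]
        raise FormatError(f"non-finite amplitude at row {bad[0]}, column {bad[1]}")
    return RadarCube(
        amplitudes=amplitudes,
        range_bin_spacing=float(meta["range_bin_spacing"]),
        slow_time_rate=float(meta["slow_time_rate"]),
        start_range=float(meta["start_range"]),
        stage=str(meta["stage"]),
        provenance=meta.get("provenance") or {},
    )
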