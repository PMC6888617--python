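"""Species physiological reference data.

Why anatomy matters here: the lungs drive the respiratory chest excursion and
the heart drives the (much smaller, in humans) precordial pulse.  The
lung-to-heart weight ratio (LHWR) of an adult human is about 3, whereas for
dogs, cats and rabbits it is 1.1-1.5, and in small quadrupeds the heart also
sits close behind the front ribs with little overlying tissue.  A radar
therefore sees human chest motion dominated by respiration, while for common
pets the heartbeat component is comparable to or stronger than breathing.
That asymmetry is what the downstream respiration/heartbeat energy-ratio
classifier exploits; this module holds the organ-weight table behind it and
the species presets that parameterize the echo simulator.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources

from .errors import InvalidInputError

SPECIES = ("human", "dog", "cat", "rabbit")

#: analyzable band of the pipeline: slow-time content above the low-pass
#: cutoff is discarded, so preset frequencies must stay below this (Hz).
ANALYSIS_BAND_MAX_HZ = 5.0


@dataclass(frozen=True)
class OrganWeights:
    """Lung and heart mass of one subject class, in grams."""

    lungs_mass: float
    heart_mass: float

    def __post_init__(self):
        for name, value in (("lungs_mass", self.lungs_mass), ("heart_mass", self.heart_mass)):
            if not (math.isfinite(value) and value > 0):
                raise InvalidInputError(f"{name} must be strictly positive and finite, got {value}")


def lhwr(weights: OrganWeights) -> float:
    """Lung-to-heart weight ratio, dimensionless.

    Full precision is returned; round to two decimals for display (the
    convention used in published organ-weight tables).
    """
    return weights.lungs_mass / weights.heart_mass


def amplitude_ratio_from_lhwr(value: float) -> float:
    """Monotone link from LHWR to an expected chest-displacement ratio m_b/m_h.

    No quantitative anatomical law connects organ-weight ratio to the
    displacement amplitudes a radar observes; this mapping is an explicit
    modelling choice used only to orient the species presets (respiration- vs
    heartbeat-dominant).  It is a power law (affine in log-log space) anchored
    so that LHWR 3 -> ratio 10 (human regime, respiration dominant) and
    LHWR 1.5 -> ratio 1 (upper edge of the pet regime, where heartbeat is
    comparable to or stronger than breathing); every tabulated pet LHWR
    (1.12-1.50) then maps to the <= 1 regime.
    """
    if not (math.isfinite(value) and value > 0):
        raise InvalidInputError(f"lhwr must be strictly positive and finite, got {value}")
    slope = math.log(10.0) / math.log(3.0 / 1.5)
    return (value / 1.5) ** slope


@dataclass(frozen=True)
class SpeciesProfile:
    """Simulation preset for one species.

    Frequency intervals are Hz; amplitude intervals are meters of chest-wall
    displacement.  ``body_drift_amp`` is the amplitude of slow whole-body sway
    (nonzero for rabbits, which fidget even when calm).  ``echo_amplitude`` is
    the relative echo strength (radar cross-section scale) of the body.
    """

    species_name: str
    resp_freq_range: tuple[float, float]
    heart_freq_range: tuple[float, float]
    resp_amp_range: tuple[float, float]
    heart_amp_range: tuple[float, float]
    body_drift_amp: float
    lhwr: float
    echo_amplitude: float = 1.0

    def __post_init__(self):
        for name in ("resp_freq_range", "heart_freq_range", "resp_amp_range", "heart_amp_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise InvalidInputError(f"{self.species_name}: {name} must satisfy 0 < lower <= upper")
        if self.species_name != "rabbit" and self.heart_freq_range[0] < self.resp_freq_range[1]:
            raise InvalidInputError(
                f"{self.species_name}: heart frequency range must lie above respiration range"
            )
        if self.heart_freq_range[1] > ANALYSIS_BAND_MAX_HZ:
            raise InvalidInputError(
                f"{self.species_name}: frequencies must stay within the {ANALYSIS_BAND_MAX_HZ} Hz analysis band"
            )
        if not self.lhwr > 0:
            raise InvalidInputError(f"{self.species_name}: lhwr must be > 0")
        if self.body_drift_amp < 0 or self.echo_amplitude <= 0:
            raise InvalidInputError(f"{self.species_name}: invalid drift or echo amplitude")


def load_organ_weight_table() -> list[dict]:
    """The packaged organ-weight table.

    Rows have keys ``species``, ``sex``, ``body_kg``, ``lungs_g``, ``heart_g``
    with numeric fields converted to float.
    """
    rows = []
    with resources.files("uwbvitals.data").joinpath("organ_weights.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                {
                    "species": row["species"],
                    "sex": row["sex"],
                    "body_kg": float(row["body_kg"]),
                    "lungs_g": float(row["lungs_g"]),
                    "heart_g": float(row["heart_g"]),
                }
            )
    return rows


def _table_lhwr(species: str, sex: str) -> float:
    for row in load_organ_weight_table():
        if row["species"] == species and row["sex"] == sex:
            return lhwr(OrganWeights(row["lungs_g"], row["heart_g"]))
    raise InvalidInputError(f"no organ-weight entry for {species}/{sex}")


def default_profiles() -> dict[str, SpeciesProfile]:
    """Built-in presets for the four monitored species.

    Frequency ranges bracket the rates observed on real subjects at rest
    (human 0.35/1.35 Hz, dog 0.3/1.65 Hz, cat 0.3/1.85 Hz; rabbits breathe
    well above the human range).  Amplitude ranges encode the anatomical
    asymmetry discussed in the module docstring: human respiration displacement
    is an order of magnitude above the heartbeat pulse, while for pets the two
    are comparable.  LHWR values are computed from the packaged table (male
    preset for the sexed rows).
    """
    mm = 1e-3
    return {
        "human": SpeciesProfile(
            species_name="human",
            resp_freq_range=(0.2, 0.5),
            heart_freq_range=(1.0, 1.7),
            resp_amp_range=(2.0 * mm, 6.0 * mm),
            heart_amp_range=(0.1 * mm, 0.4 * mm),
            body_drift_amp=0.0,
            lhwr=_table_lhwr("human", "M"),
            echo_amplitude=1.0,
        ),
        "dog": SpeciesProfile(
            species_name="dog",
            resp_freq_range=(0.2, 0.45),
            heart_freq_range=(1.3, 2.0),
            # 10-22 kg dogs are torso-scale targets: chest excursions of a few
            # millimeters, with the heartbeat felt as strongly as breathing.
            resp_amp_range=(1.0 * mm, 3.0 * mm),
            heart_amp_range=(1.0 * mm, 3.0 * mm),
            body_drift_amp=0.0,
            lhwr=_table_lhwr("dog", "M"),
            echo_amplitude=1.0,
        ),
        "cat": SpeciesProfile(
            species_name="cat",
            resp_freq_range=(0.2, 0.5),
            heart_freq_range=(1.6, 2.4),
            resp_amp_range=(0.5 * mm, 2.0 * mm),
            heart_amp_range=(0.5 * mm, 2.0 * mm),
            body_drift_amp=0.0,
            lhwr=_table_lhwr("cat", "MF"),
            echo_amplitude=0.5,
        ),
        "rabbit": SpeciesProfile(
            species_name="rabbit",
            resp_freq_range=(0.8, 1.4),
            heart_freq_range=(2.6, 4.2),
            resp_amp_range=(0.3 * mm, 1.0 * mm),
            heart_amp_range=(0.1 * mm, 0.3 * mm),
            body_drift_amp=1.0 * mm,
            lhwr=_table_lhwr("rabbit", "MF"),
            echo_amplitude=0.5,
        ),
    }
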