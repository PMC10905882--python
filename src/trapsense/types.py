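"""Core domain types for the optical wingbeat-sensor surveillance pipeline.

An insect transiting the sensing zone of the trap-mounted optical sensor
modulates a light beam with its wing flap; each transit is stored as a short
mono waveform (a :class:`Recording`) together with capture metadata.  The
system targets four classes — *Aedes* female/male and *Culex* female/male —
and treats every other insect as non-target.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ClassLabel",
    "TARGET_CLASSES",
    "Validity",
    "WingbeatParams",
    "Recording",
    "CollectionCycle",
    "FieldScenario",
    "DetectorNoise",
]


class ClassLabel(str, enum.Enum):
    """Genus × sex classes plus the catch-all non-target class.

    The first four members are the "target" mosquito classes the sensor is
    meant to detect and classify; ``NON_TARGET`` covers every other insect
    entering the trap (other culicid genera, chironomids, phlebotomines, ...).
    """

    AEDES_F = "AEDES_F"
    AEDES_M = "AEDES_M"
    CULEX_F = "CULEX_F"
    CULEX_M = "CULEX_M"
    NON_TARGET = "NON_TARGET"

    @property
    def is_target(self) -> bool:
        return self is not ClassLabel.NON_TARGET

    @property
    def genus(self) -> Optional[str]:
        if self is ClassLabel.NON_TARGET:
            return None
        return "Aedes" if self.value.startswith("AEDES") else "Culex"


#: The four target classes, in canonical (and tie-breaking) order.
TARGET_CLASSES: tuple[ClassLabel, ...] = (
    ClassLabel.AEDES_F,
    ClassLabel.AEDES_M,
    ClassLabel.CULEX_F,
    ClassLabel.CULEX_M,
)


class Validity(str, enum.Enum):
    """Ground-truth morphology of a synthetic recording.

    ``DOUBLE_FLIGHT`` — two insects transited the zone with overlapping
    envelopes; ``WALL_HIT`` — the insect struck the flight-tube wall, leaving
    a truncated, clipped envelope.  Both are rejected during data cleaning.
    """

    VALID = "VALID"
    DOUBLE_FLIGHT = "DOUBLE_FLIGHT"
    WALL_HIT = "WALL_HIT"


@dataclass(frozen=True)
class WingbeatParams:
    """Harmonic-series parameters of one class's flight tone.

    Parameters
    ----------
    f0_base:
        Fundamental wingbeat frequency (Hz) at the 28 °C reference
        temperature.
    temp_coeff:
        Fractional change of f0 per °C away from 28 °C.  Flight tone rises
        with ambient temperature, so the default is positive.
    n_harmonics:
        Number of harmonics synthesized (fundamental included).
    harmonic_decay:
        Amplitude ratio between successive harmonics, in (0, 1].
    f0_sd:
        Between-individual standard deviation of the fundamental (Hz).
    """

    f0_base: float
    temp_coeff: float = 0.008
    n_harmonics: int = 4
    harmonic_decay: float = 0.55
    f0_sd: float = 40.0

    def __post_init__(self) -> None:
        if self.f0_base <= 0:
            raise ValueError("f0_base must be positive")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if not (0 < self.harmonic_decay <= 1):
            raise ValueError("harmonic_decay must be in (0, 1]")
        if self.f0_sd < 0:
            raise ValueError("f0_sd must be non-negative")

    def f0_at(self, temperature: float, offset: float = 0.0) -> float:
        """Expected fundamental for an individual at ``temperature`` °C."""
        return (self.f0_base + offset) * (1.0 + self.temp_coeff * (temperature - 28.0))


@dataclass
class Recording:
    """One insect transit: waveform plus capture metadata.

    ``true_label``, ``validity`` and ``f0_true`` are simulator ground truth;
    they are absent (``None``) for real sensor data.
    """

    samples: np.ndarray
    sample_rate: float
    timestamp: Optional[datetime] = None
    temperature: Optional[float] = None
    humidity: Optional[float] = None
    true_label: Optional[ClassLabel] = None
    validity: Optional[Validity] = None
    f0_true: Optional[float] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class CollectionCycle:
    """Interval between placing and collecting the catch bag (24–72 h)."""

    cycle_id: str
    start: datetime
    end: datetime

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"cycle {self.cycle_id}: end must follow start")

    def contains(self, t: datetime) -> bool:
        """Half-open membership: start <= t < end."""
        return self.start <= t < self.end


@dataclass
class FieldScenario:
    """Stochastic description of one field trial.

    ``class_intensities`` are expected captures per 24 h of cycle duration for
    each class (Poisson); ``diel_profile`` maps a genus (or ``NON_TARGET``) to
    24 non-negative hourly weights summing to 1; ``seasonal_trend`` maps month
    number to a multiplier applied to all intensities.
    """

    cycles: Sequence[CollectionCycle]
    class_intensities: dict[ClassLabel, float]
    diel_profile: dict[str, np.ndarray]
    seasonal_trend: dict[int, float] = field(default_factory=dict)
    excluded_cycles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ordered = sorted(self.cycles, key=lambda c: c.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(f"cycles {a.cycle_id} and {b.cycle_id} overlap")
        self.cycles = list(ordered)
        for label, lam in self.class_intensities.items():
            if lam < 0:
                raise ValueError(f"negative intensity for {label}")
        norm = {}
        for key, w in self.diel_profile.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (24,) or (w < 0).any():
                raise ValueError("diel profile must be 24 non-negative weights")
            if w.sum() <= 0:
                raise ValueError("diel profile must have positive mass")
            norm[key] = w / w.sum()
        self.diel_profile = norm


@dataclass(frozen=True)
class DetectorNoise:
    """Event-level misclassification rates of an idealized sensor.

    Used to derive synthetic per-cycle sensor counts with known error,
    independent of the waveform pipeline: a target event is missed (called
    non-target) with probability ``miss_rate``; a non-target event is called
    target with probability ``false_alarm_rate`` and then assigned a class
    uniformly; a detected target's class is drawn from the row of
    ``class_confusion`` for its true class (identity if ``None``).
    """

    miss_rate: float = 0.0
    false_alarm_rate: float = 0.0
    class_confusion: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for r in (self.miss_rate, self.false_alarm_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        if self.class_confusion is not None:
            cm = np.asarray(self.class_confusion, dtype=float)
            if cm.shape != (4, 4) or (cm < 0).any():
                raise ValueError("class_confusion must be a non-negative 4x4 matrix")
            if not np.allclose(cm.sum(axis=1), 1.0):
                raise ValueError("class_confusion rows must sum to 1")
            object.__setattr__(self, "class_confusion", cm)
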