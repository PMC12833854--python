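"""Core study data model: measurements, animal trajectories, studies.

The measurement unit is declared once per study and interpreted strictly:
caliper volume (mm³), bioluminescence (photons/s) or mass (g). All downstream
growth-rate mathematics is unit-agnostic because rates come from ratios of
values in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional


class Unit(str, Enum):
    """Tumor-burden measurement unit for a study."""

    volume_mm3 = "volume_mm3"
    bli_photons_per_s = "bli_photons_per_s"
    weight_g = "weight_g"


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Raised when parsed data violate a structural invariant."""


class InsufficientDataError(ValueError):
    """Raised when a computation has too few usable observations."""


@dataclass
class Measurement:
    """One tumor-burden reading: study day, value, and a soft exclusion mark.

    ``excluded`` is a filter state set by quality control; the underlying
    value is never destroyed. Values ≤ 0 are representable (they are data a
    QC criterion flags) but are never used in log-space computations.
    """

    day: float
    value: float
    excluded: bool = False

    @property
    def usable(self) -> bool:
        """True when the point can enter log-space math."""
        return (not self.excluded) and self.value > 0


@dataclass
class AnimalSeries:
    """One animal's ordered trajectory plus group label and terminal data."""

    animal_id: str
    group: str
    measurements: list[Measurement] = field(default_factory=list)
    terminal_weight: Optional[float] = None
    euthanasia_day: Optional[float] = None

    def __post_init__(self) -> None:
        self.measurements.sort(key=lambda m: m.day)
        days = [m.day for m in self.measurements]
        if len(set(days)) != len(days):
            raise ValidationError(
                f"animal {self.animal_id!r}: duplicate measurement days"
            )

    def usable_measurements(self) -> list[Measurement]:
        """Measurements that are positive and not excluded, day-ordered."""
        return [m for m in self.measurements if m.usable]

    def days(self) -> list[float]:
        return [m.day for m in self.measurements]

    def first_positive_value(self) -> Optional[float]:
        """Baseline for homogeneity scoring: first recorded positive value."""
        for m in self.measurements:
            if m.value > 0:
                return m.value
        return None

    def copy(self) -> "AnimalSeries":
        return AnimalSeries(
            animal_id=self.animal_id,
            group=self.group,
            measurements=[replace(m) for m in self.measurements],
            terminal_weight=self.terminal_weight,
            euthanasia_day=self.euthanasia_day,
        )


@dataclass
class Study:
    """A cohort of animals measured on a (possibly ragged) day grid."""

    animals: list[AnimalSeries]
    unit: Unit = Unit.volume_mm3
    group_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.animals:
            raise ValidationError("a study requires at least one animal")
        ids = [a.animal_id for a in self.animals]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate animal id(s): {sorted(dupes)}")
        if not self.group_names:
            seen: list[str] = []
            for a in self.animals:
                if a.group not in seen:
                    seen.append(a.group)
            self.group_names = seen
        for a in self.animals:
            if a.group not in self.group_names:
                raise ValidationError(
                    f"animal {a.animal_id!r} has unknown group {a.group!r}"
                )

    def group(self, name: str) -> list[AnimalSeries]:
        return [a for a in self.animals if a.group == name]

    def all_days(self) -> list[float]:
        """Sorted union of measurement days across the study."""
        days: set[float] = set()
        for a in self.animals:
            days.update(a.days())
        return sorted(days)

    def copy(self) -> "Study":
        return Study(
            animals=[a.copy() for a in self.animals],
            unit=self.unit,
            group_names=list(self.group_names),
        )
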