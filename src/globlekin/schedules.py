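"""Irradiation schedules: piecewise-constant dose-rate segments and pulses.

A schedule is an ordered sequence of elements, each either a
:class:`Segment` (a duration in hours at a constant dose rate in Gy/h) or a
:class:`Pulse` (an acute dose delivered instantaneously at that point in the
sequence).  Constructors cover the canonical designs: acute exposure,
single constant-rate exposure of protraction time T = D / dose_rate, and the
two-fraction split-dose experiment (two acute doses separated by a repair
gap).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Segment", "Pulse", "IrradiationSchedule"]


@dataclass(frozen=True)
class Segment:
    """Constant dose-rate exposure: ``duration`` hours at ``dose_rate`` Gy/h."""

    duration: float
    dose_rate: float

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError(f"segment duration must be >= 0 h, got {self.duration}")
        if self.dose_rate < 0:
            raise ValueError(f"dose rate must be >= 0 Gy/h, got {self.dose_rate}")

    @property
    def dose(self) -> float:
        return self.duration * self.dose_rate


@dataclass(frozen=True)
class Pulse:
    """Instantaneous (acute) dose in Gy."""

    dose: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"pulse dose must be >= 0 Gy, got {self.dose}")


@dataclass(frozen=True)
class IrradiationSchedule:
    """Ordered sequence of constant-rate segments and instantaneous pulses."""

    elements: tuple[Segment | Pulse, ...]
    kind: str = "segments"

    @classmethod
    def acute(cls, dose: float) -> "IrradiationSchedule":
        """Single instantaneous dose."""
        return cls(elements=(Pulse(dose),), kind="acute")

    @classmethod
    def constant_rate(cls, dose: float, dose_rate: float) -> "IrradiationSchedule":
        """Single exposure of dose D at constant rate, protraction time T = D/rate."""
        if dose < 0:
            raise ValueError(f"dose must be >= 0 Gy, got {dose}")
        if dose_rate <= 0:
            raise ValueError(
                f"dose_rate must be positive (got {dose_rate} Gy/h); a zero rate "
                "with nonzero dose means infinite protraction — use the "
                "low-dose-rate limit instead"
            )
        return cls(elements=(Segment(dose / dose_rate, dose_rate),), kind="constant_rate")

    @classmethod
    def split(
        cls, fraction_dose: float, gap: float, second_dose: float | None = None
    ) -> "IrradiationSchedule":
        """Two acute fractions separated by ``gap`` hours without irradiation.

        The classic experiment uses equal fractions; an unequal second dose
        may be given explicitly.
        """
        d2 = fraction_dose if second_dose is None else second_dose
        return cls(
            elements=(Pulse(fraction_dose), Segment(gap, 0.0), Pulse(d2)),
            kind="split",
        )

    @classmethod
    def from_segments(
        cls, segments: list[tuple[float, float]]
    ) -> "IrradiationSchedule":
        """Build from an explicit list of (duration_h, dose_rate_Gy_per_h)."""
        return cls(elements=tuple(Segment(t, r) for t, r in segments), kind="segments")

    @classmethod
    def from_dict(cls, d: dict) -> "IrradiationSchedule":
        """Build from a schedule descriptor mapping (YAML/JSON/CSV row)."""
        kind = d.get("type")
        if kind == "acute":
            return cls.acute(float(d["dose_Gy"]))
        if kind == "constant_rate":
            return cls.constant_rate(float(d["dose_Gy"]), float(d["dose_rate_Gy_per_h"]))
        if kind == "split":
            return cls.split(float(d["fraction_dose_Gy"]), float(d["gap_h"]))
        if kind == "segments":
            return cls.from_segments(d["segments"])
        raise ValueError(f"unknown schedule type {kind!r}")

    @property
    def total_dose(self) -> float:
        return sum(
            e.dose if isinstance(e, Segment) else e.dose for e in self.elements
        )

    @property
    def total_time(self) -> float:
        """Protraction time: total duration of all segments (pulses take no time)."""
        return sum(e.duration for e in self.elements if isinstance(e, Segment))

    @property
    def fraction_dose(self) -> float | None:
        if self.kind == "split":
            return self.elements[0].dose
        return None

    @property
    def gap(self) -> float | None:
        if self.kind == "split":
            return self.elements[1].duration
        return None
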