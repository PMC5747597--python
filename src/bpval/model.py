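"""Core data model for alternating-device measurement studies.

A study consists of participants measured in up to two sessions.  Within a
session each variable (SBP, DBP, HR) is observed seven times in alternation:
odd positions (1, 3, 5, 7) on the criterion device, even positions (2, 4, 6)
on the test device.  The model stores readings in that positional layout and
enforces the device/position parity at construction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Device",
    "Variable",
    "Sex",
    "Reading",
    "ParticipantProfile",
    "SessionSeries",
    "StudyDataset",
    "IntegrityError",
    "SchemaError",
    "CRITERION_POSITIONS",
    "TEST_POSITIONS",
    "N_POSITIONS",
    "device_for_position",
    "PLAUSIBLE_RANGE",
]

N_POSITIONS = 7
CRITERION_POSITIONS = (1, 3, 5, 7)
TEST_POSITIONS = (2, 4, 6)


class Device(str, Enum):
    CRITERION = "criterion"
    TEST = "test"


class Variable(str, Enum):
    SBP = "SBP"
    DBP = "DBP"
    HR = "HR"

    @property
    def units(self) -> str:
        return "bpm" if self is Variable.HR else "mm Hg"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


#: wide plausibility bounds per variable; values outside warn but never fail
PLAUSIBLE_RANGE: Mapping[Variable, tuple[float, float]] = {
    Variable.SBP: (30.0, 300.0),
    Variable.DBP: (30.0, 300.0),
    Variable.HR: (30.0, 250.0),
}


def device_for_position(position: int) -> Device:
    """Device implied by the alternating protocol at a 1-based position."""
    if position not in range(1, N_POSITIONS + 1):
        raise ValueError(f"position must be in 1..{N_POSITIONS}, got {position}")
    return Device.CRITERION if position % 2 == 1 else Device.TEST


class SchemaError(ValueError):
    """Input file is missing required columns or has unmappable labels."""


class IntegrityError(ValueError):
    """Structural invariant violated (e.g. device/position parity).

    Carries the full list of offending records so callers see every problem
    at once rather than the first one hit.
    """

    def __init__(self, message: str, violations: Optional[Sequence[str]] = None):
        self.violations = list(violations or [])
        if self.violations:
            message = message + "\n  " + "\n  ".join(self.violations)
        super().__init__(message)


@dataclass(frozen=True)
class Reading:
    """One measurement: participant x session x position x variable."""

    participant_id: str
    session: int
    position: int
    device: Device
    variable: Variable
    value: float

    def __post_init__(self) -> None:
        if self.session not in (1, 2):
            raise IntegrityError(
                f"session must be 1 or 2, got {self.session!r} "
                f"(participant {self.participant_id})"
            )
        expected = device_for_position(self.position)
        if self.device is not expected:
            raise IntegrityError(
                f"device/position parity violated: position {self.position} implies "
                f"{expected.value!r}, got {self.device.value!r} "
                f"(participant {self.participant_id}, session {self.session}, "
                f"variable {self.variable.value})"
            )
        if not math.isfinite(self.value):
            raise IntegrityError(
                f"non-finite value for participant {self.participant_id} "
                f"session {self.session} position {self.position}"
            )

    @property
    def in_plausible_range(self) -> bool:
        lo, hi = PLAUSIBLE_RANGE[self.variable]
        return lo <= self.value <= hi


@dataclass(frozen=True)
class ParticipantProfile:
    """Demographics/anthropometrics for one participant."""

    participant_id: str
    sex: Optional[Sex] = None
    age: Optional[float] = None
    weight_kg: Optional[float] = None
    height_cm: Optional[float] = None
    arm_circ_mm: Optional[float] = None

    @property
    def bmi(self) -> Optional[float]:
        if self.weight_kg is None or self.height_cm is None or self.height_cm <= 0:
            return None
        return self.weight_kg / (self.height_cm / 100.0) ** 2

    @property
    def age_eligible(self) -> Optional[bool]:
        return None if self.age is None else self.age >= 25

    @property
    def arm_eligible(self) -> Optional[bool]:
        if self.arm_circ_mm is None:
            return None
        return 220.0 <= self.arm_circ_mm <= 320.0

    @property
    def eligible(self) -> Optional[bool]:
        flags = [self.age_eligible, self.arm_eligible]
        if any(f is False for f in flags):
            return False
        if any(f is None for f in flags):
            return None
        return True


@dataclass
class SessionSeries:
    """The ordered seven-slot value vector for one participant x session x variable.

    ``values[i]`` corresponds to position ``i + 1``; missing slots are ``None``.
    """

    participant_id: str
    session: int
    variable: Variable
    values: list[Optional[float]] = field(default_factory=lambda: [None] * N_POSITIONS)

    def __post_init__(self) -> None:
        if len(self.values) != N_POSITIONS:
            raise IntegrityError(
                f"series must have exactly {N_POSITIONS} slots, got {len(self.values)} "
                f"(participant {self.participant_id}, session {self.session}, "
                f"variable {self.variable.value})"
            )

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.values)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.participant_id, self.session, self.variable.value)

    def value_at(self, position: int) -> Optional[float]:
        return self.values[position - 1]

    def criterion_values(self) -> list[float]:
        """Values at the four criterion positions (complete series only)."""
        self._require_complete()
        return [self.values[p - 1] for p in CRITERION_POSITIONS]

    def test_values(self) -> list[float]:
        """Values at the three test positions (complete series only)."""
        self._require_complete()
        return [self.values[p - 1] for p in TEST_POSITIONS]

    def _require_complete(self) -> None:
        if not self.complete:
            missing = [i + 1 for i, v in enumerate(self.values) if v is None]
            raise IntegrityError(
                f"series incomplete at positions {missing} "
                f"(participant {self.participant_id}, session {self.session}, "
                f"variable {self.variable.value})"
            )

    def to_readings(self) -> list[Reading]:
        out = []
        for pos, val in enumerate(self.values, start=1):
            if val is None:
                continue
            out.append(
                Reading(
                    participant_id=self.participant_id,
                    session=self.session,
                    position=pos,
                    device=device_for_position(pos),
                    variable=self.variable,
                    value=float(val),
                )
            )
        return out


@dataclass
class StudyDataset:
    """Validated collection of series plus optional participant profiles."""

    series: dict[tuple[str, int, str], SessionSeries] = field(default_factory=dict)
    profiles: dict[str, ParticipantProfile] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def add_series(self, s: SessionSeries) -> None:
        if s.key in self.series:
            raise IntegrityError(f"duplicate series {s.key}")
        self.series[s.key] = s

    def get_series(
        self, participant_id: str, session: int, variable: Variable | str
    ) -> Optional[SessionSeries]:
        var = Variable(variable).value
        return self.series.get((participant_id, session, var))

    @property
    def participant_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for key in self.series:
            seen.setdefault(key[0])
        return list(seen)

    def iter_series(
        self,
        session: Optional[int] = None,
        variable: Optional[Variable | str] = None,
        complete_only: bool = False,
    ) -> Iterable[SessionSeries]:
        var = Variable(variable).value if variable is not None else None
        for s in self.series.values():
            if session is not None and s.session != session:
                continue
            if var is not None and s.variable.value != var:
                continue
            if complete_only and not s.complete:
                continue
            yield s

    def complete_participants(
        self,
        sessions: Sequence[int],
        variables: Sequence[Variable | str],
    ) -> list[str]:
        """Participants with a complete series for every requested session x variable."""
        out = []
        vars_ = [Variable(v) for v in variables]
        for pid in self.participant_ids:
            ok = True
            for sess in sessions:
                for var in vars_:
                    s = self.get_series(pid, sess, var)
                    if s is None or not s.complete:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                out.append(pid)
        return out

    def to_readings(self) -> list[Reading]:
        out: list[Reading] = []
        for s in self.series.values():
            out.extend(s.to_readings())
        return out

    def validate(self) -> list[str]:
        """Return a list of warning strings; raise IntegrityError on hard failures."""
        warnings: list[str] = []
        if self.profiles:
            orphans = [pid for pid in self.participant_ids if pid not in self.profiles]
            if orphans:
                raise IntegrityError(
                    "series reference participants absent from profiles", orphans
                )
        for s in self.series.values():
            if not s.complete:
                warnings.append(
                    f"incomplete series (excluded from protocol evaluation): "
                    f"participant {s.participant_id}, session {s.session}, "
                    f"variable {s.variable.value}"
                )
            lo, hi = PLAUSIBLE_RANGE[s.variable]
            for pos, val in enumerate(s.values, start=1):
                if val is not None and not (lo <= val <= hi):
                    warnings.append(
                        f"value {val} outside plausible range [{lo}, {hi}]: "
                        f"participant {s.participant_id}, session {s.session}, "
                        f"position {pos}, variable {s.variable.value}"
                    )
        return warnings
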