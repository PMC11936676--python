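"""Typed records shared across the analysis stages."""

from __future__ import annotations

import math
from dataclasses import dataclass


class RecordError(ValueError):
    """A record violates one of its invariants."""


@dataclass(frozen=True)
class HeatShockRecord:
    """One individual's outcome in an acute heat-shock trial."""

    individual_id: str
    species: str  # "host" or "parasitoid"
    shock_temperature: float  # deg C
    survived: int  # 1 survived, 0 died

    def __post_init__(self) -> None:
        if self.survived not in (0, 1):
            raise RecordError(f"survived must be 0 or 1, got {self.survived!r}")
        if not math.isfinite(self.shock_temperature):
            raise RecordError("shock_temperature must be finite")


@dataclass(frozen=True)
class GradientTrial:
    """Paired control/gradient positions for one individual on the bar."""

    individual_id: str
    rearing_temperature: float  # deg C daytime maximum during development
    position_control: float  # mark index, gradient deactivated
    position_gradient: float  # mark index, gradient activated
    dry_mass: float | None = None  # mg, optional

    def __post_init__(self) -> None:
        for name in ("position_control", "position_gradient"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 1:
                raise RecordError(f"{name} must be a finite mark index >= 1, got {value!r}")


@dataclass(frozen=True)
class EmergenceRecord:
    """Days to adult emergence for one insect from one leaf."""

    insect_type: str  # "host" (moth) or "parasitoid"
    rearing_temperature: float  # deg C daytime maximum
    days_to_emergence: float

    def __post_init__(self) -> None:
        if self.insect_type not in ("host", "parasitoid"):
            raise RecordError(f"insect_type must be 'host' or 'parasitoid', got {self.insect_type!r}")
        if not self.days_to_emergence > 0:
            raise RecordError("days_to_emergence must be positive")
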