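"""Dosing regimens with per-kg semantics.

A regimen is an induction dose (mg/kg over a short zero-order infusion,
1 min by default) followed by one or more maintenance segments
(mg/kg/h for a duration in hours).  The maintenance start policy is
"after-induction" (maintenance begins when the induction infusion ends)
or "concurrent" (both start at t = 0, the loading+maintenance study
dialect).  An optional rate cap rejects maintenance rates above the
allowed ceiling for a weight band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .compartments import DoseEvent
from .units import MIN_PER_HOUR

__all__ = ["Regimen", "resolve_events"]


@dataclass(frozen=True)
class Regimen:
    induction_dose: float  # mg/kg
    induction_duration: float = 1.0  # min
    maintenance: Sequence[tuple[float, float]] = ()  # (mg/kg/h, hours)
    maintenance_start: str = "after-induction"  # or "concurrent"
    rate_cap: float | None = None  # mg/kg/h

    def __post_init__(self):
        if self.induction_dose < 0:
            raise ValueError("induction dose must be >= 0")
        if self.induction_duration <= 0:
            raise ValueError("induction duration must be > 0")
        if self.maintenance_start not in ("after-induction", "concurrent"):
            raise ValueError(f"unknown maintenance_start {self.maintenance_start!r}")
        for rate, hours in self.maintenance:
            if rate < 0:
                raise ValueError("maintenance rate must be >= 0")
            if hours <= 0:
                raise ValueError("maintenance duration must be > 0")
            if self.rate_cap is not None and rate > self.rate_cap:
                raise ValueError(
                    f"maintenance rate {rate} mg/kg/h exceeds cap {self.rate_cap} mg/kg/h"
                )

    @property
    def total_dose_per_kg(self) -> float:
        """Total administered dose in mg/kg."""
        return self.induction_dose + sum(r * h for r, h in self.maintenance)

    @property
    def end_of_maintenance(self) -> float:
        """Time (min) at which the last maintenance segment ends."""
        start = 0.0 if self.maintenance_start == "concurrent" else self.induction_duration
        return start + sum(h for _, h in self.maintenance) * MIN_PER_HOUR

    def to_dict(self) -> dict:
        return {
            "induction_dose_mg_per_kg": self.induction_dose,
            "induction_duration_min": self.induction_duration,
            "maintenance": [
                {"rate_mg_per_kg_per_h": r, "duration_h": h} for r, h in self.maintenance
            ],
            "maintenance_start": self.maintenance_start,
            "rate_cap_mg_per_kg_per_h": self.rate_cap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Regimen":
        known = {
            "induction_dose_mg_per_kg",
            "induction_duration_min",
            "maintenance",
            "maintenance_start",
            "rate_cap_mg_per_kg_per_h",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown regimen keys: {sorted(unknown)}")
        return cls(
            induction_dose=d["induction_dose_mg_per_kg"],
            induction_duration=d.get("induction_duration_min", 1.0),
            maintenance=tuple(
                (m["rate_mg_per_kg_per_h"], m["duration_h"]) for m in d.get("maintenance", ())
            ),
            maintenance_start=d.get("maintenance_start", "after-induction"),
            rate_cap=d.get("rate_cap_mg_per_kg_per_h"),
        )

    def label(self) -> str:
        maint = " + ".join(f"{r:g} mg/kg/h x {h:g} h" for r, h in self.maintenance)
        s = f"{self.induction_dose:g} mg/kg over {self.induction_duration:g} min"
        return f"{s} + {maint}" if maint else s


def resolve_events(regimen: Regimen, weight: float) -> list[DoseEvent]:
    """Convert a per-kg regimen into absolute dose events for a body weight."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    events = []
    if regimen.induction_dose > 0:
        events.append(
            DoseEvent(0.0, regimen.induction_duration, regimen.induction_dose * weight)
        )
    t = 0.0 if regimen.maintenance_start == "concurrent" else regimen.induction_duration
    for rate, hours in regimen.maintenance:
        dur = hours * MIN_PER_HOUR
        if rate > 0:
            events.append(DoseEvent(t, dur, rate * weight * hours))
        t += dur
    return events
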