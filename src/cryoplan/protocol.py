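"""Freeze-thaw protocol phases.

The clinical default is two cycles, each of 10 min active freezing,
2 min passive thawing and 1 min active thawing.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Phase", "Protocol", "default_protocol", "PHASE_MODES"]

PHASE_MODES = ("freeze", "passive_thaw", "active_thaw")


@dataclass(frozen=True)
class Phase:
    mode: str
    duration_s: float
    name: str = ""

    def validate(self) -> None:
        if self.mode not in PHASE_MODES:
            raise ValueError(f"unknown phase mode {self.mode!r}; expected {PHASE_MODES}")
        if not self.duration_s > 0:
            raise ValueError(f"phase duration must be positive, got {self.duration_s}")


@dataclass(frozen=True)
class Protocol:
    """Ordered sequence of phases. An empty sequence is a no-op protocol."""

    phases: tuple[Phase, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "phases", tuple(self.phases))

    def validate(self) -> None:
        for phase in self.phases:
            phase.validate()

    @property
    def total_duration_s(self) -> float:
        return sum(p.duration_s for p in self.phases)


def default_protocol(
    n_cycles: int = 2,
    freeze_s: float = 600.0,
    passive_thaw_s: float = 120.0,
    active_thaw_s: float = 60.0,
) -> Protocol:
    """Standard double freeze-thaw cycle (10 / 2 / 1 minutes)."""
    phases: list[Phase] = []
    for c in range(n_cycles):
        phases.append(Phase("freeze", freeze_s, f"freeze-{c + 1}"))
        phases.append(Phase("passive_thaw", passive_thaw_s, f"passive-thaw-{c + 1}"))
        phases.append(Phase("active_thaw", active_thaw_s, f"active-thaw-{c + 1}"))
    return Protocol(tuple(phases))
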