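"""Shared gait-event containers.

Event types follow the force-plate convention: IC (initial contact / heel
strike) and FC (final contact / toe off) of the ipsilateral foot; OIC and
OFC are the same events of the opposite foot referenced to the ipsilateral
cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EVENT_TYPES = ("IC", "FC", "OIC", "OFC")


@dataclass(frozen=True)
class GaitEvent:
    type: str
    time_s: float

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")


@dataclass
class GaitEventList:
    """A time-sorted list of typed gait events for one leg's reference frame."""

    events: list[GaitEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.time_s, e.type))
        for t in EVENT_TYPES:
            times = self.times(t)
            if np.any(np.diff(times) <= 0):
                raise ValueError(f"{t} times must be strictly increasing")

    def times(self, event_type: str) -> np.ndarray:
        return np.array([e.time_s for e in self.events if e.type == event_type])

    def filter(self, *types: str) -> "GaitEventList":
        return GaitEventList([e for e in self.events if e.type in types])

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)
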