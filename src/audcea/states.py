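"""State space of the cohort model.

The model tracks 22 mutually exclusive health states:

* 4 drinking-risk-level (DRL) states — low, medium, high, very high — the
  WHO consumption categories individuals move between;
* 5 permanent (absorbing-except-death) complication states — chronic
  alcohol-attributable diseases an individual cannot leave once entered;
* 12 tunnel states — 3 temporary alcohol-attributable events crossed with
  the 4 DRL states of origin, occupied for exactly one cycle before the
  individual returns to the origin DRL;
* 1 absorbing death state.

The ordering defined here is fixed and shared by every transition matrix
and occupancy trace in the package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Drl(enum.IntEnum):
    """WHO drinking risk level (temporary-complication tier)."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2
    VERY_HIGH = 3


class MediumTermRisk(enum.IntEnum):
    """Three-tier risk category used for medium-term complications."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


#: Chronic complications modelled as permanent states.
PERMANENT_EVENTS: tuple[str, ...] = (
    "ischemic_heart_disease",
    "ischemic_stroke",
    "hemorrhagic_stroke",
    "liver_cirrhosis",
    "chronic_pancreatitis",
)

#: Acute complications modelled as one-cycle tunnel states.
TEMPORARY_EVENTS: tuple[str, ...] = (
    "lower_respiratory_infections",
    "transport_injuries",
    "other_injuries",
)

EVENTS: tuple[str, ...] = PERMANENT_EVENTS + TEMPORARY_EVENTS


class StateKind(str, enum.Enum):
    DRL = "drl"
    PERMANENT_EVENT = "permanent_event"
    TUNNEL_EVENT = "tunnel_event"
    DEAD = "dead"


@dataclass(frozen=True)
class HealthState:
    kind: StateKind
    drl: Drl | None = None    # DRL states; for tunnels, the origin DRL
    event: str | None = None  # event states only

    @property
    def label(self) -> str:
        if self.kind is StateKind.DRL:
            return f"drl_{self.drl.name.lower()}"
        if self.kind is StateKind.PERMANENT_EVENT:
            return self.event
        if self.kind is StateKind.TUNNEL_EVENT:
            return f"{self.event}@{self.drl.name.lower()}"
        return "dead"


def _build_state_space() -> tuple[HealthState, ...]:
    states = [HealthState(StateKind.DRL, drl=d) for d in Drl]
    states += [HealthState(StateKind.PERMANENT_EVENT, event=e) for e in PERMANENT_EVENTS]
    states += [
        HealthState(StateKind.TUNNEL_EVENT, drl=d, event=e)
        for e in TEMPORARY_EVENTS
        for d in Drl
    ]
    states.append(HealthState(StateKind.DEAD))
    return tuple(states)


STATE_SPACE: tuple[HealthState, ...] = _build_state_space()
N_STATES: int = len(STATE_SPACE)  # 22
STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATE_SPACE)}
STATE_LABELS: tuple[str, ...] = tuple(s.label for s in STATE_SPACE)

DEAD_INDEX: int = N_STATES - 1


def drl_state_index(drl: Drl) -> int:
    return int(drl)


def permanent_state_index(event: str) -> int:
    return 4 + PERMANENT_EVENTS.index(event)


def tunnel_state_index(event: str, origin: Drl) -> int:
    return 9 + TEMPORARY_EVENTS.index(event) * 4 + int(origin)


PERMANENT_INDICES: tuple[int, ...] = tuple(range(4, 9))
TUNNEL_INDICES: tuple[int, ...] = tuple(range(9, 21))
DRL_INDICES: tuple[int, ...] = tuple(range(0, 4))
EVENT_STATE_INDICES: tuple[int, ...] = PERMANENT_INDICES + TUNNEL_INDICES
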