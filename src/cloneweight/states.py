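"""The multi-state structure for the hospitalized-cohort model.

Five states: normal ward (1, the initial state), ICU (2, intermediate),
and three absorbing states -- in-hospital death (3), discharge home (4)
and discharge to another healthcare facility (5).  Progression is
forward-only: patients admitted to the ICU cannot return to the ward,
giving seven allowed transitions (four ward exits, three ICU exits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

WARD = 1
ICU = 2
DEATH = 3
HOME = 4
HCF = 5

STATE_NAMES = {WARD: "ward", ICU: "icu", DEATH: "death", HOME: "home", HCF: "hcf"}

#: ward -> {icu, death, home, hcf}; icu -> {death, home, hcf}
DEFAULT_TRANSITIONS = (
    (WARD, ICU),
    (WARD, DEATH),
    (WARD, HOME),
    (WARD, HCF),
    (ICU, DEATH),
    (ICU, HOME),
    (ICU, HCF),
)


@dataclass(frozen=True)
class TransitionStructure:
    """States, allowed transitions and absorbing states of a forward-only
    multi-state model."""

    states: tuple[int, ...] = (WARD, ICU, DEATH, HOME, HCF)
    allowed: tuple[tuple[int, int], ...] = DEFAULT_TRANSITIONS
    absorbing: frozenset[int] = field(default_factory=lambda: frozenset({DEATH, HOME, HCF}))

    def __post_init__(self) -> None:
        state_set = set(self.states)
        for l, m in self.allowed:
            if l not in state_set or m not in state_set:
                raise ConfigurationError(f"allowed: transition ({l}, {m}) uses unknown state")
            if l in self.absorbing:
                raise ConfigurationError(
                    f"allowed: transition ({l}, {m}) leaves absorbing state {l}"
                )
            if l == m:
                raise ConfigurationError(f"allowed: self-transition ({l}, {m})")
        if not self.absorbing <= state_set:
            raise ConfigurationError("absorbing: not a subset of states")

    @property
    def transient(self) -> tuple[int, ...]:
        return tuple(s for s in self.states if s not in self.absorbing)

    def destinations(self, state: int) -> tuple[int, ...]:
        return tuple(m for (l, m) in self.allowed if l == state)

    def out_degree(self, state: int) -> int:
        return len(self.destinations(state))


def default_structure() -> TransitionStructure:
    """The 5-state / 7-transition structure used throughout the package."""
    return TransitionStructure()
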