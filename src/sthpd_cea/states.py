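"""Health states of the panic-disorder state-transition model."""

from __future__ import annotations

import enum


class HealthState(enum.IntEnum):
    """The four mutually exclusive model states.

    ``PF``
        Panic-free: neither panic disorder nor subthreshold symptoms.
    ``STHPD``
        Subthreshold panic disorder: clinically relevant panic symptoms
        below the diagnostic threshold.  The obligatory intermediate
        between ``PF`` and ``PD``.
    ``PD``
        Full-blown panic disorder.
    ``DEAD``
        Absorbing death state.
    """

    PF = 0
    STHPD = 1
    PD = 2
    DEAD = 3


#: States in matrix/vector order.
STATE_ORDER: tuple[HealthState, ...] = (
    HealthState.PF,
    HealthState.STHPD,
    HealthState.PD,
    HealthState.DEAD,
)

#: Alive (reward-bearing) states.
ALIVE_STATES: tuple[HealthState, ...] = (
    HealthState.PF,
    HealthState.STHPD,
    HealthState.PD,
)

N_STATES = len(STATE_ORDER)
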