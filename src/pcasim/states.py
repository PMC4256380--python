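"""Health states, risk groups, and treatment strategies.

The model walks each simulated patient through eight mutually exclusive
health states, one per annual cycle, from prostate-cancer (PCa) diagnosis
at age 65 to death. ``PCA_DEATH`` and ``OVERALL_DEATH`` are absorbing;
the only exit from metastatic castrate-resistant disease (mCRPC) is PCa
death.
"""

from __future__ import annotations

import enum


class HealthState(enum.IntEnum):
    """The eight health states of the model.

    ``DIAGNOSIS`` is instantaneous: it is where risk group and initial
    strategy are assigned, before the first annual cycle.  All other
    states are occupied for whole one-year cycles.
    """

    DIAGNOSIS = 0
    ACTIVE_SURVEILLANCE = 1
    ACTIVE_TREATMENT = 2
    RECURRENCE_FREE = 3
    RECURRENCE = 4
    MCRPC = 5
    PCA_DEATH = 6
    OVERALL_DEATH = 7

    @property
    def is_absorbing(self) -> bool:
        return self in (HealthState.PCA_DEATH, HealthState.OVERALL_DEATH)


#: Living states a patient can occupy during a cycle.
LIVING_STATES = (
    HealthState.ACTIVE_SURVEILLANCE,
    HealthState.ACTIVE_TREATMENT,
    HealthState.RECURRENCE_FREE,
    HealthState.RECURRENCE,
    HealthState.MCRPC,
)


class RiskGroup(enum.IntEnum):
    """D'Amico-style risk stratum at diagnosis."""

    LOW = 0
    INTERMEDIATE = 1
    HIGH = 2


class Strategy(enum.IntEnum):
    """Initial management strategy.

    AS       -- active surveillance (low risk only)
    RP       -- radical prostatectomy
    IMRT     -- intensity-modulated radiation therapy
    BT       -- brachytherapy
    IMRT_ADT -- IMRT + androgen deprivation therapy
    IMRT_BT  -- IMRT + brachytherapy
    IMRT_ADT_BT -- IMRT + ADT + brachytherapy
    PADT     -- primary ADT (used only in sensitivity scenario I)
    """

    AS = 0
    RP = 1
    IMRT = 2
    BT = 3
    IMRT_ADT = 4
    IMRT_BT = 5
    IMRT_ADT_BT = 6
    PADT = 7


class DeathCause(enum.IntEnum):
    """Cause of death recorded in patient trackers (0 = still alive)."""

    NONE = 0
    PCA = 1
    OTHER = 2
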