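"""Annual-cycle microsimulation engine.

Each simulated patient performs a random walk through the state graph,
one uniform draw per cycle resolved against the stacked exit partition
of the current state (disease event first, then other-cause death, stay
last).  Tracker variables record event years, so downstream transition
probabilities can depend on history (delayed treatment on the
surveillance pathway) despite the memoryless Markov core.

Timing conventions
------------------
* Cycles are one year, 1-based; every patient enters at diagnosis
  (age 65) and occupies a living state during each cycle.
* The transition draw happens at the end of the cycle: a death drawn at
  the end of cycle ``k`` means the patient lived ``k`` whole years, and
  an event drawn at the end of cycle ``k`` is recorded with event year
  ``k``.  No half-cycle correction is applied.
* Initial or delayed treatment occupies exactly one cycle
  (``ACTIVE_TREATMENT``), after which the patient follows
  recurrence-free dynamics.
* Under the lifetime horizon, patients still alive at the cycle cap
  (default 60, age 125) are absorbed at the cap: recorded as other-cause
  deaths (prostate-cancer deaths if in the metastatic state) and flagged
  ``censored``.

Randomness
----------
``run_replicate`` consumes its generator in a fixed documented order:
one uniform per patient for strategy assignment, one per patient for the
delayed-treatment modality, then one per patient per cycle.  The same
seed therefore yields bitwise-identical results.  ``run_model`` derives
per-replicate generators from ``(master_seed, replicate_index)`` so
replicates are independent of execution order, and scenario contrasts
can share random numbers by sharing the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .parameters import ModelParameters, ParameterError
from .states import DeathCause, HealthState, RiskGroup, Strategy

__all__ = [
    "PatientProfile",
    "Trackers",
    "PatientRecord",
    "CohortResult",
    "assign_strategy",
    "exit_probabilities",
    "step",
    "simulate_patient",
    "run_replicate",
    "run_model",
    "cohort_composition",
]

# short aliases for state codes used in hot loops
_AS = int(HealthState.ACTIVE_SURVEILLANCE)
_TX = int(HealthState.ACTIVE_TREATMENT)
_RF = int(HealthState.RECURRENCE_FREE)
_REC = int(HealthState.RECURRENCE)
_M = int(HealthState.MCRPC)
_DPC = int(HealthState.PCA_DEATH)
_DOC = int(HealthState.OVERALL_DEATH)


@dataclass(frozen=True)
class PatientProfile:
    """One simulated patient's fixed attributes."""

    patient_id: int
    risk: RiskGroup
    strategy: Strategy
    entry_age: float = 65.0


@dataclass
class Trackers:
    """Per-patient memory: event years (0 = never) and cause of death."""

    delayed_treatment_year: int = 0
    delayed_strategy: Strategy | None = None
    recurrence_year: int = 0
    mcrpc_year: int = 0
    death_year: int = 0
    death_cause: DeathCause = DeathCause.NONE
    censored: bool = False
    years_in_state: dict[HealthState, int] = field(default_factory=dict)


@dataclass
class PatientRecord:
    """A complete simulated life history."""

    profile: PatientProfile
    #: state occupied during each cycle, 1-based (index 0 = cycle 1)
    states: list[HealthState]
    trackers: Trackers


class CohortResult:
    """Vectorized life histories for one cohort replicate.

    Event-year arrays use 0 for "never"; ``death_cause`` uses the
    :class:`~pcasim.states.DeathCause` codes.  ``years_in_state`` has one
    column per :class:`~pcasim.states.HealthState` and counts whole lived
    years.  ``state_history`` (optional) stores the state occupied during
    each cycle.
    """

    def __init__(
        self,
        params: ModelParameters,
        risk: np.ndarray,
        strategy: np.ndarray,
        n_cycles: int,
    ) -> None:
        n = len(risk)
        self.params = params
        self.n = n
        self.n_cycles = n_cycles
        self.risk = risk
        self.strategy = strategy
        self.delayed_strategy = np.full(n, -1, dtype=np.int8)
        self.delayed_year = np.zeros(n, dtype=np.int32)
        self.recurrence_year = np.zeros(n, dtype=np.int32)
        self.mcrpc_year = np.zeros(n, dtype=np.int32)
        self.death_year = np.zeros(n, dtype=np.int32)
        self.death_cause = np.zeros(n, dtype=np.int8)
        self.censored = np.zeros(n, dtype=bool)
        #: state occupied during the final lived year (-1 while alive)
        self.last_state = np.full(n, -1, dtype=np.int8)
        self.years_in_state = np.zeros((n, len(HealthState)), dtype=np.int32)
        self.state_history: np.ndarray | None = None

    @property
    def all_absorbed(self) -> bool:
        return bool(np.all(self.death_year > 0))


def cohort_composition(cohort_size: int, risk_fractions: dict[RiskGroup, float]) -> dict[RiskGroup, int]:
    """Integer cohort counts per risk group by largest-remainder rounding."""
    groups = sorted(risk_fractions, key=int)
    exact = {g: cohort_size * risk_fractions[g] for g in groups}
    counts = {g: int(np.floor(exact[g])) for g in groups}
    short = cohort_size - sum(counts.values())
    by_remainder = sorted(groups, key=lambda g: (-(exact[g] - counts[g]), int(g)))
    for g in by_remainder[:short]:
        counts[g] += 1
    return counts


def assign_strategy(risk: RiskGroup, params: ModelParameters, rng: np.random.Generator) -> Strategy:
    """Draw one initial strategy from the risk group's allocation fractions."""
    u = rng.random()
    acc = 0.0
    items = sorted(params.allocations[risk].items(), key=lambda kv: int(kv[0]))
    for strat, frac in items:
        acc += frac
        if u < acc:
            return strat
    return items[-1][0]


def exit_probabilities(
    state: HealthState,
    risk: RiskGroup,
    strategy: Strategy,
    post_as: bool,
    cycle: int,
    params: ModelParameters,
) -> dict[HealthState, float]:
    """Competing exit probabilities of a non-absorbing state, in draw
    order, with the residual last.

    The residual is keyed by the state the patient occupies next if no
    exit fires: the state itself ("stay"), except for the one-cycle
    treatment tunnel whose residual is the recurrence-free state.
    Time-dependent entries are resolved against cycle ``cycle`` on the
    appropriate clock (both clocks coincide at model entry).
    """
    if state.is_absorbing:
        raise ValueError(f"state {state.name} is absorbing and has no exits")
    t = params.transition
    if state == HealthState.ACTIVE_SURVEILLANCE:
        out = {
            HealthState.RECURRENCE: t(risk, strategy, state, HealthState.RECURRENCE, cycle),
            HealthState.ACTIVE_TREATMENT: t(risk, strategy, state, HealthState.ACTIVE_TREATMENT, cycle),
            HealthState.OVERALL_DEATH: t(risk, strategy, state, HealthState.OVERALL_DEATH, cycle),
        }
        residual_target = state
    elif state == HealthState.ACTIVE_TREATMENT:
        out = {HealthState.OVERALL_DEATH: t(risk, strategy, state, HealthState.OVERALL_DEATH, cycle)}
        residual_target = HealthState.RECURRENCE_FREE
    elif state == HealthState.RECURRENCE_FREE:
        out = {
            HealthState.RECURRENCE: t(risk, strategy, state, HealthState.RECURRENCE, cycle, post_as),
            HealthState.OVERALL_DEATH: t(risk, strategy, state, HealthState.OVERALL_DEATH, cycle),
        }
        residual_target = state
    elif state == HealthState.RECURRENCE:
        out = {
            HealthState.MCRPC: t(risk, strategy, state, HealthState.MCRPC, cycle),
            HealthState.OVERALL_DEATH: t(risk, strategy, state, HealthState.OVERALL_DEATH, cycle),
        }
        residual_target = state
    else:  # mCRPC: the only exit is PCa death
        out = {HealthState.PCA_DEATH: params.mcrpc_to_pca_death}
        residual_target = state
    out = {s: p for s, p in out.items() if p > 0.0}
    total = sum(out.values())
    if total > 1.0 + 1e-9:
        raise ParameterError(
            f"exit partition of {state.name} (risk={risk.name}, strategy={strategy.name}, "
            f"cycle={cycle}) sums to {total} > 1"
        )
    out[residual_target] = out.get(residual_target, 0.0) + (1.0 - total)
    return out


def step(
    state: HealthState,
    risk: RiskGroup,
    strategy: Strategy,
    post_as: bool,
    cycle: int,
    params: ModelParameters,
    rng: np.random.Generator,
) -> HealthState:
    """Resolve one cycle's transition with a single uniform draw against
    the stacked exit partition (never sequential conditional draws)."""
    partition = exit_probabilities(state, risk, strategy, post_as, cycle, params)
    u = rng.random()
    acc = 0.0
    last = state
    for to_state, p in partition.items():
        acc += p
        last = to_state
        if u < acc:
            return to_state
    return last


def simulate_patient(
    profile: PatientProfile, params: ModelParameters, rng: np.random.Generator
) -> PatientRecord:
    """Walk one patient from diagnosis to absorption (or the horizon).

    This is the scalar reference implementation; :func:`run_replicate`
    uses an equivalent vectorized core, and the two are cross-checked
    against a deterministic cohort evaluation in the test suite.
    """
    n_cycles = params.n_cycles()
    trk = Trackers()
    if profile.strategy == Strategy.AS:
        # pre-draw the delayed modality so the walk consumes one uniform per cycle
        split = sorted(params.delayed_treatment_split.items(), key=lambda kv: int(kv[0]))
        u = rng.random()
        acc = 0.0
        trk.delayed_strategy = split[-1][0]
        for strat, frac in split:
            acc += frac
            if u < acc:
                trk.delayed_strategy = strat
                break
        state = HealthState.ACTIVE_SURVEILLANCE
    else:
        state = HealthState.ACTIVE_TREATMENT
    post_as = False
    states: list[HealthState] = []
    yis = {s: 0 for s in HealthState}
    for cycle in range(1, n_cycles + 1):
        states.append(state)
        yis[state] += 1
        strategy = trk.delayed_strategy if post_as else profile.strategy
        nxt = step(state, profile.risk, strategy if strategy is not None else profile.strategy,
                   post_as, cycle, params, rng)
        if nxt != state:
            if nxt == HealthState.ACTIVE_TREATMENT:
                trk.delayed_treatment_year = cycle + 1
                post_as = True
            elif nxt == HealthState.RECURRENCE:
                trk.recurrence_year = cycle
            elif nxt == HealthState.MCRPC:
                trk.mcrpc_year = cycle
            elif nxt == HealthState.PCA_DEATH:
                trk.death_year, trk.death_cause = cycle, DeathCause.PCA
            elif nxt == HealthState.OVERALL_DEATH:
                trk.death_year, trk.death_cause = cycle, DeathCause.OTHER
        state = nxt
        if state.is_absorbing:
            break
    if trk.death_year == 0 and params.horizon == "lifetime":
        trk.death_year = n_cycles
        trk.death_cause = DeathCause.PCA if state == HealthState.MCRPC else DeathCause.OTHER
        trk.censored = True
    trk.years_in_state = {s: c for s, c in yis.items() if c}
    return PatientRecord(profile=profile, states=states, trackers=trk)


def _recurrence_lookup(params: ModelParameters) -> np.ndarray:
    """(risk, strategy) -> annual recurrence probability after initial
    treatment; -1 marks combinations with no configured probability."""
    table = np.full((len(RiskGroup), len(Strategy)), -1.0)
    for g, probs in params.recurrence.items():
        for strat, p in probs.items():
            table[int(g), int(strat)] = p
    return table


def run_replicate(
    params: ModelParameters,
    rng: np.random.Generator | int | None = None,
    record_history: bool = False,
) -> CohortResult:
    """Simulate one full cohort replicate (vectorized).

    The cohort is built from ``params.cohort_size`` and the risk-group
    fractions by largest-remainder rounding, strategies are drawn from
    the allocation fractions, and every patient is walked through the
    model for ``params.n_cycles()`` cycles.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    counts = cohort_composition(params.cohort_size, params.risk_fractions)
    risk = np.repeat(
        [int(g) for g in sorted(counts, key=int)],
        [counts[g] for g in sorted(counts, key=int)],
    ).astype(np.int8)
    n = len(risk)

    # strategy assignment: one uniform per patient against the group's
    # allocation thresholds (strategies in enum order)
    u = rng.random(n)
    strategy = np.zeros(n, dtype=np.int8)
    for g in sorted(params.allocations, key=int):
        mask = risk == int(g)
        items = sorted(params.allocations[g].items(), key=lambda kv: int(kv[0]))
        edges = np.cumsum([frac for _, frac in items])
        codes = np.array([int(s) for s, _ in items], dtype=np.int8)
        idx = np.minimum(np.searchsorted(edges, u[mask], side="right"), len(codes) - 1)
        strategy[mask] = codes[idx]

    # delayed-treatment modality, pre-drawn for everyone (used by AS only)
    u = rng.random(n)
    split = sorted(params.delayed_treatment_split.items(), key=lambda kv: int(kv[0]))
    edges = np.cumsum([frac for _, frac in split])
    codes = np.array([int(s) for s, _ in split], dtype=np.int8)
    delayed = codes[np.minimum(np.searchsorted(edges, u, side="right"), len(codes) - 1)]

    return _simulate_cohort(params, risk, strategy, delayed, rng, record_history)


def _simulate_cohort(
    params: ModelParameters,
    risk: np.ndarray,
    strategy: np.ndarray,
    delayed: np.ndarray,
    rng: np.random.Generator,
    record_history: bool = False,
) -> CohortResult:
    n = len(risk)
    n_cycles = params.n_cycles()
    res = CohortResult(params, risk, strategy, n_cycles)

    od_by_year = params.overall_death.array(n_cycles)
    dt_by_year = params.delayed_treatment.array(n_cycles)
    rec_table = _recurrence_lookup(params)
    mcrpc_by_risk = np.array([params.recurrence_to_mcrpc.get(g, 0.0) for g in sorted(RiskGroup)])
    p_pca = params.mcrpc_to_pca_death
    surveillance_mode = params.as_recurrence_mode == "surveillance"
    as_rec = params.post_as_recurrence if surveillance_mode else 0.0

    state = np.where(strategy == int(Strategy.AS), _AS, _TX).astype(np.int8)
    # per-patient recurrence probability once in the recurrence-free state
    p_rec = rec_table[risk, strategy]
    p_rec[strategy == int(Strategy.AS)] = 0.0  # set on delayed treatment
    post_as_rec = (
        rec_table[risk, delayed] if surveillance_mode
        else np.full(n, params.post_as_recurrence)
    )
    if record_history:
        res.state_history = np.empty((n, n_cycles), dtype=np.int8)

    yis = res.years_in_state
    idx = np.arange(n)
    for cycle in range(1, n_cycles + 1):
        alive = state < _DPC
        if not alive.any():
            if record_history:
                res.state_history[:, cycle - 1 :] = state[:, None]
            break
        if record_history:
            res.state_history[:, cycle - 1] = state
        a = idx[alive]
        yis[a, state[a]] += 1

        od = od_by_year[cycle - 1]
        dt = dt_by_year[cycle - 1]
        u = rng.random(n)
        new_state = state.copy()

        on_as = alive & (state == _AS)
        if on_as.any():
            # stacked partition: recurrence (surveillance mode only),
            # delayed treatment, other-cause death, stay
            to_rec = on_as & (u < as_rec)
            to_tx = on_as & ~to_rec & (u < as_rec + dt)
            to_doc = on_as & ~to_rec & ~to_tx & (u < as_rec + dt + od)
            new_state[to_rec] = _REC
            res.recurrence_year[to_rec] = cycle
            new_state[to_tx] = _TX
            res.delayed_year[to_tx] = cycle + 1
            res.delayed_strategy[to_tx] = delayed[to_tx]
            p_rec[to_tx] = post_as_rec[to_tx]
            new_state[to_doc] = _DOC

        on_tx = alive & (state == _TX)
        if on_tx.any():
            to_doc = on_tx & (u < od)
            new_state[to_doc] = _DOC
            new_state[on_tx & ~to_doc] = _RF

        on_rf = alive & (state == _RF)
        if on_rf.any():
            to_rec = on_rf & (u < p_rec)
            to_doc = on_rf & ~to_rec & (u < p_rec + od)
            new_state[to_rec] = _REC
            res.recurrence_year[to_rec] = cycle
            new_state[to_doc] = _DOC

        on_rec = alive & (state == _REC)
        if on_rec.any():
            p_m = mcrpc_by_risk[risk]
            to_m = on_rec & (u < p_m)
            to_doc = on_rec & ~to_m & (u < p_m + od)
            new_state[to_m] = _M
            res.mcrpc_year[to_m] = cycle
            new_state[to_doc] = _DOC

        on_m = alive & (state == _M)
        if on_m.any():
            to_dpc = on_m & (u < p_pca)
            new_state[to_dpc] = _DPC
            res.death_year[to_dpc] = cycle
            res.death_cause[to_dpc] = int(DeathCause.PCA)
            res.last_state[to_dpc] = _M

        died_other = (new_state == _DOC) & (state != _DOC)
        res.death_year[died_other] = cycle
        res.death_cause[died_other] = int(DeathCause.OTHER)
        res.last_state[died_other] = state[died_other]
        state = new_state

    if params.horizon == "lifetime":
        unabsorbed = state < _DPC
        if unabsorbed.any():
            res.death_year[unabsorbed] = n_cycles
            res.censored[unabsorbed] = True
            res.last_state[unabsorbed] = state[unabsorbed]
            in_mcrpc = unabsorbed & (state == _M)
            res.death_cause[in_mcrpc] = int(DeathCause.PCA)
            res.death_cause[unabsorbed & ~in_mcrpc] = int(DeathCause.OTHER)
    return res


def run_model(
    params: ModelParameters,
    n_replicates: int,
    seed: int,
    record_history: bool = False,
) -> Iterator[CohortResult]:
    """Yield ``n_replicates`` independent cohort replicates.

    Replicate ``i`` uses a generator seeded from ``(seed, i)``, so a
    scenario run sharing ``seed`` with a base-case run uses common random
    numbers.
    """
    for rep in range(n_replicates):
        rng = np.random.default_rng([int(seed), rep])
        yield run_replicate(params, rng, record_history=record_history)
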