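"""Deterministic cohort-expectation oracle.

Propagates exact state-occupancy probabilities through the same
time-inhomogeneous transition structure the microsimulation samples
from (the surveillance and model-entry clocks coincide, so the expanded
state space -- splitting the post-surveillance treatment/recurrence-free
states from the upfront ones -- is Markov).  Used as an independent
check of the stochastic engine: microsimulation means must agree with
these expectations within Monte Carlo error.

Implemented from the model definition only; it shares no code with
``pcasim.engine``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pcasim.parameters import ModelParameters
from pcasim.states import HealthState, RiskGroup, Strategy

# expanded-state indices
AS_, TX0, TXD, RF0, RFD, REC_, M_, DPC_, DOC_ = range(9)
_LIVING = (AS_, TX0, TXD, RF0, RFD, REC_, M_)

#: expanded state -> reported HealthState
_COLLAPSE = {
    AS_: HealthState.ACTIVE_SURVEILLANCE,
    TX0: HealthState.ACTIVE_TREATMENT,
    TXD: HealthState.ACTIVE_TREATMENT,
    RF0: HealthState.RECURRENCE_FREE,
    RFD: HealthState.RECURRENCE_FREE,
    REC_: HealthState.RECURRENCE,
    M_: HealthState.MCRPC,
    DPC_: HealthState.PCA_DEATH,
    DOC_: HealthState.OVERALL_DEATH,
}


@dataclass
class ChainExpectation:
    """Exact per-cycle expectations for one (possibly mixed) chain."""

    #: occupancy[k-1, s]: probability of occupying HealthState s during cycle k
    occupancy: np.ndarray
    #: cumulative event probabilities by end of cycle k (index k-1)
    cum_recurrence: np.ndarray
    cum_mcrpc: np.ndarray
    cum_pca_death: np.ndarray
    cum_overall_death: np.ndarray
    le: float
    hale: float

    @classmethod
    def zeros(cls, n_cycles: int) -> "ChainExpectation":
        z = lambda: np.zeros(n_cycles)
        return cls(np.zeros((n_cycles, len(HealthState))), z(), z(), z(), z(), 0.0, 0.0)

    def add(self, other: "ChainExpectation", weight: float) -> None:
        self.occupancy += weight * other.occupancy
        self.cum_recurrence += weight * other.cum_recurrence
        self.cum_mcrpc += weight * other.cum_mcrpc
        self.cum_pca_death += weight * other.cum_pca_death
        self.cum_overall_death += weight * other.cum_overall_death
        self.le += weight * other.le
        self.hale += weight * other.hale


def chain_expectation(
    params: ModelParameters,
    risk: RiskGroup,
    strategy: Strategy,
    delayed_strategy: Strategy | None = None,
) -> ChainExpectation:
    """Expectations for one patient with a fixed strategy (and fixed
    delayed modality on the surveillance pathway)."""
    assert not params.end_of_life_all_causes, "oracle covers the default utility rule"
    n = params.n_cycles()
    surveil = params.as_recurrence_mode == "surveillance"
    as_rec = params.post_as_recurrence if surveil else 0.0
    if strategy == Strategy.AS:
        if surveil:
            p_rec_d = params.recurrence[risk][delayed_strategy]
        else:
            p_rec_d = params.post_as_recurrence
        p_rec_0 = 0.0
    else:
        p_rec_0 = params.recurrence[risk][strategy]
        p_rec_d = 0.0
    p_m = params.recurrence_to_mcrpc[risk]
    p_pca = params.mcrpc_to_pca_death

    occ = np.zeros(9)
    occ[AS_ if strategy == Strategy.AS else TX0] = 1.0
    out = ChainExpectation.zeros(n)
    u = params.utilities
    w = {
        AS_: u.long_term_morbidity, TX0: u.short_term_morbidity,
        TXD: u.short_term_morbidity, RF0: u.long_term_morbidity,
        RFD: u.long_term_morbidity, REC_: u.long_term_morbidity, M_: u.mcrpc,
    }
    cum = dict(rec=0.0, m=0.0, dpc=0.0, doc=0.0)
    for k in range(1, n + 1):
        od = params.overall_death.value(k)
        dt = params.delayed_treatment.value(k)
        for s, prob in enumerate(occ):
            out.occupancy[k - 1, int(_COLLAPSE[s])] += prob
        out.le += occ[list(_LIVING)].sum()
        out.hale += sum(occ[s] * w[s] for s in _LIVING)

        new = np.zeros(9)
        # surveillance: recurrence (surveillance mode only), delayed tx, death, stay
        new[REC_] += occ[AS_] * as_rec
        new[TXD] += occ[AS_] * dt
        new[DOC_] += occ[AS_] * od
        new[AS_] += occ[AS_] * (1 - as_rec - dt - od)
        # treatment tunnels
        for tx, rf in ((TX0, RF0), (TXD, RFD)):
            new[DOC_] += occ[tx] * od
            new[rf] += occ[tx] * (1 - od)
        # recurrence-free
        for rf, p_rec in ((RF0, p_rec_0), (RFD, p_rec_d)):
            new[REC_] += occ[rf] * p_rec
            new[DOC_] += occ[rf] * od
            new[rf] += occ[rf] * (1 - p_rec - od)
        # recurrence
        new[M_] += occ[REC_] * p_m
        new[DOC_] += occ[REC_] * od
        new[REC_] += occ[REC_] * (1 - p_m - od)
        # metastatic castrate-resistant: only exit is PCa death
        new[DPC_] += occ[M_] * p_pca
        new[M_] += occ[M_] * (1 - p_pca)
        new[DPC_] += occ[DPC_]
        new[DOC_] += occ[DOC_]

        inflow_rec = occ[AS_] * as_rec + occ[RF0] * p_rec_0 + occ[RFD] * p_rec_d
        inflow_dpc = occ[M_] * p_pca
        cum["rec"] += inflow_rec
        cum["m"] += occ[REC_] * p_m
        cum["dpc"] += inflow_dpc
        cum["doc"] += sum(occ[s] for s in (AS_, TX0, TXD, RF0, RFD, REC_)) * od
        out.cum_recurrence[k - 1] = cum["rec"]
        out.cum_mcrpc[k - 1] = cum["m"]
        out.cum_pca_death[k - 1] = cum["dpc"]
        out.cum_overall_death[k - 1] = cum["doc"]
        occ = new
    # the death-year utility substitution: each PCa death's final year was
    # counted at the mCRPC weight while it should carry the end-of-life weight
    # (patients absorbed at the cycle cap keep their state weight, so the
    # adjustment uses the pre-cap cumulative PCa deaths)
    out.hale -= out.cum_pca_death[-1] * (u.mcrpc - u.end_of_life)
    # lifetime cap absorption: survivors at the cap are recorded as deaths
    # (PCa if metastatic, other-cause otherwise), matching the engine
    if params.horizon == "lifetime":
        out.cum_pca_death[-1] += occ[M_]
        out.cum_overall_death[-1] += sum(occ[s] for s in (AS_, TX0, TXD, RF0, RFD, REC_))
    return out


def strategy_mixture(params: ModelParameters, risk: RiskGroup) -> ChainExpectation:
    """Expectations for one patient of a risk group, mixing over the
    allocation fractions (and the delayed-modality split)."""
    n = params.n_cycles()
    out = ChainExpectation.zeros(n)
    for strategy, frac in params.allocations[risk].items():
        if frac == 0:
            continue
        if strategy == Strategy.AS and params.as_recurrence_mode == "surveillance":
            for d, dfrac in params.delayed_treatment_split.items():
                out.add(chain_expectation(params, risk, strategy, d), frac * dfrac)
        else:
            out.add(chain_expectation(params, risk, strategy), frac)
    return out


def cohort_expectation(params: ModelParameters) -> ChainExpectation:
    """Whole-cohort expectations, weighting risk groups by their exact
    (largest-remainder) cohort counts."""
    from pcasim.engine import cohort_composition

    counts = cohort_composition(params.cohort_size, params.risk_fractions)
    total = sum(counts.values())
    out = ChainExpectation.zeros(params.n_cycles())
    for g, c in counts.items():
        if c:
            out.add(strategy_mixture(params, g), c / total)
    return out
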