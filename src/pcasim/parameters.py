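"""Model parameters: states, risk groups, strategies, allocation
fractions, transition probabilities, and utilities.

The complete base case is built in (:func:`base_case`); any parameter
set can also be loaded from, and saved to, a YAML/JSON document
(:func:`load_parameters`, :func:`save_parameters`).  Probabilities in a
config may be given directly as decimals or as ``{r: ..., t: ...}``
cumulative-incidence pairs, which are converted through
:mod:`pcasim.rates`.

Conventions
-----------
* All probabilities are per one-year cycle.
* Time-dependent probabilities are step functions over whole-year
  intervals ``[start, end]`` (inclusive), the final interval open-ended
  (``end = None``).  Two clocks exist: ``model-entry`` (years since
  diagnosis at age 65) and ``as-entry`` (years since entering active
  surveillance); as every patient enters the model at diagnosis and AS
  starts at entry, the two coincide in the base model but are tagged
  separately so the distinction survives configuration changes.
* For every state the per-cycle exit probabilities must sum to <= 1;
  the residual is the probability of remaining in the state.
"""

from __future__ import annotations

import copy
import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from .rates import cumulative_to_annual_probability
from .states import HealthState, RiskGroup, Strategy

__all__ = [
    "ParameterError",
    "StepFunction",
    "UtilityWeights",
    "ModelParameters",
    "base_case",
    "load_parameters",
    "save_parameters",
]

_SUM_TOL = 1e-9


class ParameterError(ValueError):
    """A model configuration violates an invariant."""


def _as_probability(value: Any, where: str) -> float:
    """Accept a decimal probability or an ``{r, t}`` cumulative-incidence
    pair and return the annual probability."""
    if isinstance(value, Mapping):
        try:
            return cumulative_to_annual_probability(float(value["r"]), float(value["t"]))
        except KeyError as exc:
            raise ParameterError(f"{where}: (r, t) pair missing key {exc}") from exc
    p = float(value)
    if not (0.0 <= p < 1.0):
        raise ParameterError(f"{where}: probability must be in [0, 1); got {p}")
    return p


@dataclass(frozen=True)
class StepFunction:
    """A piecewise-constant annual probability over whole-year intervals.

    ``pieces`` is an ordered tuple of ``(start, end, p)`` with intervals
    contiguous from year 1, non-overlapping, and the final interval
    open-ended (``end is None``).
    """

    pieces: tuple[tuple[int, int | None, float], ...]
    clock: str = "model-entry"  # or "as-entry"

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "pieces",
            tuple((int(a), None if b is None else int(b), float(p)) for a, b, p in self.pieces),
        )

    def validate(self, name: str = "step function") -> None:
        if not self.pieces:
            raise ParameterError(f"{name}: empty step function")
        if self.clock not in ("model-entry", "as-entry"):
            raise ParameterError(f"{name}: unknown clock {self.clock!r}")
        expected_start = 1
        for i, (a, b, p) in enumerate(self.pieces):
            last = i == len(self.pieces) - 1
            if a != expected_start:
                raise ParameterError(
                    f"{name}: interval {i} starts at year {a}, expected {expected_start} "
                    "(intervals must be contiguous from year 1)"
                )
            if last:
                if b is not None:
                    raise ParameterError(f"{name}: final interval must be open-ended (end = null)")
            else:
                if b is None or b < a:
                    raise ParameterError(f"{name}: interval {i} has invalid end {b!r}")
                expected_start = b + 1
            if not (0.0 <= p < 1.0):
                raise ParameterError(f"{name}: probability {p} outside [0, 1) in interval {i}")

    def value(self, year: int) -> float:
        """Probability applying in cycle ``year`` (1-based on this clock)."""
        if year < 1:
            raise ValueError(f"year must be >= 1; got {year}")
        for a, b, p in self.pieces:
            if b is None or year <= b:
                if year >= a:
                    return p
        raise AssertionError("unreachable: final interval is open-ended")

    def array(self, n_years: int) -> np.ndarray:
        """Values for years 1..n_years as a float array (index 0 = year 1)."""
        return np.array([self.value(y) for y in range(1, n_years + 1)])

    @property
    def max(self) -> float:
        return max(p for _, _, p in self.pieces)

    def to_jsonable(self) -> dict:
        return {"clock": self.clock, "pieces": [list(pc) for pc in self.pieces]}

    @classmethod
    def from_jsonable(cls, doc: Mapping, where: str = "step function") -> "StepFunction":
        pieces = tuple(
            (int(a), None if b is None else int(b), _as_probability(p, where))
            for a, b, p in doc["pieces"]
        )
        return cls(pieces=pieces, clock=doc.get("clock", "model-entry"))


@dataclass(frozen=True)
class UtilityWeights:
    """Utility per life-year by health context (base case in brackets).

    short_term_morbidity [0.88] -- year of active treatment, initial or
        delayed;
    long_term_morbidity [0.90]  -- surveillance, recurrence-free, and
        recurrence years;
    mcrpc [0.85]                -- years with metastatic
        castrate-resistant disease;
    end_of_life [0.50]          -- the final year of life when the cause
        of death is prostate cancer (overrides the state weight).
    """

    short_term_morbidity: float = 0.88
    long_term_morbidity: float = 0.90
    mcrpc: float = 0.85
    end_of_life: float = 0.50

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"utility {f.name} must be in [0, 1]; got {v}")


# Strategies a risk group may be allocated to (Table 1 plus primary ADT,
# which only enters through sensitivity scenario I).
PERMITTED_STRATEGIES: dict[RiskGroup, tuple[Strategy, ...]] = {
    RiskGroup.LOW: (Strategy.AS, Strategy.RP, Strategy.IMRT, Strategy.BT, Strategy.PADT),
    RiskGroup.INTERMEDIATE: (Strategy.RP, Strategy.IMRT, Strategy.IMRT_ADT, Strategy.IMRT_BT),
    RiskGroup.HIGH: (Strategy.IMRT_ADT, Strategy.IMRT_ADT_BT),
}


@dataclass
class ModelParameters:
    """The complete model specification.

    See the module docstring for conventions.  ``validate`` checks every
    invariant and raises :class:`ParameterError` with a message naming
    the offending entry.
    """

    cohort_size: int = 14_160
    risk_fractions: dict[RiskGroup, float] = field(default_factory=dict)
    #: initial-strategy allocation fractions per risk group (sum to 1)
    allocations: dict[RiskGroup, dict[Strategy, float]] = field(default_factory=dict)
    #: annual recurrence probability after initial treatment, by (risk, strategy)
    recurrence: dict[RiskGroup, dict[Strategy, float]] = field(default_factory=dict)
    #: annual recurrence probability after delayed treatment on the AS pathway
    post_as_recurrence: float = 0.14
    #: annual probability of moving from surveillance to delayed treatment
    delayed_treatment: StepFunction = field(
        default_factory=lambda: StepFunction(((1, 2, 0.08), (3, 5, 0.04), (6, None, 0.02)), "as-entry")
    )
    #: how delayed treatment is split across modalities (sum to 1)
    delayed_treatment_split: dict[Strategy, float] = field(
        default_factory=lambda: {Strategy.RP: 1 / 3, Strategy.IMRT: 1 / 3, Strategy.BT: 1 / 3}
    )
    #: annual probability of death from other causes (all living states
    #: except mCRPC, whose only exit is PCa death)
    overall_death: StepFunction = field(
        default_factory=lambda: StepFunction(
            ((1, 5, 0.02), (6, 10, 0.03), (11, 15, 0.04), (16, 20, 0.07), (21, None, 0.12))
        )
    )
    #: annual probability recurrence -> mCRPC, per risk group
    recurrence_to_mcrpc: dict[RiskGroup, float] = field(
        default_factory=lambda: {g: 0.07 for g in RiskGroup}
    )
    #: annual probability mCRPC -> PCa death (stay probability is the residual)
    mcrpc_to_pca_death: float = 0.27
    utilities: UtilityWeights = field(default_factory=UtilityWeights)
    #: reporting horizon: 5 | 10 | 15 | "lifetime"
    horizon: int | str = "lifetime"
    #: cycle cap for the lifetime horizon (entry at 65 -> age 125)
    max_cycles: int = 60
    entry_age: float = 65.0
    #: where Table-style AS-pathway recurrence (0.14) applies:
    #: "post-delayed-treatment" (default) or "surveillance"
    as_recurrence_mode: str = "post-delayed-treatment"
    #: if True the end-of-life utility also replaces the state weight in
    #: the death year of other-cause deaths
    end_of_life_all_causes: bool = False

    # -- accessors ---------------------------------------------------------

    def n_cycles(self) -> int:
        return self.max_cycles if self.horizon == "lifetime" else int(self.horizon)

    def recurrence_probability(
        self, risk: RiskGroup, strategy: Strategy, post_as: bool = False
    ) -> float:
        """Annual recurrence probability in the recurrence-free state for a
        patient treated with ``strategy`` (``post_as`` marks delayed
        treatment received on the surveillance pathway)."""
        if post_as and self.as_recurrence_mode == "post-delayed-treatment":
            return self.post_as_recurrence
        return self.recurrence[risk][strategy]

    def transition(
        self,
        risk: RiskGroup | None,
        strategy: Strategy | None,
        frm: HealthState,
        to: HealthState,
        cycle: int = 1,
        post_as: bool = False,
    ) -> float:
        """Single transition probability ``frm -> to`` in ``cycle``.

        Convenience accessor mirroring the transition table; the engine
        uses vectorized lookups instead.
        """
        od = self.overall_death.value(cycle)
        if frm == HealthState.MCRPC:
            if to == HealthState.PCA_DEATH:
                return self.mcrpc_to_pca_death
            if to == HealthState.MCRPC:
                return 1.0 - self.mcrpc_to_pca_death
            return 0.0
        if frm == HealthState.RECURRENCE:
            p_m = self.recurrence_to_mcrpc[risk]
            if to == HealthState.MCRPC:
                return p_m
            if to == HealthState.OVERALL_DEATH:
                return od
            if to == HealthState.RECURRENCE:
                return 1.0 - p_m - od
            return 0.0
        if frm == HealthState.RECURRENCE_FREE:
            if to == HealthState.RECURRENCE:
                return self.recurrence_probability(risk, strategy, post_as)
            if to == HealthState.OVERALL_DEATH:
                return od
            if to == HealthState.RECURRENCE_FREE:
                return 1.0 - self.recurrence_probability(risk, strategy, post_as) - od
            return 0.0
        if frm == HealthState.ACTIVE_TREATMENT:
            # one-cycle tunnel: survive -> recurrence-free
            if to == HealthState.OVERALL_DEATH:
                return od
            if to == HealthState.RECURRENCE_FREE:
                return 1.0 - od
            return 0.0
        if frm == HealthState.ACTIVE_SURVEILLANCE:
            dt = self.delayed_treatment.value(cycle)
            rec = self.post_as_recurrence if self.as_recurrence_mode == "surveillance" else 0.0
            if to == HealthState.ACTIVE_TREATMENT:
                return dt
            if to == HealthState.RECURRENCE:
                return rec
            if to == HealthState.OVERALL_DEATH:
                return od
            if to == HealthState.ACTIVE_SURVEILLANCE:
                return 1.0 - dt - rec - od
            return 0.0
        raise ValueError(f"no transitions out of {frm.name}")

    # -- validation --------------------------------------------------------

    def validate(self) -> "ModelParameters":
        if self.cohort_size < 1:
            raise ParameterError(f"cohort_size must be >= 1; got {self.cohort_size}")
        if self.horizon not in (5, 10, 15, "lifetime"):
            raise ParameterError(f"horizon must be 5, 10, 15 or 'lifetime'; got {self.horizon!r}")
        if self.max_cycles < 1:
            raise ParameterError("max_cycles must be >= 1")
        if self.as_recurrence_mode not in ("post-delayed-treatment", "surveillance"):
            raise ParameterError(f"unknown as_recurrence_mode {self.as_recurrence_mode!r}")

        total = sum(self.risk_fractions.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise ParameterError(f"risk_fractions sum to {total}, expected 1")
        for g, f in self.risk_fractions.items():
            if f < 0:
                raise ParameterError(f"risk fraction for {g.name} is negative")

        for g, alloc in self.allocations.items():
            s = sum(alloc.values())
            if abs(s - 1.0) > _SUM_TOL:
                raise ParameterError(
                    f"allocation fractions for risk group {g.name} sum to {s}, expected 1"
                )
            for strat, f in alloc.items():
                if f < 0:
                    raise ParameterError(f"allocation {g.name}/{strat.name} is negative")
                if strat not in PERMITTED_STRATEGIES[g]:
                    raise ParameterError(
                        f"strategy {strat.name} is not permitted for risk group {g.name}"
                    )
                if strat != Strategy.AS and f > 0 and strat not in self.recurrence.get(g, {}):
                    raise ParameterError(
                        f"no recurrence probability for allocated strategy {g.name}/{strat.name}"
                    )

        for g, probs in self.recurrence.items():
            for strat, p in probs.items():
                if not (0.0 <= p < 1.0):
                    raise ParameterError(
                        f"recurrence probability {g.name}/{strat.name} = {p} outside [0, 1)"
                    )
        if not (0.0 <= self.post_as_recurrence < 1.0):
            raise ParameterError("post_as_recurrence outside [0, 1)")
        for g, p in self.recurrence_to_mcrpc.items():
            if not (0.0 <= p < 1.0):
                raise ParameterError(f"recurrence_to_mcrpc[{g.name}] = {p} outside [0, 1)")
        if not (0.0 <= self.mcrpc_to_pca_death <= 1.0):
            raise ParameterError("mcrpc_to_pca_death outside [0, 1]")

        split_sum = sum(self.delayed_treatment_split.values())
        if abs(split_sum - 1.0) > _SUM_TOL:
            raise ParameterError(f"delayed_treatment_split sums to {split_sum}, expected 1")

        self.delayed_treatment.validate("delayed_treatment")
        self.overall_death.validate("overall_death")
        self.utilities.validate()

        # exit-probability partitions must sum to <= 1 in every cycle
        od_max = self.overall_death.max
        as_rec = self.post_as_recurrence if self.as_recurrence_mode == "surveillance" else 0.0
        if self.delayed_treatment.max + as_rec + od_max > 1.0 + _SUM_TOL:
            raise ParameterError(
                "active-surveillance exit partition exceeds 1: "
                f"delayed treatment {self.delayed_treatment.max} + recurrence {as_rec} "
                f"+ overall death {od_max}"
            )
        for g, probs in self.recurrence.items():
            for strat, p in probs.items():
                if p + od_max > 1.0 + _SUM_TOL:
                    raise ParameterError(
                        f"recurrence-free exit partition exceeds 1 for {g.name}/{strat.name}: "
                        f"recurrence {p} + overall death {od_max}"
                    )
        if self.post_as_recurrence + od_max > 1.0 + _SUM_TOL:
            raise ParameterError("post-AS recurrence-free exit partition exceeds 1")
        for g, p in self.recurrence_to_mcrpc.items():
            if p + od_max > 1.0 + _SUM_TOL:
                raise ParameterError(
                    f"recurrence-state exit partition exceeds 1 for {g.name}: "
                    f"mCRPC {p} + overall death {od_max}"
                )
        return self

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "cohort_size": self.cohort_size,
            "risk_fractions": {g.name: f for g, f in self.risk_fractions.items()},
            "allocations": {
                g.name: {s.name: f for s, f in alloc.items()}
                for g, alloc in self.allocations.items()
            },
            "recurrence": {
                g.name: {s.name: p for s, p in probs.items()}
                for g, probs in self.recurrence.items()
            },
            "post_as_recurrence": self.post_as_recurrence,
            "delayed_treatment": self.delayed_treatment.to_jsonable(),
            "delayed_treatment_split": {
                s.name: f for s, f in self.delayed_treatment_split.items()
            },
            "overall_death": self.overall_death.to_jsonable(),
            "recurrence_to_mcrpc": {g.name: p for g, p in self.recurrence_to_mcrpc.items()},
            "mcrpc_to_pca_death": self.mcrpc_to_pca_death,
            "utilities": dataclasses.asdict(self.utilities),
            "horizon": self.horizon,
            "max_cycles": self.max_cycles,
            "entry_age": self.entry_age,
            "as_recurrence_mode": self.as_recurrence_mode,
            "end_of_life_all_causes": self.end_of_life_all_causes,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ModelParameters":
        def risk(name: str) -> RiskGroup:
            try:
                return RiskGroup[name.upper()]
            except KeyError:
                raise ParameterError(f"unknown risk group {name!r}") from None

        def strat(name: str) -> Strategy:
            try:
                return Strategy[name.upper()]
            except KeyError:
                raise ParameterError(f"unknown strategy {name!r}") from None

        kwargs: dict[str, Any] = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        for key, val in doc.items():
            if key == "risk_fractions":
                kwargs[key] = {risk(k): float(v) for k, v in val.items()}
            elif key == "allocations":
                kwargs[key] = {
                    risk(g): {strat(s): float(f) for s, f in alloc.items()}
                    for g, alloc in val.items()
                }
            elif key == "recurrence":
                kwargs[key] = {
                    risk(g): {
                        strat(s): _as_probability(p, f"recurrence {g}/{s}")
                        for s, p in probs.items()
                    }
                    for g, probs in val.items()
                }
            elif key == "post_as_recurrence":
                kwargs[key] = _as_probability(val, "post_as_recurrence")
            elif key in ("delayed_treatment", "overall_death"):
                kwargs[key] = StepFunction.from_jsonable(val, key)
            elif key == "delayed_treatment_split":
                kwargs[key] = {strat(s): float(f) for s, f in val.items()}
            elif key == "recurrence_to_mcrpc":
                kwargs[key] = {
                    risk(g): _as_probability(p, f"recurrence_to_mcrpc {g}")
                    for g, p in val.items()
                }
            elif key == "mcrpc_to_pca_death":
                kwargs[key] = _as_probability(val, "mcrpc_to_pca_death")
            elif key == "utilities":
                kwargs[key] = UtilityWeights(**{k: float(v) for k, v in val.items()})
            else:
                kwargs[key] = val
        return cls(**kwargs)


def base_case(low_risk_mcrpc: float = 0.07) -> ModelParameters:
    """The complete printed base case.

    ``low_risk_mcrpc`` sets the low-risk recurrence -> mCRPC probability.
    The default 0.07 applies the same progression probability to every
    risk group; passing 0.0 gives the gated variant in which low-risk
    recurrences never progress to metastatic disease (see
    ``docs/methods.md`` for when each variant is appropriate).
    """
    params = ModelParameters(
        cohort_size=14_160,
        risk_fractions={
            RiskGroup.LOW: 0.5,
            RiskGroup.INTERMEDIATE: 0.3,
            RiskGroup.HIGH: 0.2,
        },
        allocations={
            RiskGroup.LOW: {
                Strategy.AS: 0.10,
                Strategy.RP: 0.30,
                Strategy.IMRT: 0.30,
                Strategy.BT: 0.30,
            },
            RiskGroup.INTERMEDIATE: {
                Strategy.RP: 0.49,
                Strategy.IMRT: 0.24,
                Strategy.IMRT_ADT: 0.19,
                Strategy.IMRT_BT: 0.08,
            },
            RiskGroup.HIGH: {
                Strategy.IMRT_ADT: 0.77,
                Strategy.IMRT_ADT_BT: 0.23,
            },
        },
        recurrence={
            RiskGroup.LOW: {
                Strategy.RP: 0.03,
                Strategy.IMRT: 0.03,
                Strategy.BT: 0.03,
            },
            RiskGroup.INTERMEDIATE: {
                Strategy.RP: 0.03,
                Strategy.IMRT: 0.04,
                Strategy.IMRT_ADT: 0.04,
                Strategy.IMRT_BT: 0.04,
            },
            RiskGroup.HIGH: {
                Strategy.IMRT_ADT: 0.09,
                Strategy.IMRT_ADT_BT: 0.08,
            },
        },
        recurrence_to_mcrpc={
            RiskGroup.LOW: low_risk_mcrpc,
            RiskGroup.INTERMEDIATE: 0.07,
            RiskGroup.HIGH: 0.07,
        },
    )
    return params.validate()


def load_parameters(source: str | Path | Mapping | io.TextIOBase) -> ModelParameters:
    """Load and validate a parameter set from a YAML/JSON document, file
    path, open stream, or mapping."""
    if isinstance(source, Mapping):
        doc = source
    elif isinstance(source, io.TextIOBase):
        doc = yaml.safe_load(source)
    else:
        text = Path(source).read_text()
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ParameterError("parameter document must be a mapping")
    return ModelParameters.from_dict(doc).validate()


def save_parameters(params: ModelParameters, path: str | Path, fmt: str | None = None) -> None:
    """Write a parameter set to ``path`` as YAML (default) or JSON."""
    path = Path(path)
    doc = params.to_dict()
    if fmt == "json" or (fmt is None and path.suffix == ".json"):
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def parameters_digest(params: ModelParameters) -> str:
    """Stable hash of a parameter set, for run manifests."""
    import hashlib

    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def deep_copy(params: ModelParameters) -> ModelParameters:
    return copy.deepcopy(params)
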