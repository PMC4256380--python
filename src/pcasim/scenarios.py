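"""Deterministic sensitivity scenarios as parameter overrides.

A :class:`ScenarioSpec` is a named list of ``(path, value)`` overrides
applied to a base parameter set.  Paths are dotted strings into
:class:`~pcasim.parameters.ModelParameters`, e.g.
``mcrpc_to_pca_death``, ``allocations.LOW``, ``recurrence.HIGH.IMRT_ADT``
or ``overall_death.pieces``.  Values may be scalars, ``{r, t}``
cumulative-incidence pairs, nested mappings (keyed by risk-group /
strategy names), or step-function piece lists.

The five one-way scenarios (I-V) and an example two-way composition are
shipped as YAML fixtures under ``pcasim/data`` and loaded with
:func:`get_scenario`.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .parameters import (
    ModelParameters,
    ParameterError,
    StepFunction,
    _as_probability,
)
from .states import RiskGroup, Strategy

__all__ = [
    "ScenarioSpec",
    "apply_scenario",
    "get_scenario",
    "list_scenarios",
    "two_way_spec",
]

#: ids of the packaged scenario fixtures
SCENARIO_IDS = ("I", "II", "III", "IV", "V", "two-way")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named set of parameter overrides."""

    id: str
    overrides: tuple[tuple[str, Any], ...] = ()
    description: str = ""

    @classmethod
    def from_jsonable(cls, doc: Mapping) -> "ScenarioSpec":
        return cls(
            id=str(doc["id"]),
            overrides=tuple((str(o["path"]), o["value"]) for o in doc.get("overrides", ())),
            description=str(doc.get("description", "")),
        )


def _enum_key(segment: str) -> Any:
    for enum_cls in (RiskGroup, Strategy):
        try:
            return enum_cls[segment.upper()]
        except KeyError:
            continue
    return segment


def _convert_mapping(value: Mapping, where: str) -> dict:
    if set(value) >= {"r", "t"}:
        return _as_probability(value, where)  # type: ignore[return-value]
    out = {}
    for k, v in value.items():
        key = _enum_key(str(k))
        out[key] = _convert_mapping(v, f"{where}.{k}") if isinstance(v, Mapping) else float(v)
    return out


def _set_path(params: ModelParameters, path: str, value: Any) -> None:
    segments = path.split(".")
    # walk to the parent of the leaf, remembering the grandparent so
    # frozen step functions can be rebuilt in place
    holder: Any = params
    trail: list[tuple[Any, Any]] = []  # (container, key) pairs leading to holder
    for seg in segments[:-1]:
        if isinstance(holder, dict):
            key = _enum_key(seg)
            if key not in holder:
                raise ParameterError(f"scenario path {path!r}: no entry {seg!r}")
            trail.append((holder, key))
            holder = holder[key]
        else:
            if not hasattr(holder, seg):
                raise ParameterError(f"scenario path {path!r}: no field {seg!r}")
            trail.append((holder, seg))
            holder = getattr(holder, seg)

    leaf = segments[-1]
    if isinstance(holder, StepFunction):
        if leaf != "pieces":
            raise ParameterError(f"scenario path {path!r}: step functions only expose 'pieces'")
        rebuilt = StepFunction.from_jsonable({"pieces": value, "clock": holder.clock}, path)
        container, key = trail[-1]
        _assign(container, key, rebuilt)
        return

    if isinstance(value, Mapping):
        value = _convert_mapping(value, path)
    elif isinstance(holder, dict) or dataclasses.is_dataclass(holder):
        current = holder.get(_enum_key(leaf)) if isinstance(holder, dict) else getattr(holder, leaf, None)
        if isinstance(current, StepFunction):
            value = StepFunction.from_jsonable({"pieces": value, "clock": current.clock}, path)
        elif isinstance(value, (int, float)) and isinstance(current, float):
            value = float(value)

    if isinstance(holder, dict):
        _assign(holder, _enum_key(leaf), value)
    else:
        if not hasattr(holder, leaf):
            raise ParameterError(f"scenario path {path!r}: no field {leaf!r}")
        _assign(holder, leaf, value)


def _assign(container: Any, key: Any, value: Any) -> None:
    if isinstance(container, dict):
        container[key] = value
    else:
        setattr(container, key, value)


def apply_scenario(params: ModelParameters, spec: ScenarioSpec) -> ModelParameters:
    """Return a new validated parameter set with the scenario's overrides
    applied; ``params`` is left untouched."""
    new = copy.deepcopy(params)
    for path, value in spec.overrides:
        _set_path(new, path, value)
    return new.validate()


def list_scenarios() -> tuple[str, ...]:
    return SCENARIO_IDS


def get_scenario(scenario_id: str) -> ScenarioSpec:
    """Load a packaged scenario fixture (``I``..``V``, ``two-way``) or a
    scenario YAML file by path."""
    if scenario_id in SCENARIO_IDS:
        name = "scenario_" + scenario_id.replace("-", "_") + ".yaml"
        text = resources.files("pcasim.data").joinpath(name).read_text()
    elif Path(scenario_id).exists():
        text = Path(scenario_id).read_text()
    else:
        raise ParameterError(
            f"unknown scenario {scenario_id!r}; expected one of {SCENARIO_IDS} or a file path"
        )
    return ScenarioSpec.from_jsonable(yaml.safe_load(text))


def two_way_spec(
    recurrence: Mapping,
    recurrence_to_mcrpc: float | Mapping,
    scenario_id: str = "two-way-custom",
) -> ScenarioSpec:
    """Build a two-way scenario varying recurrence probabilities and the
    recurrence -> mCRPC probability simultaneously.

    ``recurrence`` maps risk-group names to ``{strategy: probability}``
    mappings (only listed entries are overridden).  ``recurrence_to_mcrpc``
    is either one probability applied to every risk group or a mapping of
    risk-group names to probabilities.
    """
    overrides: list[tuple[str, Any]] = []
    for g, probs in recurrence.items():
        gname = g.name if isinstance(g, RiskGroup) else str(g)
        for s, p in probs.items():
            sname = s.name if isinstance(s, Strategy) else str(s)
            overrides.append((f"recurrence.{gname}.{sname}", p))
    if isinstance(recurrence_to_mcrpc, Mapping):
        for g, p in recurrence_to_mcrpc.items():
            gname = g.name if isinstance(g, RiskGroup) else str(g)
            overrides.append((f"recurrence_to_mcrpc.{gname}", p))
    else:
        for g in RiskGroup:
            overrides.append((f"recurrence_to_mcrpc.{g.name}", float(recurrence_to_mcrpc)))
    return ScenarioSpec(id=scenario_id, overrides=tuple(overrides))
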