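"""Conversions between cumulative incidences, annual rates, and annual
transition probabilities.

Source studies report cumulative incidences ``r`` over a period of ``t``
years.  Assuming a constant hazard within the period, the annual event
rate is ``r_1y = -ln(1 - r) / t`` and the corresponding per-cycle
(annual) transition probability is ``p_1y = 1 - exp(-r_1y)``.

All functions operate in double precision and use ``log1p``/``expm1`` so
the ``t = 1`` round trip (``cumulative incidence -> probability``)
recovers ``r`` to machine precision.
"""

from __future__ import annotations

import math
from typing import NamedTuple


class CumulativeIncidence(NamedTuple):
    """A proportion ``r`` in [0, 1) observed over ``t`` years (t > 0)."""

    r: float
    t: float


def _validate(r: float, t: float) -> None:
    if not (0.0 <= r < 1.0):
        raise ValueError(f"cumulative incidence r must be in [0, 1); got r={r!r}")
    if not (t > 0.0):
        raise ValueError(f"period length t must be positive; got t={t!r}")


def cumulative_to_annual_rate(r: float, t: float = 1.0) -> float:
    """Annual event rate (events per person-year) implied by a cumulative
    incidence ``r`` over ``t`` years: ``-ln(1 - r) / t``.

    Strictly increasing in ``r``; decreasing in ``t`` for fixed ``r > 0``.
    ``r = 1`` is rejected (infinite rate) rather than clamped.
    """
    _validate(r, t)
    return -math.log1p(-r) / t


def annual_rate_to_probability(r_1y: float) -> float:
    """Per-cycle transition probability for a constant annual rate:
    ``1 - exp(-r_1y)``, in [0, 1)."""
    if not (r_1y >= 0.0) or math.isinf(r_1y):
        raise ValueError(f"annual rate must be finite and >= 0; got r_1y={r_1y!r}")
    return -math.expm1(-r_1y)


def cumulative_to_annual_probability(r: float, t: float = 1.0) -> float:
    """Annual transition probability from a ``t``-year cumulative
    incidence: the composition of the two conversions above.

    Equals ``1 - (1 - r)**(1/t)``; for ``t = 1`` this is the identity.
    Applying the result independently for ``t`` consecutive years
    reproduces the cumulative incidence ``r``.
    """
    return annual_rate_to_probability(cumulative_to_annual_rate(r, t))
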