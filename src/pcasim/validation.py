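"""Internal validation: model-predicted annual event rates versus the
observed literature rates the model was built from.

The predicted annual rate of a pathway is its person-year incidence
rate: events divided by person-years at risk in the pathway's source
state, with the event year counted as a full at-risk year.  Under this
convention the estimator of a single-exit state's rate converges on its
configured annual transition probability.  For treatment pathways the
at-risk exposure is the treatment year plus subsequent recurrence-free
years; on the active-surveillance pathway exposure starts at delayed
treatment (surveillance years themselves carry no recurrence risk in the
default model reading).  Verbose output also reports the
continuous-hazard reading ``-ln(1 - rate)``.

Predicted rates are compared to the observed constants with one-sample
two-sided t-tests across cohort replicates (the literature provides no
standard errors, so a two-sample test is not computable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .engine import CohortResult, run_model
from .parameters import ModelParameters
from .states import DeathCause, HealthState, RiskGroup, Strategy

__all__ = [
    "ValidationRow",
    "observed_rates",
    "predicted_annual_rate",
    "compare_to_observed",
    "validation_table",
]

_TX = int(HealthState.ACTIVE_TREATMENT)
_RF = int(HealthState.RECURRENCE_FREE)
_REC = int(HealthState.RECURRENCE)
_M = int(HealthState.MCRPC)

#: pathway selector: (RiskGroup, Strategy) for recurrence pathways, or
#: "recurrence_to_mcrpc" / "mcrpc_to_pca_death"
Pathway = tuple[RiskGroup, Strategy] | str


@dataclass(frozen=True)
class ValidationRow:
    """One pathway of the validation report."""

    label: str
    pathway: Pathway
    predicted: float
    observed: float
    reference: str
    t_statistic: float
    p_value: float


def observed_rates() -> list[dict]:
    """The packaged observed literature rates, one entry per pathway."""
    text = resources.files("pcasim.data").joinpath("observed_rates.yaml").read_text()
    doc = yaml.safe_load(text)
    rows = []
    for row in doc["rows"]:
        pw = row["pathway"]
        if isinstance(pw, list):
            pw = (RiskGroup[pw[0]], Strategy[pw[1]])
        rows.append({**row, "pathway": pw})
    return rows


def predicted_annual_rate(result: CohortResult, pathway: Pathway) -> float:
    """Events per person-year at risk on a pathway, for one replicate.

    Returns NaN (with a warning) when the pathway accrues no
    person-years.
    """
    if pathway == "recurrence_to_mcrpc":
        py = float(result.years_in_state[:, _REC].sum())
        events = float(np.count_nonzero(result.mcrpc_year > 0))
    elif pathway == "mcrpc_to_pca_death":
        py = float(result.years_in_state[:, _M].sum())
        events = float(
            np.count_nonzero((result.death_cause == int(DeathCause.PCA)) & ~result.censored)
        )
    else:
        risk, strategy = pathway
        mask = (result.risk == int(risk)) & (result.strategy == int(strategy))
        py = float(result.years_in_state[mask, _TX].sum() + result.years_in_state[mask, _RF].sum())
        events = float(np.count_nonzero(result.recurrence_year[mask] > 0))
    if py == 0.0:
        warnings.warn(f"pathway {pathway!r}: zero person-years at risk; rate undefined")
        return float("nan")
    return events / py


def compare_to_observed(predicted: np.ndarray, observed: float) -> tuple[float, float]:
    """One-sample two-sided t-test of replicate-level predicted rates
    against the observed constant; returns ``(t, p)``."""
    arr = np.asarray(predicted, dtype=float)
    if arr.size < 2:
        raise ValueError("compare_to_observed requires at least 2 replicate values")
    if np.ptp(arr) == 0.0:
        if arr[0] == observed:
            return 0.0, 1.0
        warnings.warn("zero variance across replicates with mean != observed")
        return float(np.sign(arr[0] - observed)) * float("inf"), float(np.nextafter(0, 1))
    t, p = stats.ttest_1samp(arr, popmean=observed)
    return float(t), float(p)


def validation_table(
    params: ModelParameters,
    n_replicates: int = 100,
    seed: int = 0,
    verbose: bool = False,
) -> pd.DataFrame:
    """The full validation report: every configured pathway with its
    predicted rate (mean across replicates), the observed literature
    rate, and the t-test against it.

    ``verbose`` adds the per-replicate spread and the continuous-hazard
    reading of the predicted rate.
    """
    rows = observed_rates()
    rates = np.empty((n_replicates, len(rows)))
    for rep, result in enumerate(run_model(params, n_replicates, seed)):
        for j, row in enumerate(rows):
            rates[rep, j] = predicted_annual_rate(result, row["pathway"])
    out = []
    for j, row in enumerate(rows):
        vals = rates[:, j]
        vals = vals[~np.isnan(vals)]
        if vals.size < 2:
            t, p, mean = float("nan"), float("nan"), float("nan")
        else:
            mean = float(np.mean(vals))
            t, p = compare_to_observed(vals, row["observed"])
        rec = {
            "label": row["label"],
            "predicted": mean,
            "observed": row["observed"],
            "reference": row["reference"],
            "t_statistic": t,
            "p_value": p,
        }
        if verbose:
            rec["predicted_sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
            rec["predicted_hazard"] = -np.log1p(-mean) if mean < 1 else float("nan")
        out.append(rec)
    return pd.DataFrame(out)
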