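# Methods

## Model structure

`pcasim` is an individual-level (microsimulation) state-transition model
with a one-year cycle. Eight health states are modeled: diagnosis
(instantaneous), active surveillance, active treatment, recurrence-free,
recurrence, metastatic castrate-resistant prostate cancer (mCRPC), PCa
death, and other-cause death. The two death states are absorbing, and
the only exit from mCRPC is PCa death — patients with metastatic
castrate-resistant disease are assumed not to die of other causes.

Each patient is assigned a risk group at entry (low/intermediate/high,
base-case cohort fractions 0.5/0.3/0.2 applied to a 14,160-patient
cohort by largest-remainder rounding, giving 7080/4248/2832) and an
initial strategy drawn from the risk group's allocation fractions:

| risk group   | allocation                                                |
|--------------|-----------------------------------------------------------|
| low          | AS 0.10, RP 0.30, IMRT 0.30, BT 0.30                      |
| intermediate | RP 0.49, IMRT 0.24, IMRT+ADT 0.19, IMRT+BT 0.08           |
| high         | IMRT+ADT 0.77, IMRT+ADT+BT 0.23                           |

Annual recurrence probabilities after treatment are 0.03 for all
low-risk treatments, 0.03 (RP) / 0.04 (IMRT variants) for intermediate
risk, and 0.09 / 0.08 for the two high-risk strategies. Surveillance
patients move to delayed treatment with annual probability 0.08 (years
1–2), 0.04 (3–5), 0.02 (6–10, held at 0.02 beyond year 10 — the final
printed interval is extended open-ended); after delayed treatment they
follow recurrence-free dynamics with the surveillance-pathway recurrence
probability 0.14. Recurrence progresses to mCRPC at 0.07/year and mCRPC
to PCa death at 0.27/year. Other-cause mortality is a step function of
years since entry: 0.02 (1–5), 0.03 (6–10), 0.04 (11–15), 0.07 (16–20),
0.12 (21+), applied in every living state except mCRPC.

Literature inputs given as a cumulative incidence `r` over `t` years are
converted with `r_1y = -ln(1-r)/t` and `p_1y = 1 - exp(-r_1y)`
(`pcasim.rates`); configs may supply `{r, t}` pairs anywhere a
probability is expected.

## Timing and accounting conventions

* Cycles are 1-based years; everyone enters at exactly age 65 (the entry
  age is a configuration hook left at a point mass — no age distribution
  is published for this cohort definition).
* The transition draw closes the cycle: death drawn at the end of cycle
  `k` means `k` whole lived years; an event drawn at the end of cycle
  `k` carries event year `k`. No half-cycle correction is applied, since
  the model is specified directly in annual probabilities.
* Competing exits are resolved with **one** uniform draw against the
  stacked partition, in the fixed order *disease event, other-cause
  death, residual* — sequential conditional Bernoulli draws would bias
  the competing risks.
* Initial and delayed treatment occupy exactly one cycle (a tunnel
  state, utility 0.88) with no recurrence exit; recurrence risk starts
  in the recurrence-free state the following year. Other-cause mortality
  applies during the treatment year as well (the step-function row
  nominally covers surveillance/recurrence/recurrence-free, but leaving
  the treatment year immortal would be indefensible).
* The "lifetime" horizon caps at 60 cycles (age 125, configurable);
  patients still alive there (&lt;0.3% of a cohort) are absorbed at the
  cap, recorded as other-cause deaths (PCa deaths if metastatic) and
  flagged `censored`. Finite horizons (5/10/15) leave survivors
  unabsorbed, and LE/HALE refuse to evaluate them.
* The delayed-treatment clock is tagged separately (`as-entry`) from the
  mortality clock (`model-entry`); the two coincide in the base model
  because surveillance starts at entry.

## Utilities and HALE

Each lived year is weighted by the utility of its state: active
treatment 0.88 (short-term morbidity), surveillance / recurrence-free /
recurrence 0.90 (long-term morbidity), mCRPC 0.85, and end-of-life 0.50.
The end-of-life weight replaces the state weight **in the death year
only, for PCa deaths** — "end-of-life" is read as the terminal-disease
phase; other-cause death years keep their state utility (switchable via
`end_of_life_all_causes`). Surveillance years carry the long-term
morbidity weight 0.90 rather than 1.0; whether untreated surveillance
time should be discounted at all is genuinely open, and the choice is
confined to `UtilityWeights`. Years are undiscounted.

## The low-risk metastatic gate

Published risk-group outcome tables for this management mix report no
metastatic progression and no PCa death in low-risk disease through 15
years, which a universal recurrence→mCRPC probability of 0.07 cannot
produce; the gating mechanism (e.g. a salvage-treatment failure lag) is
not specified anywhere. The package therefore exposes both readings:
`base_case()` applies 0.07 to every risk group, and
`base_case(low_risk_mcrpc=0.0)` — the *gated* variant used by
`scripts/acceptance.py` — shuts the low-risk metastatic pathway off, so
low-risk patients can recur but then die only of other causes. Low-risk
metastatic/PCa-death cells are treated as structurally unresolved in the
acceptance comparisons.

## Sensitivity scenarios

Scenarios are pure parameter overrides (`pcasim.scenarios`), shipped as
YAML fixtures: (I) the low-risk cohort may receive primary ADT
(allocation 0.06, recurrence 0.01, alternative surveillance/treatment
fractions); (II) alternative allocation fractions for all groups; (III)
alternative post-treatment recurrence probabilities; (IV) mCRPC→PCa
death 0.35; (V) late other-cause mortality 0.15. Two printed alternative
allocation columns do not sum to 1 (low risk with PADT totals 1.06, high
risk 0.99); the fixtures renormalize them to 1, preserving the printed
ratios. The two-way analysis (joint recurrence and recurrence→mCRPC
variation) is parametric — `run_two_way` requires explicit overrides
because no alternative value for the 0.07 progression probability is
published; the packaged `two-way` fixture is an example upward
variation. Scenario batches share the master seed (common random
numbers) so contrasts reflect parameters, not sampling noise.

## Validation harness

The predicted annual rate of a pathway is its person-year incidence
rate: events ÷ person-years at risk in the source state, the event year
counting as a full at-risk year — under this convention a single-exit
state's rate estimator converges on its configured annual probability.
Treatment-pathway exposure is the treatment year plus subsequent
recurrence-free years; on the surveillance pathway exposure starts at
delayed treatment. The continuous-hazard reading `-ln(1 - rate)` is
reported alongside in verbose mode. Predicted rates are compared with
the observed literature constants by a one-sample two-sided t-test
across replicates (no standard errors are published for the observed
rates, so a two-sample test is not computable). Note that with ≥100
replicates of a 14,160-patient cohort the replicate-level standard error
is ~0.002, so this test rejects *any* systematic predicted–observed gap;
it is a precision statement about the simulator, not a clinical
equivalence test.

## Uncertainty

Replicate-based: the point estimate is the mean across Monte Carlo
cohort replicates; the 95% interval is the 2.5/97.5 empirical percentile
(assumption-free), with a normal-approximation option. Whether published
intervals of this model family are percentile- or normal-based is not
stated; percentile is the default because it needs no distributional
assumption.

## Randomness and reproducibility

Replicate `i` of a run seeds `numpy`'s PCG64 from `(master_seed, i)`,
and each replicate consumes uniforms in a fixed documented order
(strategy assignment, delayed-modality pre-draw, one uniform per patient
per cycle), so results are bitwise-reproducible from the manifest
(parameters hash + seed + replicate count) and independent of scenario
ordering. The scalar reference walk (`simulate_patient`) uses one draw
per cycle and is cross-checked against the vectorized engine through a
deterministic cohort oracle in the test suite.

## Problem sizes

The default run and the acceptance script use the full 14,160-patient
cohort with 120 lifetime replicates (≈5 s on one CPU with the vectorized
engine); the published analysis scale of 1000 replicates is available
via `--replicates 1000` and changes the means negligibly (the intervals
narrow). Unit and property tests use cohorts of 300–20,000 with
deterministic seeds.

## What the simulations do and do not show

All inputs are literature-derived constants; no patient-level data enter
the model. Passing tests therefore demonstrate internal consistency —
that the engine samples exactly the specified transition structure
(verified against an independent deterministic cohort evaluation), that
the accounting conventions are applied as documented, and that the
pipeline is reproducible — not that the transition inputs themselves are
correct for any particular population. Model outputs inherit every
limitation of those inputs: treatment complications are not modeled,
within-period hazards are constant by construction of the rate
conversion, recurrence probabilities do not depend on time since
treatment, and entry is a point mass at age 65. With the printed
other-cause mortality schedule, a never-progressing patient's expected
survival is ≈19.0 years (the deterministic cohort evaluation in the test
suite computes this bound); any reported life expectancy above that is
unreachable under these inputs, which is the main reason several
published headline values are not reproduced — see the acceptance test
output for the cell-by-cell comparison.
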