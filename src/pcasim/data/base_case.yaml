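# The complete built-in base case as a loadable configuration
# (identical to pcasim.base_case()): treatment allocation by risk group,
# annual transition probabilities, utilities, cohort composition.
cohort_size: 14160
risk_fractions:
  LOW: 0.5
  INTERMEDIATE: 0.3
  HIGH: 0.2
allocations:
  LOW:
    AS: 0.1
    RP: 0.3
    IMRT: 0.3
    BT: 0.3
  INTERMEDIATE:
    RP: 0.49
    IMRT: 0.24
    IMRT_ADT: 0.19
    IMRT_BT: 0.08
  HIGH:
    IMRT_ADT: 0.77
    IMRT_ADT_BT: 0.23
recurrence:
  LOW:
    RP: 0.03
    IMRT: 0.03
    BT: 0.03
  INTERMEDIATE:
    RP: 0.03
    IMRT: 0.04
    IMRT_ADT: 0.04
    IMRT_BT: 0.04
  HIGH:
    IMRT_ADT: 0.09
    IMRT_ADT_BT: 0.08
post_as_recurrence: 0.14
delayed_treatment:
  clock: as-entry
  pieces:
  - - 1
    - 2
    - 0.08
  - - 3
    - 5
    - 0.04
  - - 6
    - null
    - 0.02
delayed_treatment_split:
  RP: 0.3333333333333333
  IMRT: 0.3333333333333333
  BT: 0.3333333333333333
overall_death:
  clock: model-entry
  pieces:
  - - 1
    - 5
    - 0.02
  - - 6
    - 10
    - 0.03
  - - 11
    - 15
    - 0.04
  - - 16
    - 20
    - 0.07
  - - 21
    - null
    - 0.12
recurrence_to_mcrpc:
  LOW: 0.07
  INTERMEDIATE: 0.07
  HIGH: 0.07
mcrpc_to_pca_death: 0.27
utilities:
  short_term_morbidity: 0.88
  long_term_morbidity: 0.9
  mcrpc: 0.85
  end_of_life: 0.5
horizon: lifetime
max_cycles: 60
entry_age: 65.0
as_recurrence_mode: post-delayed-treatment
end_of_life_all_causes: false
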