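# Sensitivity analysis III: alternative annual recurrence probabilities
# following initial treatment.
id: III
description: Alternative recurrence probabilities after initial treatment
overrides:
  - path: recurrence.LOW
    value: {RP: 0.01, IMRT: 0.05, BT: 0.02}
  - path: recurrence.INTERMEDIATE
    value: {RP: 0.05, IMRT: 0.03, IMRT_ADT: 0.03, IMRT_BT: 0.01}
  - path: recurrence.HIGH
    value: {IMRT_ADT: 0.07, IMRT_ADT_BT: 0.10}
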