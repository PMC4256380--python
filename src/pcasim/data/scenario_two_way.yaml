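# Example two-way composition: recurrence probabilities raised to the
# larger of the base-case and alternative values, combined with a
# recurrence -> mCRPC probability of 0.08 (the observed literature value
# in the validation table).  The two-way analysis is parametric -- see
# pcasim.scenarios.two_way_spec -- and the exact values varied in the
# source analysis are not published; this fixture is the package's
# documented example of an upward joint variation.
id: two-way
description: Joint upward variation of recurrence and mCRPC-progression probabilities
overrides:
  - path: recurrence.LOW
    value: {RP: 0.03, IMRT: 0.05, BT: 0.03}
  - path: recurrence.INTERMEDIATE
    value: {RP: 0.05, IMRT: 0.04, IMRT_ADT: 0.04, IMRT_BT: 0.04}
  - path: recurrence.HIGH
    value: {IMRT_ADT: 0.09, IMRT_ADT_BT: 0.10}
  - path: recurrence_to_mcrpc
    value: {LOW: 0.08, INTERMEDIATE: 0.08, HIGH: 0.08}
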