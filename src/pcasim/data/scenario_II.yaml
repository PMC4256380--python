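# Sensitivity analysis II: alternative active-surveillance/treatment
# allocation fractions for every risk group (the high-risk column totals
# 0.99 as printed and is renormalized to sum to 1), plus the alternative
# delayed-treatment step function.
id: II
description: Alternative treatment-allocation fractions
overrides:
  - path: allocations.LOW
    value: {AS: 0.20, RP: 0.26, IMRT: 0.27, BT: 0.27}
  - path: allocations.INTERMEDIATE
    value: {RP: 0.46, IMRT: 0.23, IMRT_ADT: 0.21, IMRT_BT: 0.10}
  - path: allocations.HIGH
    value: {IMRT_ADT: 0.47474747474747475, IMRT_ADT_BT: 0.5252525252525253}
  - path: delayed_treatment.pieces
    value: [[1, 2, 0.10], [3, 5, 0.05], [6, null, 0.02]]
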