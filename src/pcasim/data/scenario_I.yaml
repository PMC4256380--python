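# Sensitivity analysis I: the low-risk cohort may receive primary
# androgen deprivation therapy (PADT).  Uses the alternative low-risk
# column: AS 0.20, RP 0.26, IMRT 0.27, BT 0.27, PADT 0.06 -- those
# fractions total 1.06 as printed, so they are renormalized to sum to 1
# -- together with the alternative delayed-treatment step function and
# low-risk recurrence probabilities (PADT recurrence 0.01).
id: I
description: Primary androgen deprivation therapy offered to the low-risk cohort
overrides:
  - path: allocations.LOW
    value:
      AS: 0.18867924528301888
      RP: 0.24528301886792453
      IMRT: 0.25471698113207547
      BT: 0.25471698113207547
      PADT: 0.056603773584905655
  - path: delayed_treatment.pieces
    value: [[1, 2, 0.10], [3, 5, 0.05], [6, null, 0.02]]
  - path: recurrence.LOW
    value: {RP: 0.01, IMRT: 0.05, BT: 0.02, PADT: 0.01}
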