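# Sensitivity analysis V: higher other-cause mortality in the open-ended
# tail of the step function (0.12 -> 0.15 from year 21 on).
id: V
description: Higher late other-cause mortality
overrides:
  - path: overall_death.pieces
    value: [[1, 5, 0.02], [6, 10, 0.03], [11, 15, 0.04], [16, 20, 0.07], [21, null, 0.15]]
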