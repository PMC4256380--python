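# Sensitivity analysis IV: higher annual probability of prostate-cancer
# death from the metastatic castrate-resistant state (0.27 -> 0.35).
id: IV
description: Higher mCRPC-to-PCa-death probability
overrides:
  - path: mcrpc_to_pca_death
    value: 0.35
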