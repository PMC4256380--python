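# Observed annual rates from the peer-reviewed literature used to build
# the model, for the internal-validation report (one row per pathway).
# "pathway" is either [risk group, initial strategy] for recurrence
# pathways or a named disease transition.
rows:
  - pathway: [LOW, AS]
    label: "Active surveillance -> PCa recurrence (low risk)"
    observed: 0.15
    reference: "Klotz et al., J Clin Oncol 2010"
  - pathway: [LOW, RP]
    label: "Radical prostatectomy -> PCa recurrence (low risk)"
    observed: 0.03
    reference: "Klotz et al., J Clin Oncol 2010"
  - pathway: [LOW, IMRT]
    label: "IMRT -> PCa recurrence (low risk)"
    observed: 0.03
    reference: "Klotz et al., J Clin Oncol 2010"
  - pathway: [LOW, BT]
    label: "Brachytherapy -> PCa recurrence (low risk)"
    observed: 0.03
    reference: "Klotz et al., J Clin Oncol 2010"
  - pathway: [INTERMEDIATE, RP]
    label: "Radical prostatectomy -> PCa recurrence (intermediate risk)"
    observed: 0.03
    reference: "Aizer et al., Int J Radiat Oncol Biol Phys 2009"
  - pathway: [INTERMEDIATE, IMRT_BT]
    label: "IMRT+brachytherapy -> PCa recurrence (intermediate risk)"
    observed: 0.04
    reference: "Vora et al., Urology 2013"
  - pathway: [INTERMEDIATE, IMRT_ADT]
    label: "IMRT+ADT -> PCa recurrence (intermediate risk)"
    observed: 0.04
    reference: "Aizer et al., Int J Radiat Oncol Biol Phys 2009"
  - pathway: [INTERMEDIATE, IMRT]
    label: "IMRT -> PCa recurrence (intermediate risk)"
    observed: 0.04
    reference: "Vora et al., Urology 2013"
  - pathway: [HIGH, IMRT_ADT]
    label: "IMRT+ADT -> PCa recurrence (high risk)"
    observed: 0.09
    reference: "Aizer et al., Int J Radiat Oncol Biol Phys 2009"
  - pathway: [HIGH, IMRT_ADT_BT]
    label: "IMRT+ADT+brachytherapy -> PCa recurrence (high risk)"
    observed: 0.08
    reference: "Kotecha et al., Int J Radiat Oncol Biol Phys 2013"
  - pathway: recurrence_to_mcrpc
    label: "PCa recurrence -> mCRPC"
    observed: 0.08
    reference: "Crook et al., N Engl J Med 2012"
  - pathway: mcrpc_to_pca_death
    label: "mCRPC -> PCa death"
    observed: 0.31
    reference: "Dragomir et al., BMJ Open 2014"
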