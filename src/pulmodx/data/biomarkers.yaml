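# Literature-derived disease -> biomarker association map.
# Weights are association strengths in (0, 1]; `baseline` is the normative
# intensity every marker rests at (the healthy profile). Edit freely: the
# marker vocabulary is the ordered union of all markers listed here.
baseline: 0.1
markers:
  - MMP-9
  - ELANE
  - TGF-beta
  - CRP
  - PCT
  - IL-6
  - IFN-alpha
  - CXCL10
  - TLR3
  - IL-1beta
  - TNF-alpha
  - SP-D
  - POSTN
  - IL-5
  - YKL-40
  - fibrinogen
  - CC16
  - IL-8
  - G-CSF
  - MUC5AC
diseases:
  bronchiectasis:
    MMP-9: 0.8
    ELANE: 0.8
    TGF-beta: 0.8
  pneumonia:
    CRP: 0.8
    PCT: 0.8
    IL-6: 0.8
  URTI:
    IFN-alpha: 0.8
    CXCL10: 0.8
    TLR3: 0.8
  LRTI:
    IL-1beta: 0.8
    TNF-alpha: 0.8
    SP-D: 0.8
  asthma:
    POSTN: 0.8
    IL-5: 0.8
    YKL-40: 0.8
  COPD:
    IL-6: 0.8
    fibrinogen: 0.8
    CC16: 0.8
  bronchiolitis:
    IL-8: 0.8
    G-CSF: 0.8
    MUC5AC: 0.8
  healthy: {}
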