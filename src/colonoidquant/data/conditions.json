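[
  {"index": 1, "label": "DMSO", "description": "0.033% DMSO vehicle control", "reference": true},
  {"index": 2, "label": "TOFA", "description": "50 uM tofacitinib", "reference": false},
  {"index": 3, "label": "BUD", "description": "10 uM budesonide", "reference": false},
  {"index": 4, "label": "TNF_PIC", "description": "TNF 100 ng/mL + Poly(I:C) 20 ug/mL stimulation", "reference": false},
  {"index": 5, "label": "TOFA_TNF_PIC", "description": "tofacitinib pre-treatment + TNF/Poly(I:C) stimulation", "reference": false},
  {"index": 6, "label": "BUD_TNF_PIC", "description": "budesonide pre-treatment + TNF/Poly(I:C) stimulation", "reference": false}
]
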