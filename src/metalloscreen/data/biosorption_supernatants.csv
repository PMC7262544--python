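group,element,mean_ug_ml,sd_ug_ml
MultiElementSolution,Al,1.67,
MultiElementSolution,Fe,0.99,
MultiElementSolution,Ga,1.67,
MultiElementSolution,La,2.20,
MultiElementSolution,Nd,2.34,
MultiElementSolution,Gd,2.41,
MultiElementSolution,Eu,2.44,
MultiElementSolution,Er,2.52,
ErMn_adaptation,Al,1.82,0.5
ErMn_adaptation,Fe,3.32,1.12
ErMn_adaptation,Ga,0.52,0.17
ErMn_adaptation,La,1.11,0.36
ErMn_adaptation,Nd,1.11,0.34
ErMn_adaptation,Gd,1.25,0.34
ErMn_adaptation,Eu,1.22,0.34
ErMn_adaptation,Er,1.13,0.3
Wild_type,Al,1.93,0.49
Wild_type,Fe,3.66,0.74
Wild_type,Ga,0.34,0.12
Wild_type,La,0.58,0.23
Wild_type,Nd,0.6,0.24
Wild_type,Gd,0.72,0.31
Wild_type,Eu,0.69,0.29
Wild_type,Er,0.65,0.2
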