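element,mean_ug_ml,sd_ug_ml
V,931.1,74.8
Ga,76.4,7.4
Mo,1123,86.7
Nd,558.3,113.7
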