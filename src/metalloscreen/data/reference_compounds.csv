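name,neutral_mass,class
Desferrioxamine B,560.3539,desferrioxamine-like
Desferrioxamine E,600.3488,desferrioxamine-like
Desferrioxamine G1,618.3594,desferrioxamine-like
Bisucaberin,400.2327,desferrioxamine-like
Bisucaberin B,418.2433,desferrioxamine-like
Citric acid,192.0270,citrate
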