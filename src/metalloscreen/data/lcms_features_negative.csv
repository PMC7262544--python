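name,measured_mz,theoretical_mz,adduct,mode,class,hplc_fractions
Desferrioxamine G1,617.3519,617.3510,[M-H]-,negative,desferrioxamine-like,14;15
Desferrioxamine E,599.3416,599.3404,[M-H]-,negative,desferrioxamine-like,10;14;15
Desferrioxamine B,559.3461,559.3455,[M-H]-,negative,desferrioxamine-like,15
Bisucaberin B,417.2413,417.2349,[M-H]-,negative,desferrioxamine-like,10;14;15
Citric acid,191.0354,191.0191,[M-H]-,negative,citrate,5;26
,631.3751,,[M-H]-,negative,desferrioxamine-like,14
,614.3494,,[M-H]-,negative,desferrioxamine-like,10
,582.3220,,[M-H]-,negative,desferrioxamine-like,10
,568.3063,,[M-H]-,negative,desferrioxamine-like,10
,543.3589,,[M-H]-,negative,desferrioxamine-like,14
,517.3422,,[M-H]-,negative,desferrioxamine-like,10;14;15
,503.3268,,[M-H]-,negative,desferrioxamine-like,10
,430.2234,,[M-H]-,negative,desferrioxamine-like,10
,401.2461,,[M-H]-,negative,desferrioxamine-like,10;14
,400.2134,,[M-H]-,negative,desferrioxamine-like,10
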