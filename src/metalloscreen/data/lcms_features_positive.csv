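name,measured_mz,theoretical_mz,adduct,mode,class,hplc_fractions
Desferrioxamine G1,619.3629,619.3667,[M+H]+,positive,desferrioxamine-like,14
Desferrioxamine E,601.3571,601.3561,[M+H]+,positive,desferrioxamine-like,10;14;15
Desferrioxamine B,561.3583,561.3612,[M+H]+,positive,desferrioxamine-like,15
Bisucaberin B,419.2486,419.2506,[M+H]+,positive,desferrioxamine-like,14;15
Bisucaberin,401.2374,401.2400,[M+H]+,positive,desferrioxamine-like,10;14;15
,633.3788,,[M+H]+,positive,desferrioxamine-like,14
,613.3549,,[M+H]+,positive,desferrioxamine-like,10
,584.3267,,[M+H]+,positive,desferrioxamine-like,10
,547.2941,,[M+H]+,positive,desferrioxamine-like,10
,515.2682,,[M+H]+,positive,desferrioxamine-like,10
,501.2523,,[M+H]+,positive,desferrioxamine-like,10
,403.2511,,[M+H]+,positive,desferrioxamine-like,10
,400.2031,,[M+H]+,positive,desferrioxamine-like,15
,348.1735,,[M+H]+,positive,desferrioxamine-like,10
,317.1563,,[M+H]+,positive,desferrioxamine-like,10;14;15
,315.1511,,[M+H]+,positive,desferrioxamine-like,10;15
,310.1809,,[M+H]+,positive,desferrioxamine-like,14;15
,302.2031,,[M+H]+,positive,desferrioxamine-like,10
,299.6374,,[M+H]+,positive,desferrioxamine-like,14
,281.1667,,[M+H]+,positive,desferrioxamine-like,15
,260.1752,,[M+H]+,positive,desferrioxamine-like,10;14;15
,257.1451,,[M+H]+,positive,desferrioxamine-like,10
,252.9893,,[M+H]+,positive,desferrioxamine-like,10;14
,246.1288,,[M+H]+,positive,desferrioxamine-like,5;14
,233.1450,,[M+H]+,positive,desferrioxamine-like,10;14;15
,219.1318,,[M+H]+,positive,desferrioxamine-like,10;14;15
,217.1503,,[M+H]+,positive,desferrioxamine-like,10
,203.1350,,[M+H]+,positive,desferrioxamine-like,10
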