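material,element,mean_ug_ml,sd_ug_ml,n
BlankTMOS,V,23.3,1.7,4
BlankTMOS,Ga,13.1,0.3,4
BlankTMOS,Mo,160.4,2.6,4
BlankTMOS,Nd,90.3,3.3,4
DFOB,V,74.9,4.8,4
DFOB,Ga,126.7,12.9,4
DFOB,Mo,197.1,6.6,4
DFOB,Nd,466.9,3.9,4
C18_CWB2,V,111,6,4
C18_CWB2,Ga,42.8,3.9,4
C18_CWB2,Mo,333,15,4
C18_CWB2,Nd,467.6,8.6,4
XAD_CWB2,V,78,1.3,4
XAD_CWB2,Ga,25.5,0.4,4
XAD_CWB2,Mo,335.2,2.3,4
XAD_CWB2,Nd,467.4,4.3,4
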