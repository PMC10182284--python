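name,alpha,beta,gamma,vmax_rps,km_um,kon_1e7_per_M_s
bMF1,b,b,b,786,67,3.5
TF1,T,T,T,189,17,3.4
PdF1,P,P,P,338,77,1.3
bbT,b,b,T,608,61,3.0
PbP,P,b,P,477,117,1.2
PPT,P,P,T,228,59,1.2
PTP,P,T,P,123,33,1.1
TTb,T,T,b,57,8,2.2
bTb,b,T,b,17,2,3.0
PTT,P,T,T,9,4,0.7
bTT,b,T,T,5,1,2.0
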