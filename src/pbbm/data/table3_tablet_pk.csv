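# IR tablets, two independent clinical studies: observed means vs
# model-predicted values, with the printed integer %PE.
study,dose_mg,metric,observed,predicted,pe_pct
A,5,cmax_ng_ml,105.68,101.20,4
A,5,tmax_h,2.00,3.00,-50
A,5,auc_ng_h_ml,982.48,906.13,8
A,10,cmax_ng_ml,166.54,183.75,-10
A,10,tmax_h,3.00,3.00,0
A,10,auc_ng_h_ml,1347.37,1667.98,-24
A,25,cmax_ng_ml,336.84,312.63,7
A,25,tmax_h,3.00,3.00,0
A,25,auc_ng_h_ml,3658.83,2961.29,19
A,50,cmax_ng_ml,587.95,401.38,32
A,50,tmax_h,4.00,4.00,0
A,50,auc_ng_h_ml,6759.43,3906.82,42
B,2.5,cmax_ng_ml,44.21,51.74,-17
B,2.5,tmax_h,4.00,3.00,25
B,2.5,auc_ng_h_ml,451.03,461.70,-2
B,10,cmax_ng_ml,194.09,183.75,5
B,10,tmax_h,2.50,3.00,-20
B,10,auc_ng_h_ml,1917.80,1667.98,13
B,25,cmax_ng_ml,335.98,312.63,7
B,25,tmax_h,4.00,3.00,25
B,25,auc_ng_h_ml,3653.04,2961.29,19
B,50,cmax_ng_ml,484.65,401.38,17
B,50,tmax_h,4.00,3.00,25
B,50,auc_ng_h_ml,5681.64,3906.82,31
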