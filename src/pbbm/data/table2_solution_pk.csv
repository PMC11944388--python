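# Oral-solution doses: observed clinical summary metrics (literature-reported
# means) vs model-predicted values, with the printed integer %PE.
dose_mg,metric,observed,predicted,pe_pct
0.5,cmax_ng_ml,8.42,11.09,-32
0.5,tmax_h,1.00,3.00,-200
0.5,auc_ng_h_ml,54.10,78.06,-44
1,cmax_ng_ml,23.46,22.19,5
1,tmax_h,1.50,3.00,-100
1,auc_ng_h_ml,176.32,197.88,-12
2.5,cmax_ng_ml,50.15,55.46,-11
2.5,tmax_h,1.50,3.00,-100
2.5,auc_ng_h_ml,454.96,494.69,-9
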