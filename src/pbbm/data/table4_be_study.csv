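# Bioequivalence study of two 5 mg wet-granulation tablets (50 um reference,
# 89 um test): observed vs model-predicted metrics and their T/R ratios.
quantity,metric,observed,predicted,pe_pct
ref_50um,cmax_ng_ml,101.80,104.23,-2
ref_50um,auc_ng_h_ml,1088.00,938.55,14
test_89um,cmax_ng_ml,87.80,94.93,-8
test_89um,auc_ng_h_ml,1030.00,856.75,17
tr_ratio,cmax_ng_ml,0.86,0.91,-6
tr_ratio,auc_ng_h_ml,0.95,0.91,4
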