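# Simulated 5 mg mean-profile T/R ratios versus the oral solution (R1) and
# the 83 um dry-granulation tablet (R2), across the particle-size grid.
reference,metric,formulation,ratio
solution,cmax,solution,1.00
solution,cmax,10,1.00
solution,cmax,25,0.99
solution,cmax,50,0.97
solution,cmax,83,0.92
solution,cmax,120,0.86
solution,cmax,160,0.80
solution,cmax,210,0.74
solution,tmax,solution,1.00
solution,tmax,10,1.01
solution,tmax,25,1.02
solution,tmax,50,1.04
solution,tmax,83,1.06
solution,tmax,120,1.10
solution,tmax,160,1.12
solution,tmax,210,1.15
solution,auc,solution,1.00
solution,auc,10,1.00
solution,auc,25,0.99
solution,auc,50,0.96
solution,auc,83,0.91
solution,auc,120,0.86
solution,auc,160,0.80
solution,auc,210,0.74
tablet_83um,cmax,solution,1.08
tablet_83um,cmax,10,1.08
tablet_83um,cmax,25,1.07
tablet_83um,cmax,50,1.05
tablet_83um,cmax,83,1.00
tablet_83um,cmax,120,0.94
tablet_83um,cmax,160,0.87
tablet_83um,cmax,210,0.80
tablet_83um,tmax,solution,0.94
tablet_83um,tmax,10,0.95
tablet_83um,tmax,25,0.95
tablet_83um,tmax,50,0.97
tablet_83um,tmax,83,1.00
tablet_83um,tmax,120,1.03
tablet_83um,tmax,160,1.05
tablet_83um,tmax,210,1.08
tablet_83um,auc,solution,1.09
tablet_83um,auc,10,1.09
tablet_83um,auc,25,1.08
tablet_83um,auc,50,1.05
tablet_83um,auc,83,1.00
tablet_83um,auc,120,0.94
tablet_83um,auc,160,0.88
tablet_83um,auc,210,0.81
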