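# Drug-specific model parameters: fitted 3-compartment IV disposition,
# in vitro permeability/solubility and the in vivo dissolution settings.
parameter,value,unit,origin
peff,0.157,cm/h,in vitro extrapolation
solubility,40,ug/mL,in vitro
z_dry_tablets,31,,in vitro fitting (0.1 N HCl medium)
z_be_study,22.3,,in vitro fitting (0.1 N HCl medium)
particle_size_tablets,83,um,in vitro
particle_size_be_test,89,um,in vitro
particle_size_be_ref,50,um,in vitro
k10,0.5409,1/h,in vivo fitting
k12,0.086,1/h,in vivo fitting
k21,0.0441,1/h,in vivo fitting
k13,4.319,1/h,in vivo fitting
k31,2.24,1/h,in vivo fitting
v1,4.756,L,in vivo fitting
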