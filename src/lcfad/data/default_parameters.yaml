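# Reference kinetic/stoichiometric parameter set (whole algal biomass;
# use f_fa: 0.11 for the lipid-extracted residue).
km_p: 10.0
km_h: 20.0
km_fa: 6.0
km_v: 20.0
Ks_p: 0.5
Ks_h: 0.5
Ks_fa: 0.5
Ks_v: 0.5
Y_h: 0.05
Y_v: 0.05
Y_m: 0.05
kd_h: 0.8
kd_v: 0.8
kd_m: 0.05
f_fa: 0.35
Khfa: 5.0
Kvfa: 5.0
Kmfa: 5.0
a: 0.5
b: 0.5
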