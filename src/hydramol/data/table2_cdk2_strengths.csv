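id,sd_nh2a_e81,sd_nh2b,sd_nh_l83,sdx_mol,sdc_mol,sd_mol
X02,0.86,1.04,0.71,2.61,5.34,7.95
X35,0.89,1.07,0.74,2.70,5.49,8.18
X36,0.84,1.03,0.71,2.59,5.60,8.19
X44,0.98,1.14,0.82,6.96,6.75,13.71
20Z,0.92,1.09,0.76,4.67,7.31,11.98
26Z,0.96,1.12,0.88,6.28,5.59,11.86
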