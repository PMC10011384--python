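feature,r
sd_nh2a_e81,0.59
sd_nh2b,0.53
sd_nh_l83,0.69
sdx_mol,0.60
sdc_mol,-0.21
sd_mol,0.39
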