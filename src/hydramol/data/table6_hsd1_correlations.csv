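feature,r
log_kb_int,0.48
sa_int,0.67
log_kb_ext,-0.27
sa_ext,-0.08
sa_mol,0.10
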