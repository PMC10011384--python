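constant,value,note
D,63.7,published donor calibration for the reference charge backend
A,-4.4362,published acceptor calibration for the reference charge backend
T,0.274,bond reduction factor
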