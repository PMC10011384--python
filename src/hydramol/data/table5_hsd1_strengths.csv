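id,log_kb_int,sa_int,log_kb_ext,sa_ext,sa_mol
2,1.56,0.68,1.49,0.63,4.36
3,0.54,0.57,2.58,0.70,4.20
4,1.64,0.69,1.70,0.64,4.36
5,1.66,0.72,1.68,0.63,4.40
6,1.84,0.78,1.42,0.66,4.50
7,1.90,0.78,1.62,0.66,4.55
8,1.82,0.68,1.46,0.68,5.25
9,1.20,0.76,0.70,0.48,4.99
10,0.98,0.65,1.34,0.49,5.04
11,0.88,0.61,1.11,0.48,5.01
12,0.85,0.68,0.81,0.51,5.00
13,1.69,0.66,1.70,0.67,5.14
14,1.69,0.73,1.70,0.65,4.48
15,0.92,0.76,1.09,0.59,4.60
16,0.41,0.63,0.42,0.59,4.90
17,1.56,0.66,1.68,0.62,5.02
18,1.84,0.67,1.97,0.64,5.28
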