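id,r5,r6,r7,pic50
2,H,H,H,7.0
3,H,H,H,6.0
4,CH3,H,H,7.7
5,H,CH3,H,7.2
6,H,H,CH3,7.5
7,CH3,H,CH3,8.2
8,CH3,H,CH2OCH3,7.6
9,CH3,H,CHF2,7.6
10,CH3,H,CF3,7.3
11,H,H,CF3,6.7
12,Cyclopropyl,H,CHF2,8.0
13,CH2OCH3,H,CH3,7.8
14,H,CH2CH3,H,7.5
15,H,Cl,H,7.3
16,H,Cyano,H,6.6
17,H,OCH3,H,7.2
18,H,CH2CH2OH,H,6.5
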