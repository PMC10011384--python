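id,r1,r2,pic50
X02,Vinyl,Phenyl,4.82
X35,Vinyl,3-pyridine,5.51
X36,Phenyl,Phenyl,6.03
X44,4-Phenyl sulfonamide,4-Phenyl sulfonamide,7.15
20Z,4-Phenyl sulfonamide,2-Naphthalene,4.07
26Z,4-Phenyl sulfonamide,3-Aniline,7.15
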