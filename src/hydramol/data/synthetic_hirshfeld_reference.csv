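# Synthetic reference charge set: approximate Hirshfeld-style partial
# charges for simple molecules, assembled from literature consensus values.
# These are a stand-in for the quantum-chemical reference data used to
# parameterise the charge model's electronegativities; they are NOT
# computed values from any specific calculation.
smiles,atom_index,element,target_charge_e,weight
O,0,O,-0.310,4
O,1,H,0.155,4
O,2,H,0.155,4
N,0,N,-0.257,1
N,1,H,0.0857,1
C,0,C,-0.168,1
C,1,H,0.042,1
CO,0,C,0.042,1
CO,1,O,-0.266,1
F,0,F,-0.225,1
F,1,H,0.225,1
S,0,S,-0.118,1
S,1,H,0.059,1
Cl,0,Cl,-0.165,1
Cl,1,H,0.165,1
c1ccccc1,0,C,-0.039,1
c1ccccc1,6,H,0.039,1
CF,0,C,0.055,1
CF,1,F,-0.205,1
CCl,0,C,-0.029,1
CCl,1,Cl,-0.151,1
CBr,0,C,-0.060,1
CBr,1,Br,-0.135,1
CI,0,C,-0.090,1
CI,1,I,-0.105,1
C=O,0,C,0.166,1
C=O,1,O,-0.286,1
C#N,0,C,0.078,1
C#N,1,N,-0.191,1
P,0,P,0.066,1
P,1,H,-0.022,1
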