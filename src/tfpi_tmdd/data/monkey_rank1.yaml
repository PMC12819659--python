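# Rank-1 (minimum-SSR) cynomolgus-monkey parameter set of the two-target
# TMDD model for the anti-TFPI antibody MG1113.
# Units: kg, nM, L/day, L, 1/day, 1/(nM*day).
BW: 3.5
KD: 0.04665
CL_D: 0.1454
V2: 0.1112
V3: 0.1346
k01: 20.32
k02: 8.859e-8
k12: 0.4033
k_loss: 3.149e-7
k_el_MG1113: 0.4543
k_on: 28.50
k_deg_s: 75.50
k_deg_m: 1.150
k_el_CS: 0.3094
k_el_CM: 0.006851
sTFPI_base: 0.9456
mTFPI_base: 12.04
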