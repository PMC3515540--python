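# Consensus amino-acid residue partial specific volumes (Cohn-Edsall) and
# residue (in-chain, water-subtracted) masses.
# columns: one-letter code, residue mass (g/mol), partial specific volume (mL/g)
residue,mass_g_mol,vbar_mL_g
A,71.0788,0.74
R,156.1875,0.70
N,114.1038,0.62
D,115.0886,0.60
C,103.1388,0.63
E,129.1155,0.66
Q,128.1307,0.67
G,57.0519,0.64
H,137.1411,0.67
I,113.1594,0.90
L,113.1594,0.90
K,128.1741,0.82
M,131.1926,0.75
F,147.1766,0.77
P,97.1167,0.76
S,87.0782,0.63
T,101.1051,0.70
W,186.2132,0.74
Y,163.1760,0.71
V,99.1326,0.86
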