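# One-bead-per-residue HPS parameters: sigma (nm), lambda (hydropathy,
# CALVADOS-family optimized scale), charge (e), mass (amu).
name,sigma,lam,charge,mass
A,0.504,0.2743297969040348,0.0,71.08
C,0.548,0.5615435099141777,0.0,103.14
D,0.558,0.0416040480605567,-1.0,115.09
E,0.592,0.0006935460962935,-1.0,129.12
F,0.636,0.8672358982062975,0.0,147.18
G,0.45,0.7012713677972457,0.0,57.05
H,0.608,0.4663667290557992,0.0,137.14
I,0.618,0.5423623610671892,0.0,113.16
K,0.636,0.1790211738990582,1.0,128.17
L,0.618,0.6440005007782226,0.0,113.16
M,0.618,0.5308481134337497,0.0,131.19
N,0.568,0.4255859009787431,0.0,114.1
P,0.556,0.3593126576364644,0.0,97.12
Q,0.602,0.3934318551056041,0.0,128.13
R,0.656,0.7307624767517166,1.0,156.19
S,0.518,0.4625416811611541,0.0,87.08
T,0.562,0.3713162976273964,0.0,101.1
V,0.586,0.2083769608174481,0.0,99.07
W,0.678,0.9893764740371644,0.0,186.21
Y,0.646,0.9774611449343455,0.0,163.18
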