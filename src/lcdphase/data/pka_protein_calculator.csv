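# Side-chain and terminal pKa values, Putnam "Protein Calculator v3.4" set.
# Default set: reproduces the printed TDP-43 net-charge values at pH 7.4.
group,pka
D,4.40
E,4.40
H,6.50
C,8.50
Y,10.00
K,10.00
R,12.00
N_TERM,8.00
C_TERM,3.10
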