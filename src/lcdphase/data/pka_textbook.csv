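# Alternative textbook side-chain / terminal pKa set (shipped for comparison).
group,pka
D,3.65
E,4.25
H,6.00
C,8.30
Y,10.07
K,10.53
R,12.48
N_TERM,9.00
C_TERM,2.00
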