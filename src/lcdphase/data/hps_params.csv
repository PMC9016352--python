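# One-bead-per-residue parameters for the hydrophobicity-scale (HPS) model.
# mass in Da, charge in elementary charges, sigma_A in Angstrom, lambda dimensionless.
# Canonical 20 residues: Dignon et al. (2018) HPS parameter set (Kapcha-Rossky scale).
# SEP (phosphoserine, one-letter code 's'): charge -2 fixed by phosphate chemistry,
# mass = Ser + HPO3; sigma/lambda are package defaults in the spirit of the
# phospho-residue HPS extension (see docs/methods.md).
code,mass,charge,sigma_A,lambda
A,71.08,0.0,5.04,0.730
R,156.19,1.0,6.56,0.000
N,114.10,0.0,5.68,0.432
D,115.09,-1.0,5.58,0.378
C,103.14,0.0,5.48,0.595
Q,128.13,0.0,6.02,0.514
E,129.11,-1.0,5.92,0.459
G,57.05,0.0,4.50,0.649
H,137.14,0.0,6.08,0.514
I,113.16,0.0,6.18,0.973
L,113.16,0.0,6.18,0.973
K,128.17,1.0,6.36,0.514
M,131.20,0.0,6.18,0.838
F,147.18,0.0,6.36,1.000
P,97.12,0.0,5.56,1.000
S,87.08,0.0,5.18,0.595
T,101.10,0.0,5.62,0.676
W,186.21,0.0,6.78,0.946
Y,163.18,0.0,6.46,0.865
V,99.07,0.0,5.86,0.892
s,167.06,-2.0,6.00,0.140
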