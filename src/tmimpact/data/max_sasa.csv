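# Reference maximum SASA (A^2) per residue type, computed on an
# extended Gly-X-Gly tripeptide with the package radii, probe 1.4 A,
# 960 sphere points.  RSA = residue SASA / this value.
residue,max_sasa
ALA,113.07
ARG,239.02
ASN,153.17
ASP,152.47
CYS,138.69
GLN,188.11
GLU,186.57
GLY,86.28
HIS,183.48
ILE,177.90
LEU,177.35
LYS,204.24
MET,193.75
PHE,203.64
PRO,136.29
SER,125.56
THR,149.74
TRP,253.12
TYR,221.57
VAL,153.95
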