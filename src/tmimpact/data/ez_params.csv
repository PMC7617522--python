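# Depth-dependent pseudo-energy (Ez) curve parameters per residue type.
# curve_kind sigmoidal: E(z) = E0 / (1 + (|z|/z_mid)^n)
# curve_kind gaussian:  E(z) = E0 * exp(-(|z|-z_mid)^2 / (2*sigma^2))
# E0 in pseudo-energy units (kcal/mol scale), z_mid and sigma in Angstrom.
# This file is the single source of the potential and is swappable: point
# TMIMPACT at a different table to change the membrane-insertion model.
residue,curve_kind,E0,z_mid,n,sigma
ALA,sigmoidal,-0.29,10.22,4.67,
ARG,sigmoidal,1.55,9.34,4.68,
ASN,sigmoidal,0.89,12.78,6.28,
ASP,sigmoidal,1.19,14.25,8.98,
CYS,sigmoidal,-0.49,12.50,6.00,
GLN,sigmoidal,1.21,10.46,2.59,
GLU,sigmoidal,1.30,14.66,4.16,
GLY,sigmoidal,-0.01,13.86,6.00,
HIS,sigmoidal,0.75,12.26,2.77,
ILE,sigmoidal,-0.56,14.34,10.69,
LEU,sigmoidal,-0.64,17.34,8.61,
LYS,sigmoidal,1.66,11.11,2.09,
MET,sigmoidal,-0.28,18.04,7.13,
PHE,sigmoidal,-0.80,19.67,7.12,
PRO,sigmoidal,0.83,18.09,3.53,
SER,sigmoidal,0.10,13.86,6.00,
THR,sigmoidal,0.01,13.86,6.00,
VAL,sigmoidal,-0.47,11.35,4.97,
TRP,gaussian,-0.85,11.65,,7.20
TYR,gaussian,-0.42,13.04,,6.00
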