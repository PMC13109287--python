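# Synthetic surrogate hydrophobicity scale (class-based).
# The published MD-derived per-residue index values are not reproduced here;
# this surrogate only preserves the class structure the hydropathy score
# relies on: hydrophobic residues have indices near zero, polar residues
# intermediate values, charged residues high values, and the maximum index
# product (ARG*ARG) equals 11.0, the upper root of the hydropathy parabola
# with a=0.033, b=0.363.
resname,H
GLY,0.15
ALA,0.20
VAL,0.25
LEU,0.30
ILE,0.35
MET,0.45
PHE,0.55
TYR,0.70
TRP,0.85
SER,1.30
PRO,1.50
THR,1.70
CYS,1.90
ASN,2.10
GLN,2.30
HIS,2.60
LYS,2.85
ASP,3.05
GLU,3.20
ARG,3.3166247903554
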