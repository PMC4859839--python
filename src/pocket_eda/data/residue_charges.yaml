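# Formal net charges (e) of amino-acid residues at physiological protonation.
# ALY = N(6)-acetyllysine (acetylated side chain is neutral).
ALA: 0
ARG: 1
ASN: 0
ASP: -1
CYS: 0
GLN: 0
GLU: -1
GLY: 0
HIS: 0
ILE: 0
LEU: 0
LYS: 1
MET: 0
PHE: 0
PRO: 0
SER: 0
THR: 0
TRP: 0
TYR: 0
VAL: 0
ALY: 0
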