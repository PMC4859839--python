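label,DE_HL,e_el_10,DE_ex_HL,DE_del_HF,DE_HF
ARG45,-28.74,-29.07,0.33,-3.09,-31.83
ALA33,-5.90,-18.02,12.12,-10.51,-16.41
ASN248,2.22,-8.18,10.40,-3.76,-1.54
GLY34,0.08,-5.09,5.17,-2.63,-2.55
LEU249,2.1,-12.4,14.47,-3.3,-1.2
PHE184,-0.80,-1.20,0.39,-0.66,-1.46
SER270,3.74,-9.408,13.15,-4.34,-0.60
PHE44,1.04,-0.10,1.14,-0.29,0.74
PHE67,0.66,-0.44,1.10,-0.22,0.44
ALY16B,-4.15,-15.64,11.48,-5.15,-9.30
ILE117,2.39,-5.86,8.26,-2.08,0.32
THR37,1.97,-16.81,18.79,-6.95,-4.94
SER225,3.68,-8.24,11.92,-7.47,-3.80
ASP118,13.59,-9.85,23.44,-12.68,0.90
TYR269,0.71,-3.74,4.43,-1.37,-0.658
ADP,-17.78,-107.18,89.40,-34.85,-52.62
NICO,14.62,-14.54,29.16,-12.72,1.90
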