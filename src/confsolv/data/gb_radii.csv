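# Bondi-type intrinsic GB radii (nm) and HCT descreening scales per element.
element,rho_nm,scale
H,0.12,0.85
C,0.17,0.72
N,0.155,0.79
O,0.15,0.85
F,0.15,0.88
P,0.185,0.86
S,0.18,0.96
Cl,0.17,0.80
Br,0.185,0.80
I,0.198,0.80
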