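# Solvent registry: name, relative dielectric permittivity, embedding index.
# Dielectric values are editable literature placeholders; replace with your
# preferred compilation if needed. Order: descending permittivity.
name,dielectric,embedding_index
water,78.4,0
dmso,46.7,1
sulfolane,43.3,2
glycerin,42.5,3
acetonitrile,37.5,4
dmf,36.7,5
dmpu,36.1,6
nitromethane,35.9,7
nitrobenzene,34.8,8
methanol,32.7,9
nmp,32.2,10
hmpa,30.0,11
propionitrile,29.7,12
2-nitropropane,25.5,13
benzonitrile,25.2,14
ethanol,24.5,15
acetone,20.7,16
ipa,17.9,17
pyridine,12.4,18
octanol,10.3,19
trifluorotoluene,9.2,20
dcm,8.93,21
thf,7.58,22
acetic_acid,6.2,23
dme,6.18,24
ethyl_acetate,6.02,25
butyl_formate,5.3,26
chloroform,4.81,27
mtbe,4.5,28
diethyl_ether,4.33,29
oxylol,2.57,30
toluene,2.38,31
benzene,2.27,32
1-4-dioxane,2.25,33
carbon_tetrachloride,2.24,34
hexafluoroacetone,2.1,35
hexafluorobenzene,2.03,36
cyclohexane,2.02,37
hexane,1.88,38
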