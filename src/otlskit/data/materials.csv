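name,chemical_class,refractive_index,incompatible_with
fused silica,glass,1.46,
N-BK7,glass,1.52,
PMMA,monomer_polymer,1.49,
PS,monomer_polymer,1.59,solvent
SMMA,monomer_polymer,1.56,solvent
SAN,monomer_polymer,1.57,solvent
HIVEX,monomer_polymer,1.55,
NK55,monomer_polymer,1.56,
KOC55,monomer_polymer,1.55,
FEP,fluoropolymer,1.34,
PTFE,fluoropolymer,1.35,
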