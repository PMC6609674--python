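name,refractive_index,reagent_class
ECi,1.56,solvent
BABB,1.56,solvent
DBE,1.56,solvent
TDE,1.46,aqueous
Ce3D,1.49,aqueous
CLARITY,1.45,aqueous
water,1.33,expansion
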