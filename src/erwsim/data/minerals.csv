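mineral,mechanism,log_k25,Ea_kJmol,n_H,molar_mass_g,stoich_Ca,stoich_Mg,stoich_K,stoich_Na,stoich_Si,stoich_Al,stoich_P,stoich_C,log_Keq,source
albite,acid,-10.16,65.0,0.457,262.22,0,0,0,1,3,1,0,0,,palandri_kharaka_2004
albite,neutral,-12.56,69.8,0.0,262.22,0,0,0,1,3,1,0,0,,palandri_kharaka_2004
albite,base,-15.60,71.0,-0.572,262.22,0,0,0,1,3,1,0,0,,palandri_kharaka_2004
anorthite,acid,-3.50,16.6,1.411,278.21,1,0,0,0,2,2,0,0,,palandri_kharaka_2004
anorthite,neutral,-9.12,17.8,0.0,278.21,1,0,0,0,2,2,0,0,,palandri_kharaka_2004
forsterite,acid,-6.85,67.2,0.470,140.69,0,2,0,0,1,0,0,0,,palandri_kharaka_2004
forsterite,neutral,-10.64,79.0,0.0,140.69,0,2,0,0,1,0,0,0,,palandri_kharaka_2004
diopside,acid,-6.36,96.1,0.710,216.55,1,1,0,0,2,0,0,0,,palandri_kharaka_2004
diopside,neutral,-11.11,40.6,0.0,216.55,1,1,0,0,2,0,0,0,,palandri_kharaka_2004
epidote,acid,-10.60,71.1,0.338,483.22,2,0,0,0,3,2,0,0,,palandri_kharaka_2004
epidote,neutral,-11.99,70.7,0.0,483.22,2,0,0,0,3,2,0,0,,palandri_kharaka_2004
epidote,base,-17.33,79.1,-0.556,483.22,2,0,0,0,3,2,0,0,,palandri_kharaka_2004
chlorite,acid,-11.11,88.0,0.500,555.80,0,5,0,0,3,2,0,0,,palandri_kharaka_2004_clinochlore
chlorite,neutral,-12.52,88.0,0.0,555.80,0,5,0,0,3,2,0,0,,palandri_kharaka_2004_clinochlore
ferroactinolite,acid,-8.40,18.9,0.700,970.08,2,0,0,0,8,0,0,0,,palandri_kharaka_2004_tremolite_proxy
ferroactinolite,neutral,-10.60,94.4,0.0,970.08,2,0,0,0,8,0,0,0,,palandri_kharaka_2004_tremolite_proxy
quartz,neutral,-13.40,90.9,0.0,60.08,0,0,0,0,1,0,0,0,,palandri_kharaka_2004
calcite,acid,-0.30,14.4,1.000,100.09,1,0,0,0,0,0,0,1,-8.48,palandri_kharaka_2004
calcite,neutral,-5.81,23.5,0.0,100.09,1,0,0,0,0,0,0,1,-8.48,palandri_kharaka_2004
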